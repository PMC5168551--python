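C1x,C1y,C2x,C2y,C3x,C3y,C4x,C4y,C5x,C5y,mode1,mode2,category
0.07,0.75,0.18,0.75,0.86,0.88,0.93,0.94,0.93,0.88,0.46,0.54,2
0.11,0.69,0.14,0.75,0.61,0.75,0.82,0.75,0.96,0.88,0.37,0.63,2
0.07,0.81,0.11,0.81,0.36,0.81,0.82,0.75,0.96,0.88,0.71,0.29,1
0.11,0.81,0.18,0.81,0.54,0.69,0.82,0.75,1.00,0.81,0.65,0.35,1
0.11,0.81,0.18,0.81,0.50,0.69,0.79,0.69,1.00,0.69,0.68,0.32,1
0.11,0.75,0.18,0.81,0.46,0.69,0.79,0.69,0.96,0.69,0.60,0.40,1
0.11,0.81,0.14,0.81,0.46,0.63,0.79,0.63,1.00,0.81,0.64,0.36,1
0.11,0.81,0.21,0.81,0.54,0.50,0.75,0.44,0.96,0.44,0.62,0.38,1
0.11,0.81,0.18,0.81,0.50,0.69,0.79,0.69,1.00,0.69,0.68,0.32,1
0.11,0.75,0.18,0.81,0.46,0.69,0.79,0.69,0.96,0.69,0.60,0.40,1
0.11,0.75,0.18,0.81,0.36,0.69,0.75,0.56,1.00,0.75,0.65,0.35,1
0.11,0.63,0.18,0.56,0.43,0.56,0.75,0.63,0.96,0.94,0.32,0.68,2
0.07,0.81,0.32,0.63,0.46,0.63,0.39,0.63,0.93,0.81,0.58,0.42,1
0.07,0.56,0.14,0.56,0.29,0.56,0.75,0.56,0.96,0.94,0.38,0.62,2
0.11,0.56,0.18,0.63,0.21,0.63,0.82,0.81,1.00,0.88,0.32,0.68,2
0.11,0.50,0.14,0.56,0.29,0.56,0.79,0.75,0.96,0.94,0.25,0.75,2
0.11,0.50,0.18,0.56,0.46,0.50,0.79,0.63,1.00,1.00,0.40,0.60,2
0.11,0.75,0.29,0.69,0.57,0.56,0.75,0.63,0.96,0.81,0.60,0.40,1
0.07,0.81,0.25,0.75,0.46,0.63,0.79,0.63,0.96,0.81,0.31,0.69,2
0.11,0.81,0.29,0.69,0.68,0.50,0.75,0.56,0.96,0.81,0.63,0.37,1
0.11,0.75,0.36,0.63,0.61,0.56,0.75,0.56,0.96,0.75,0.31,0.69,2
0.11,0.88,0.18,0.88,0.46,0.75,0.21,0.88,0.96,0.56,0.57,0.43,1
0.07,0.94,0.18,0.94,0.25,0.94,0.82,0.63,0.96,0.50,0.64,0.36,1
0.11,0.94,0.29,0.81,0.50,0.56,0.36,0.69,1.00,0.44,0.58,0.42,1
0.11,0.88,0.18,0.94,0.57,0.63,0.79,0.56,0.93,0.63,0.67,0.33,1
0.07,0.75,0.14,0.75,0.39,0.75,0.71,0.69,0.96,0.88,0.66,0.34,1
0.07,0.69,0.32,0.56,0.54,0.56,0.75,0.56,0.96,0.94,0.67,0.33,1
0.07,0.63,0.21,0.56,0.39,0.56,0.75,0.63,1.00,0.94,0.37,0.63,2
0.11,0.63,0.39,0.44,0.54,0.56,0.75,0.56,1.00,0.94,0.58,0.42,1
0.11,0.69,0.21,0.69,0.50,0.56,0.71,0.56,0.96,0.81,0.59,0.41,1
0.11,0.63,0.39,0.44,0.54,0.56,0.75,0.56,1.00,0.94,0.58,0.42,1
0.11,0.63,0.39,0.38,0.46,0.44,0.71,0.50,0.96,0.94,0.33,0.67,2
0.07,0.63,0.25,0.63,0.43,0.56,0.71,0.50,0.96,0.88,0.62,0.38,1
0.14,0.75,0.18,0.81,0.46,0.69,0.71,0.69,0.96,0.81,0.66,0.34,1
0.07,0.69,0.18,0.75,0.46,0.75,0.75,0.75,0.96,0.88,0.34,0.66,2
0.11,0.81,0.14,0.88,0.36,0.88,0.82,0.75,1.00,0.81,0.60,0.40,1
0.11,0.69,0.18,0.69,0.43,0.75,0.79,0.81,1.00,0.88,0.35,0.65,2
0.07,0.75,0.14,0.81,0.36,0.75,0.75,0.75,0.96,0.94,0.71,0.29,1
0.07,0.81,0.18,0.81,0.43,0.75,0.79,0.75,1.00,0.88,0.60,0.40,1
0.07,0.81,0.25,0.69,0.39,0.63,0.75,0.63,0.93,0.69,0.63,0.37,1
0.07,0.81,0.29,0.63,0.43,0.56,0.71,0.44,0.82,0.56,0.60,0.40,1
0.11,0.81,0.21,0.69,0.50,0.56,0.82,0.56,0.86,0.56,0.62,0.38,1
0.11,0.88,0.29,0.75,0.50,0.63,0.75,0.56,0.86,0.56,0.59,0.41,1
0.04,0.81,0.21,0.75,0.54,0.44,0.75,0.50,0.86,0.63,0.37,0.63,2
0.07,0.56,0.18,0.56,0.54,0.63,0.79,0.75,0.96,0.81,0.41,0.59,2
0.11,0.56,0.50,0.38,0.68,0.44,0.75,0.63,0.96,0.75,0.39,0.61,2
0.07,0.63,0.29,0.44,0.50,0.50,0.75,0.69,0.96,0.81,0.32,0.68,2
0.07,0.56,0.29,0.44,0.64,0.50,0.75,0.63,0.96,0.81,0.30,0.70,2
0.11,0.69,0.21,0.69,0.50,0.50,0.71,0.56,0.96,0.81,0.66,0.34,1
0.11,0.63,0.18,0.63,0.54,0.44,0.75,0.63,1.00,0.88,0.30,0.70,2
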