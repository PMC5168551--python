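C1x,C1y,C2x,C2y,C3x,C3y,C4x,C4y,C5x,C5y,mode1,mode2,category
0.11,0.57,0.18,0.50,0.50,0.57,0.25,0.50,0.96,0.43,0.29,0.71,2
0.11,0.71,0.14,0.57,0.36,0.57,0.79,0.36,0.96,0.36,0.70,0.30,1
0.07,0.57,0.14,0.57,0.43,0.57,0.75,0.64,0.96,0.50,0.31,0.69,2
0.07,0.36,0.14,0.29,0.39,0.50,0.79,0.64,1.00,0.64,0.25,0.75,2
0.07,0.29,0.14,0.29,0.46,0.57,0.79,0.71,0.96,0.64,0.33,0.67,2
0.11,0.36,0.18,0.29,0.18,0.29,0.79,0.71,1.00,0.71,0.32,0.68,2
0.11,0.29,0.14,0.29,0.57,0.64,0.82,0.64,1.00,0.64,0.30,0.70,2
0.11,0.36,0.14,0.36,0.46,0.57,0.79,0.64,1.00,0.57,0.30,0.70,2
0.07,0.29,0.14,0.29,0.46,0.57,0.79,0.71,0.96,0.64,0.33,0.67,2
0.11,0.36,0.18,0.29,0.18,0.29,0.79,0.71,1.00,0.71,0.32,0.68,2
0.11,0.36,0.14,0.29,0.43,0.50,0.79,0.64,1.00,0.71,0.30,0.70,2
0.14,0.50,0.18,0.50,0.43,0.57,0.75,0.57,0.82,0.64,0.27,0.73,2
0.07,0.50,0.21,0.43,0.57,0.50,0.79,0.43,0.93,0.21,0.78,0.22,1
0.11,0.64,0.14,0.64,0.50,0.57,0.75,0.43,0.96,0.29,0.81,0.19,1
0.07,0.36,0.18,0.36,0.46,0.43,0.75,0.50,0.96,0.29,0.33,0.67,2
0.11,0.43,0.14,0.43,0.43,0.50,0.75,0.57,0.96,0.36,0.79,0.21,1
0.11,0.50,0.29,0.57,0.57,0.57,0.75,0.64,0.96,0.43,0.30,0.70,2
0.07,0.57,0.25,0.71,0.43,0.71,0.79,0.71,1.00,0.50,0.72,0.28,1
0.07,0.50,0.14,0.57,0.54,0.64,0.32,0.64,0.96,0.43,0.53,0.47,1
0.11,0.50,0.32,0.57,0.54,0.57,0.79,0.50,1.00,0.29,0.84,0.16,1
0.11,0.64,0.32,0.86,0.57,0.86,0.79,0.64,0.96,0.36,0.80,0.20,1
0.11,0.29,0.18,0.29,0.50,0.43,0.18,0.29,0.96,0.64,0.35,0.65,2
0.11,0.50,0.18,0.50,0.46,0.71,0.82,0.93,0.96,1.00,0.33,0.67,2
0.07,0.36,0.18,0.36,0.36,0.43,0.21,0.36,0.96,0.57,0.32,0.68,2
0.11,0.43,0.14,0.43,0.25,0.43,0.14,0.43,0.96,0.57,0.34,0.66,2
0.07,0.29,0.29,0.57,0.61,0.71,0.75,0.71,0.96,0.57,0.37,0.63,2
0.11,0.50,0.14,0.50,0.54,0.64,0.71,0.64,0.96,0.50,0.49,0.51,2
0.07,0.43,0.18,0.43,0.61,0.71,0.75,0.64,0.96,0.57,0.32,0.68,2
0.11,0.43,0.25,0.57,0.64,0.64,0.79,0.64,0.96,0.57,0.37,0.63,2
0.07,0.43,0.25,0.57,0.61,0.71,0.75,0.71,0.96,0.57,0.74,0.26,1
0.07,0.43,0.25,0.50,0.46,0.50,0.82,0.57,0.96,0.57,0.38,0.62,2
0.11,0.29,0.18,0.29,0.50,0.50,0.79,0.64,0.96,0.79,0.29,0.71,2
0.07,0.29,0.25,0.43,0.43,0.43,0.82,0.57,0.96,0.64,0.70,0.30,1
0.11,0.36,0.29,0.50,0.50,0.57,0.82,0.57,0.96,0.64,0.89,0.11,1
0.07,0.43,0.18,0.43,0.54,0.50,0.79,0.57,0.96,0.57,0.87,0.13,1
0.07,0.29,0.18,0.36,0.43,0.43,0.75,0.64,0.96,0.57,0.80,0.20,1
0.11,0.36,0.18,0.43,0.43,0.57,0.79,0.71,0.96,0.71,0.26,0.74,2
0.07,0.50,0.21,0.50,0.57,0.64,0.50,0.71,0.96,0.43,0.49,0.51,2
0.07,0.57,0.39,0.79,0.57,0.71,0.75,0.64,0.96,0.43,0.61,0.39,1
0.11,0.50,0.18,0.57,0.57,0.64,0.75,0.64,0.96,0.36,0.70,0.30,1
0.07,0.43,0.21,0.50,0.46,0.64,0.75,0.64,0.96,0.29,0.76,0.24,1
0.07,0.43,0.25,0.57,0.57,0.64,0.75,0.57,0.96,0.29,0.80,0.20,1
0.11,0.50,0.21,0.57,0.61,0.71,0.79,0.64,1.00,0.43,0.65,0.35,1
0.07,0.43,0.14,0.43,0.46,0.57,0.79,0.64,1.00,0.57,0.33,0.67,2
0.07,0.50,0.14,0.50,0.36,0.50,0.75,0.64,0.96,0.50,0.27,0.73,2
0.11,0.64,0.21,0.64,0.43,0.71,0.75,0.71,0.96,0.43,0.37,0.63,2
0.11,0.50,0.21,0.50,0.54,0.64,0.79,0.57,0.96,0.50,0.91,0.09,1
0.11,0.43,0.21,0.43,0.61,0.57,0.82,0.50,1.00,0.43,0.74,0.26,1
0.11,0.43,0.18,0.43,0.57,0.64,0.75,0.71,0.96,0.36,0.31,0.69,2
0.11,0.50,0.29,0.57,0.54,0.71,0.79,0.79,1.00,0.57,0.81,0.19,1
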