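C1x,C1y,C2x,C2y,C3x,C3y,C4x,C4y,C5x,C5y,mode1,mode2,mode3,mode4,category
0.07,0.75,0.18,0.75,0.86,0.88,0.93,0.94,0.93,0.88,0.29,0.19,0.31,0.22,3
0.11,0.69,0.14,0.75,0.61,0.75,0.82,0.75,0.96,0.88,0.30,0.15,0.37,0.18,3
0.07,0.81,0.11,0.81,0.36,0.81,0.82,0.75,0.96,0.88,0.13,0.17,0.12,0.59,4
0.11,0.81,0.18,0.81,0.54,0.69,0.82,0.75,1.00,0.81,0.16,0.33,0.19,0.33,4
0.11,0.81,0.18,0.81,0.50,0.69,0.79,0.69,1.00,0.69,0.18,0.17,0.14,0.51,4
0.11,0.75,0.18,0.81,0.46,0.69,0.79,0.69,0.96,0.69,0.22,0.25,0.20,0.33,4
0.11,0.81,0.14,0.81,0.46,0.63,0.79,0.63,1.00,0.81,0.15,0.38,0.19,0.28,2
0.11,0.81,0.21,0.81,0.54,0.50,0.75,0.44,0.96,0.44,0.21,0.28,0.19,0.32,4
0.11,0.81,0.18,0.81,0.50,0.69,0.79,0.69,1.00,0.69,0.18,0.17,0.14,0.51,4
0.11,0.75,0.18,0.81,0.46,0.69,0.79,0.69,0.96,0.69,0.22,0.25,0.20,0.33,4
0.11,0.75,0.18,0.81,0.36,0.69,0.75,0.56,1.00,0.75,0.14,0.24,0.16,0.46,4
0.11,0.63,0.18,0.56,0.43,0.56,0.75,0.63,0.96,0.94,0.42,0.12,0.31,0.14,1
0.07,0.81,0.32,0.63,0.46,0.63,0.39,0.63,0.93,0.81,0.22,0.24,0.18,0.36,4
0.07,0.56,0.14,0.56,0.29,0.56,0.75,0.56,0.96,0.94,0.31,0.15,0.34,0.20,3
0.11,0.56,0.18,0.63,0.21,0.63,0.82,0.81,1.00,0.88,0.31,0.13,0.38,0.18,3
0.11,0.50,0.14,0.56,0.29,0.56,0.79,0.75,0.96,0.94,0.40,0.10,0.34,0.16,1
0.11,0.50,0.18,0.56,0.46,0.50,0.79,0.63,1.00,1.00,0.36,0.15,0.31,0.17,1
0.11,0.75,0.29,0.69,0.57,0.56,0.75,0.63,0.96,0.81,0.22,0.26,0.19,0.33,4
0.07,0.81,0.25,0.75,0.46,0.63,0.79,0.63,0.96,0.81,0.41,0.11,0.26,0.22,1
0.11,0.81,0.29,0.69,0.68,0.50,0.75,0.56,0.96,0.81,0.19,0.15,0.14,0.52,4
0.11,0.75,0.36,0.63,0.61,0.56,0.75,0.56,0.96,0.75,0.47,0.10,0.27,0.16,1
0.11,0.88,0.18,0.88,0.46,0.75,0.21,0.88,0.96,0.56,0.20,0.27,0.18,0.35,4
0.07,0.94,0.18,0.94,0.25,0.94,0.82,0.63,0.96,0.50,0.14,0.29,0.16,0.41,4
0.11,0.94,0.29,0.81,0.50,0.56,0.36,0.69,1.00,0.44,0.21,0.22,0.17,0.39,4
0.11,0.88,0.18,0.94,0.57,0.63,0.79,0.56,0.93,0.63,0.11,0.17,0.11,0.61,4
0.07,0.75,0.14,0.75,0.39,0.75,0.71,0.69,0.96,0.88,0.16,0.21,0.16,0.47,4
0.07,0.69,0.32,0.56,0.54,0.56,0.75,0.56,0.96,0.94,0.18,0.15,0.14,0.53,4
0.07,0.63,0.21,0.56,0.39,0.56,0.75,0.63,1.00,0.94,0.27,0.17,0.43,0.13,3
0.11,0.63,0.39,0.44,0.54,0.56,0.75,0.56,1.00,0.94,0.16,0.39,0.21,0.24,2
0.11,0.69,0.21,0.69,0.50,0.56,0.71,0.56,0.96,0.81,0.24,0.21,0.20,0.35,4
0.11,0.63,0.39,0.44,0.54,0.56,0.75,0.56,1.00,0.94,0.16,0.39,0.21,0.24,2
0.11,0.63,0.39,0.38,0.46,0.44,0.71,0.50,0.96,0.94,0.38,0.13,0.37,0.13,1
0.07,0.63,0.25,0.63,0.43,0.56,0.71,0.50,0.96,0.88,0.20,0.15,0.15,0.50,4
0.14,0.75,0.18,0.81,0.46,0.69,0.71,0.69,0.96,0.81,0.16,0.18,0.15,0.51,4
0.07,0.69,0.18,0.75,0.46,0.75,0.75,0.75,0.96,0.88,0.41,0.12,0.29,0.17,1
0.11,0.81,0.14,0.88,0.36,0.88,0.82,0.75,1.00,0.81,0.15,0.33,0.18,0.35,4
0.11,0.69,0.18,0.69,0.43,0.75,0.79,0.81,1.00,0.88,0.30,0.15,0.36,0.19,3
0.07,0.75,0.14,0.81,0.36,0.75,0.75,0.75,0.96,0.94,0.13,0.17,0.13,0.57,4
0.07,0.81,0.18,0.81,0.43,0.75,0.79,0.75,1.00,0.88,0.18,0.21,0.18,0.43,4
0.07,0.81,0.25,0.69,0.39,0.63,0.75,0.63,0.93,0.69,0.16,0.27,0.18,0.39,4
0.07,0.81,0.29,0.63,0.43,0.56,0.71,0.44,0.82,0.56,0.22,0.26,0.21,0.31,4
0.11,0.81,0.21,0.69,0.50,0.56,0.82,0.56,0.86,0.56,0.21,0.27,0.20,0.32,4
0.11,0.88,0.29,0.75,0.50,0.63,0.75,0.56,0.86,0.56,0.23,0.27,0.22,0.28,4
0.04,0.81,0.21,0.75,0.54,0.44,0.75,0.50,0.86,0.63,0.38,0.15,0.31,0.16,1
0.07,0.56,0.18,0.56,0.54,0.63,0.79,0.75,0.96,0.81,0.29,0.21,0.32,0.19,3
0.11,0.56,0.50,0.38,0.68,0.44,0.75,0.63,0.96,0.75,0.25,0.19,0.41,0.14,3
0.07,0.63,0.29,0.44,0.50,0.50,0.75,0.69,0.96,0.81,0.44,0.11,0.26,0.19,1
0.07,0.56,0.29,0.44,0.64,0.50,0.75,0.63,0.96,0.81,0.45,0.10,0.26,0.19,1
0.11,0.69,0.21,0.69,0.50,0.50,0.71,0.56,0.96,0.81,0.17,0.14,0.13,0.55,4
0.11,0.63,0.18,0.63,0.54,0.44,0.75,0.63,1.00,0.88,0.45,0.10,0.26,0.19,1
0.11,0.50,0.18,0.44,0.50,0.50,0.25,0.44,0.96,0.38,0.39,0.13,0.31,0.16,1
0.11,0.63,0.14,0.50,0.36,0.50,0.79,0.31,0.96,0.31,0.17,0.42,0.17,0.24,2
0.07,0.50,0.14,0.50,0.43,0.50,0.75,0.56,0.96,0.44,0.34,0.20,0.32,0.14,1
0.07,0.31,0.14,0.25,0.39,0.44,0.79,0.56,1.00,0.56,0.37,0.16,0.34,0.13,1
0.07,0.25,0.14,0.25,0.46,0.50,0.79,0.63,0.96,0.56,0.40,0.14,0.26,0.20,1
0.11,0.31,0.18,0.25,0.18,0.25,0.79,0.63,1.00,0.63,0.35,0.18,0.31,0.16,1
0.11,0.25,0.14,0.25,0.57,0.56,0.82,0.56,1.00,0.56,0.32,0.14,0.38,0.17,3
0.11,0.31,0.14,0.31,0.46,0.50,0.79,0.56,1.00,0.50,0.26,0.22,0.40,0.12,3
0.07,0.25,0.14,0.25,0.46,0.50,0.79,0.63,0.96,0.56,0.40,0.14,0.26,0.20,1
0.11,0.31,0.18,0.25,0.18,0.25,0.79,0.63,1.00,0.63,0.35,0.18,0.31,0.16,1
0.11,0.31,0.14,0.25,0.43,0.44,0.79,0.56,1.00,0.63,0.41,0.15,0.27,0.17,1
0.14,0.44,0.18,0.44,0.43,0.50,0.75,0.50,0.82,0.56,0.34,0.14,0.37,0.14,3
0.07,0.44,0.21,0.38,0.57,0.44,0.79,0.38,0.93,0.19,0.14,0.52,0.17,0.17,2
0.11,0.56,0.14,0.56,0.50,0.50,0.75,0.38,0.96,0.25,0.12,0.56,0.16,0.15,2
0.07,0.31,0.18,0.31,0.46,0.38,0.75,0.44,0.96,0.25,0.26,0.20,0.40,0.14,3
0.11,0.38,0.14,0.38,0.43,0.44,0.75,0.50,0.96,0.31,0.13,0.52,0.14,0.21,2
0.11,0.44,0.29,0.50,0.57,0.50,0.75,0.56,0.96,0.38,0.29,0.14,0.43,0.14,3
0.07,0.50,0.25,0.63,0.43,0.63,0.79,0.63,1.00,0.44,0.14,0.33,0.15,0.39,4
0.07,0.44,0.14,0.50,0.54,0.56,0.32,0.56,0.96,0.38,0.23,0.23,0.20,0.34,4
0.11,0.44,0.32,0.50,0.54,0.50,0.79,0.44,1.00,0.25,0.10,0.63,0.13,0.13,2
0.11,0.56,0.32,0.75,0.57,0.75,0.79,0.56,0.96,0.31,0.11,0.61,0.15,0.14,2
0.11,0.25,0.18,0.25,0.50,0.38,0.18,0.25,0.96,0.56,0.26,0.20,0.39,0.15,3
0.11,0.44,0.18,0.44,0.46,0.63,0.82,0.81,0.96,0.88,0.27,0.19,0.41,0.13,3
0.07,0.31,0.18,0.31,0.36,0.38,0.21,0.31,0.96,0.50,0.39,0.13,0.27,0.21,1
0.11,0.38,0.14,0.38,0.25,0.38,0.14,0.38,0.96,0.50,0.27,0.19,0.39,0.15,3
0.07,0.25,0.29,0.50,0.61,0.63,0.75,0.63,0.96,0.50,0.30,0.20,0.33,0.17,3
0.11,0.44,0.14,0.44,0.54,0.56,0.71,0.56,0.96,0.44,0.21,0.14,0.17,0.49,4
0.07,0.38,0.18,0.38,0.61,0.63,0.75,0.56,0.96,0.50,0.29,0.16,0.39,0.15,3
0.11,0.38,0.25,0.50,0.64,0.56,0.79,0.56,0.96,0.50,0.25,0.25,0.36,0.13,3
0.07,0.38,0.25,0.50,0.61,0.63,0.75,0.63,0.96,0.50,0.16,0.44,0.17,0.24,2
0.07,0.38,0.25,0.44,0.46,0.44,0.82,0.50,0.96,0.50,0.29,0.21,0.33,0.17,3
0.11,0.25,0.18,0.25,0.50,0.44,0.79,0.56,0.96,0.69,0.28,0.21,0.38,0.12,3
0.07,0.25,0.25,0.38,0.43,0.38,0.82,0.50,0.96,0.56,0.17,0.42,0.19,0.22,2
0.11,0.31,0.29,0.44,0.50,0.50,0.82,0.50,0.96,0.56,0.08,0.70,0.10,0.12,2
0.07,0.38,0.18,0.38,0.54,0.44,0.79,0.50,0.96,0.50,0.11,0.61,0.14,0.14,2
0.07,0.25,0.18,0.31,0.43,0.38,0.75,0.56,0.96,0.50,0.11,0.59,0.15,0.15,2
0.11,0.31,0.18,0.38,0.43,0.50,0.79,0.63,0.96,0.63,0.25,0.18,0.47,0.10,3
0.07,0.44,0.21,0.44,0.57,0.56,0.50,0.63,0.96,0.38,0.21,0.27,0.32,0.19,3
0.07,0.50,0.39,0.69,0.57,0.63,0.75,0.56,0.96,0.38,0.22,0.27,0.18,0.33,4
0.11,0.44,0.18,0.50,0.57,0.56,0.75,0.56,0.96,0.31,0.17,0.36,0.18,0.29,2
0.07,0.38,0.21,0.44,0.46,0.56,0.75,0.56,0.96,0.25,0.15,0.42,0.17,0.27,2
0.07,0.38,0.25,0.50,0.57,0.56,0.75,0.50,0.96,0.25,0.13,0.56,0.16,0.16,2
0.11,0.44,0.21,0.50,0.61,0.63,0.79,0.56,1.00,0.38,0.19,0.31,0.19,0.31,2
0.07,0.38,0.14,0.38,0.46,0.50,0.79,0.56,1.00,0.50,0.35,0.19,0.30,0.16,1
0.07,0.44,0.14,0.44,0.36,0.44,0.75,0.56,0.96,0.44,0.41,0.14,0.30,0.15,1
0.11,0.56,0.21,0.56,0.43,0.63,0.75,0.63,0.96,0.38,0.25,0.25,0.37,0.13,3
0.11,0.44,0.21,0.44,0.54,0.56,0.79,0.50,0.96,0.44,0.08,0.70,0.10,0.12,2
0.11,0.38,0.21,0.38,0.61,0.50,0.82,0.44,1.00,0.38,0.16,0.46,0.19,0.18,2
0.11,0.38,0.18,0.38,0.57,0.56,0.75,0.63,0.96,0.31,0.26,0.16,0.45,0.13,3
0.11,0.44,0.29,0.50,0.54,0.63,0.79,0.69,1.00,0.50,0.12,0.55,0.15,0.18,2
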