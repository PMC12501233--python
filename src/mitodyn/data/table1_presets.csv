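cell_line,condition,c_w,c_n,c_jw,m_p,opa1,drp1
OVCAR3,+S,1,0.28,0.62,0.99,0.02,0.31
OVCAR3,SS,0.05,0.6,0.31,,0.06,0.2
CAOV3,+S,0.55,0.32,1,0.63,0.03,0.1
CAOV3,SS,0.47,0.59,0.73,0.76,0.07,0.09
OVCA420,+S,0.42,0.31,0.89,0.29,0.03,0.23
OVCA420,SS,0.23,1,0.47,0.32,0.04,0.13
A4,+S,0.44,0.54,0.63,0.54,0.44,1
A4,SS,0.18,0.97,0.34,0.65,0.65,0.98
OVMZ6,+S,0.29,0.62,0.41,0.54,0.93,0.23
OVMZ6,SS,0.34,0.78,0.23,0.51,1,0.16
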