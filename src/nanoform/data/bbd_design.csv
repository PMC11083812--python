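run,GMS,P80,CBD,Y1,Y2,Y3,Y4
F1,1.5,0.6,15,223,0.2544,92.7,1.82
F2,2.5,0.6,15,300,0.4440,96.5,1.15
F3,1.5,1.0,15,234,0.4328,87.9,1.75
F4,2.5,1.0,15,140,0.2574,90.8,1.08
F5,1.5,0.8,10,196,0.2999,87.0,1.15
F6,2.5,0.8,10,183,0.3165,89.4,0.71
F7,1.5,0.8,20,130,0.2548,92.4,2.45
F8,2.5,0.8,20,119,0.2602,94.9,1.51
F9,2.0,0.6,10,257,0.2862,86.6,0.86
F10,2.0,1.0,10,127,0.2770,84.6,0.84
F11,2.0,0.6,20,122,0.2516,96.1,1.91
F12,2.0,1.0,20,120,0.2043,91.8,1.82
F13,2.0,0.8,15,139,0.2914,90.2,1.34
F14,2.0,0.8,15,138,0.2905,91.9,1.37
F15,2.0,0.8,15,136,0.2844,91.3,1.36
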