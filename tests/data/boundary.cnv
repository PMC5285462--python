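FID IID CHR BP1 BP2 TYPE SCORE SITES
F1 S1 1 1000001 1100000 1 0 15
F2 S2 1 2000001 2099999 1 0 50
F3 S3 2 3000001 3999999 3 0 14
F4 S4 2 4000001 4100001 3 0 15
F5 S5 3 5000001 5250000 1 0 30
F6 S6 3 6000001 6100000 1 0 14
F7 S7 4 7000001 7099999 3 0 15
F8 S8 4 8000001 12999999 1 0 100
F9 S9 5 9000001 9100000 3 0 16
F10 S10 5 10000001 10150000 1 0 15
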