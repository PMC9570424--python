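0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000011111100000000000000
0000000000000000000000000000000000000000000111111110000000000000
0000000000000000000000000000000000000000001111111111000000000000
0000000000000000000000000000000000000000001111111111100000000000
0000000000000000000000000000000000000000001111111111100000000000
0000000000000000000000000000000000000000000111111111110000000000
0000000000000000000000000000000000000000000011111111110000000000
0000000000000000000000000000000000000000000001111111100000000000
0000000000000000000000000000000000000000000000111111000000000000
0000000000000000000000000000000000000000000000001110000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000001111110000000000000000000000000000000000000
0000000000000000000011111111000000000111000000000000000000000000
0000000000000000000111111111100000001111100000000000000000000000
0000000000000000001111111111110000011111110000000000000000000000
0000000000000000011111111111110000011111110000000000000000000000
0000000000000000011111111111111000011111111000000000000000000000
0000000000000000011111111111111000011111111000000000000000000000
0000000000000000011111111111111000011111111000000000000000000000
0000000000000000011111111111110000011111110000000000000000000000
0000000000000000001111111111100000001111110000000000000000000000
0000000000000000000111111111000000000111100000000000000000000000
0000000000000000000011111110000000000011000000000000000000000000
0000000000000000000001111100000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
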