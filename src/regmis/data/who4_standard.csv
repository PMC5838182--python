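age_band,weight
0-14,0.2615
15-49,0.5201
50-69,0.1660
70+,0.0527
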