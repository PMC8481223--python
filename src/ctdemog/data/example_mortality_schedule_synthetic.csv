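age_class,sex,qx
JUV,M,0.35
JUV,F,0.35
1Y,M,0.12
1Y,F,0.10
2Y,M,0.08
2Y,F,0.05
AD,M,0.12
AD,F,0.08
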