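year,category,count,id_r,n_events
2017,ADM,12,1,16
2017,ADF,17,2,16
2017,ADU,23,0,16
2017,2YM,7,1,16
2017,2YF,5,0,16
2017,2YU,13,0,16
2017,1YM,4,0,16
2017,1YF,1,1,16
2017,1YU,5,0,16
2017,JUV,32,1,16
2017,UNK,40,0,16
2018,ADM,30,11,32
2018,ADF,32,17,32
2018,ADU,12,0,32
2018,2YM,15,4,32
2018,2YF,2,2,32
2018,2YU,8,0,32
2018,1YM,8,0,32
2018,1YF,6,2,32
2018,1YU,8,1,32
2018,JUV,48,2,32
2018,UNK,36,1,32
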