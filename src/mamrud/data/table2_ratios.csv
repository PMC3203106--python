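rudiment,age,ect_over_mr_ratio,n
1,E11.5,3.5,2
2,E11.5,1.3,2
3,E11.5,5.6,4
4,E11.5,2.5,4
1,E12.5,4.5,4
2,E12.5,5.9,4
3,E12.5,4.0,4
4,E12.5,8.9,4
5,E12.5,4.2,4
1,E13.5,5.5,3
2,E13.5,24.8,3
3,E13.5,6.5,3
4,E13.5,8.1,3
5,E13.5,8.5,3
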