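rudiment,age,mean_volume_1e4_um3,sd_volume_1e4_um3,n
1,E11.75,9.8,0.8,4
1,E12.5,22.1,5.1,16
1,E13.5,33.6,8.1,13
2,E11.75,6.2,1.9,2
2,E12.5,15.5,3.6,14
2,E13.5,32.1,6.4,14
3,E11.75,13.1,3.5,8
3,E12.5,20.2,5.5,14
3,E13.5,34.5,10.2,13
4,E11.75,9.6,3.7,6
4,E12.5,19.1,7.9,17
4,E13.5,40.2,8.3,14
5,E12.5,16.4,5.2,15
5,E13.5,26.5,7.4,14
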