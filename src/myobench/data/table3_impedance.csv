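# Source-impedance imbalance measured at 300 Hz / 1 Vrms during rest-state
# recordings at three output noise levels (10 repeats per level).
# mag_ohm: | |Z1+R1| - |Z2+R2| |; phase_deg: |arg(Z1+R1) - arg(Z2+R2)|.
level,trial,mag_ohm,phase_deg
1,1,1300,0.6
1,2,3000,0.2
1,3,3700,0.7
1,4,200,3.0
1,5,1400,4.1
1,6,600,0.4
1,7,1100,1.0
1,8,1600,0.5
1,9,1200,0.3
1,10,1500,0.6
2,1,5300,6.4
2,2,6600,7.4
2,3,7500,5.5
2,4,7200,4.8
2,5,7500,5.5
2,6,9400,12.0
2,7,8300,11.6
2,8,9500,12.0
2,9,8700,12.2
2,10,8800,11.8
3,1,18300,21.5
3,2,21700,22.9
3,3,12700,20.4
3,4,16500,22.4
3,5,11800,40.3
3,6,19000,40.8
3,7,28800,39.9
3,8,29600,41.1
3,9,24300,41.8
3,10,29800,40.5
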