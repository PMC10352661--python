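SpliceModel 1
group I
param terminal_g_bonus 2.0
param p1_guide_start 2
param p1_guide_len 6
param p1_bonus_per_pair 0.75
param p1_min_pairs 5
param scan_floor5 1.0
param scan_floor3 5.5
pwm5 2
0.1500 0.1500 0.1500 0.5500
0.5500 0.1500 0.1500 0.1500
pwm3 6
0.5000 0.1667 0.1667 0.1667
0.1667 0.1667 0.1667 0.5000
0.1667 0.1667 0.1667 0.5000
0.6000 0.1333 0.1333 0.1333
0.8000 0.0667 0.0667 0.0667
0.0333 0.0333 0.9000 0.0333
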