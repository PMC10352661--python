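SpliceModel 1
group II
param branch_min -9
param branch_max -5
param branch_bonus 2.0
param hairpin_start -35
param hairpin_end -9
param hairpin_min_stem 4
param hairpin_bonus_per_pair 0.5
param hairpin_max_pairs 8
param scan_floor5 11.0
param scan_floor3 6.0
pwm5 8
0.0500 0.0500 0.8500 0.0500
0.0500 0.0500 0.0500 0.8500
0.0500 0.0500 0.8500 0.0500
0.0500 0.8500 0.0500 0.0500
0.0500 0.0500 0.8500 0.0500
0.1000 0.1000 0.7000 0.1000
0.1000 0.1000 0.1000 0.7000
0.7000 0.1000 0.1000 0.1000
pwm3 6
0.1000 0.7000 0.1000 0.1000
0.1000 0.1000 0.1000 0.7000
0.1000 0.1000 0.7000 0.1000
0.7000 0.1000 0.1000 0.1000
0.8000 0.0667 0.0667 0.0667
0.1167 0.1167 0.1167 0.6500
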