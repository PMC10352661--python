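StructureProfile 1
name ssrA
strategy 1 0 2
element helix 7 4 4 6 0
spacer 2 7
element strand 12
0.8500 0.0500 0.0500 0.0500
0.0500 0.0500 0.0500 0.8500
0.0500 0.0500 0.0500 0.8500
0.0500 0.0500 0.8500 0.0500
0.8500 0.0500 0.0500 0.0500
0.0500 0.8500 0.0500 0.0500
0.0500 0.0500 0.8500 0.0500
0.0500 0.0500 0.8500 0.0500
0.0500 0.0500 0.0500 0.8500
0.0500 0.0500 0.0500 0.8500
0.0500 0.8500 0.0500 0.0500
0.8500 0.0500 0.0500 0.0500
hard 3 G
hard 4 A
hard 5 C
spacer 1 6
element helix 6 4 4 5 1
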