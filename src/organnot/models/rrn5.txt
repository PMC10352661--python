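StructureProfile 1
name rrn5
strategy 0 1 2
element strand 12
0.0500 0.0500 0.8500 0.0500
0.0500 0.0500 0.8500 0.0500
0.0500 0.0500 0.0500 0.8500
0.0500 0.0500 0.0500 0.8500
0.8500 0.0500 0.0500 0.0500
0.0500 0.8500 0.0500 0.0500
0.0500 0.8500 0.0500 0.0500
0.8500 0.0500 0.0500 0.0500
0.0500 0.8500 0.0500 0.0500
0.0500 0.8500 0.0500 0.0500
0.0500 0.0500 0.0500 0.8500
0.0500 0.0500 0.8500 0.0500
spacer 2 4
element helix 6 4 4 5 0
spacer 2 4
element strand 8
0.0500 0.8500 0.0500 0.0500
0.0500 0.8500 0.0500 0.0500
0.0500 0.0500 0.8500 0.0500
0.8500 0.0500 0.0500 0.0500
0.8500 0.0500 0.0500 0.0500
0.0500 0.8500 0.0500 0.0500
0.0500 0.0500 0.0500 0.8500
0.0500 0.8500 0.0500 0.0500
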