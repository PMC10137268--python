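# Published validation records for three volunteers: observation symbols,
# experimentally recorded states, and the model's predicted states
# (30 positions each, 1-based).
v1 obs  2 2 2 2 3 2 2 1 2 2 2 1 3 3 3 2 2 2 3 2 3 2 3 2 3 2 2 3 2 1
v1 rec  2 2 2 3 2 1 2 1 2 2 2 2 3 2 1 2 1 2 2 2 3 2 2 1 2 3 2 3 1 3
v1 pred 2 2 2 3 2 1 2 1 2 2 1 2 3 2 1 2 1 1 2 2 3 2 1 1 2 3 2 2 1 3
v2 obs  1 2 1 1 3 2 2 2 1 2 2 3 1 2 2 3 2 3 1 2 3 3 3 1 2 2 1 2 3 1
v2 rec  2 2 1 3 3 1 2 2 1 2 2 2 3 3 2 2 1 1 2 3 2 3 2 2 1 3 1 3 3 2
v2 pred 2 2 1 2 3 2 2 2 1 2 2 2 3 3 2 2 2 1 2 3 2 3 2 2 1 3 1 3 3 2
v3 obs  2 2 3 1 2 1 2 2 2 2 2 1 2 2 1 2 3 2 1 2 1 2 3 1 2 1 2 1 2 1
v3 rec  2 3 3 3 2 3 2 2 2 2 3 2 2 1 2 3 2 2 3 1 3 3 2 2 1 2 3 1 2 2
v3 pred 2 3 3 2 2 3 2 1 1 2 3 2 2 1 2 3 2 2 3 1 3 3 2 1 1 2 3 1 2 2
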