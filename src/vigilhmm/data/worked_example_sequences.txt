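# Length-30 worked-example record: observation symbols (O) and the
# experimentally recorded vigilance states (Q), 1-based.
O 2 3 2 2 1 2 1 2 2 2 2 3 3 1 1 2 1 1 2 2 2 1 2 3 2 3 2 3 3 1
Q 2 2 1 3 2 2 3 1 2 2 2 1 1 2 1 2 2 2 3 2 3 1 3 1 2 2 2 2 2 1
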