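# Reference 3x3 matrices of the published vigilance HMM.
# B_init: supervised count-based emission matrix before training (as
#   printed; rows 1 and 2 do not sum to 1 exactly -- kept verbatim).
# A_hat, B_hat: transition and emission matrices after Baum-Welch training.
B_init 0.3662 0.4648 0.2690
B_init 0.2436 0.5128 0.2436
B_init 0.2877 0.4521 0.2603
A_hat 0.0069 0.6255 0.3676
A_hat 0.0865 0.0077 0.9058
A_hat 0.3637 0.1571 0.4791
B_hat 0.3078 0.2082 0.4840
B_hat 0.6987 0.0157 0.2856
B_hat 0.0191 0.8510 0.1298
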