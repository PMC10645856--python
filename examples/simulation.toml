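# Monte-Carlo study of the variance estimators under the
# multiplicative-additive scrambling model, benchmark population I.

[population]
cov = [[10.0, 3.0, 2.9], [3.0, 2.0, 1.1], [2.9, 1.1, 2.0]]
means = [3.0, 3.0, 3.0]
size = 100000

[model]
kind = "dp"
var_t = 0.5

[simulation]
sample_sizes = [200, 300, 500]
var_s = [0.2, 0.5, 1.0]
replications = 10000
seed = 2023
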