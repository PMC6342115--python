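# Full-scale simulation study (long-running: hours on one CPU).
[study]
replicates = 100
nx = 100
ny = 100
n = 100
b = 1.0
family = gamma
shape = 10
outer_maxfev = 100
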