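name: CO_FULL
feed: CO
product_demand: {acetate: '1', butanediol: '1', ethanol: '4'}
assumptions: [bifurcating-mthfr, ethanol-via-aor]
rnf_h_per_fd: '2'
h_per_atp: '4'
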