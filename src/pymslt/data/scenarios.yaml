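# Default scenario grid for `pymslt run`: download multipliers crossed
# with discount rates, plus the permanent-weight-loss and equity
# counterfactuals at base settings.
download_multipliers: [1.0, 1.5, 2.0]
discount_rates: [0.0, 0.03, 0.06]
include_no_decay: true
include_equity: true
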