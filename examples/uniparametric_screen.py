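"""Single-channel change screen: 48-h baseline z-scores in 3-h bins.

Mirrors the simple per-channel analysis: quality-filter, z-score against
the 48 hours before the dose, aggregate to 3-h bins, and flag channels
with any post-dose bin at least one baseline SD from zero.
"""

import pandas as pd

from mcir import (IndividualProfile, ResponseParams, aggregate_3h,
                  detect_uniparam_change, filter_uniparametric,
                  inject_vaccine_response, simulate_individual,
                  zscore_baseline)

profile = IndividualProfile(participant_id="uni", rng_seed=11)
s = simulate_individual(profile, 8)
dose = s.data["timestamp"].iloc[0] + pd.Timedelta(days=4)
dosed, _ = inject_vaccine_response(
    s, dose, ResponseParams(delta_temp=0.8, magnitude_scale=1.5))

filtered = filter_uniparametric(dosed)
z = zscore_baseline(filtered, dose)
agg = aggregate_3h(z)
flags = detect_uniparam_change(agg, post_window_h=96)

post = agg.data[agg.data["bin_start"] >= dose]
print("max |z| per channel in the 96-h post-dose window:")
for ch in flags:
    print(f"  {ch:10s} {post[ch].abs().max():5.2f}  flagged={flags[ch]}")
# A flag means at least one 3-h bin deviated by >= 1 SD of that person's
# own 48-h pre-dose baseline — the uni-parametric notion of change.
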