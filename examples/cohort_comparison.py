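"""Compare two synthetic groups the way the analysis compares genotypes.

Builds a small cohort in which one group wakes abruptly (30 s crossfades)
and the other gradually (120 s), runs the full pipeline per animal, and
produces the two statistical outputs: the fragmentation table (pooled
t-tests over animals) and the per-band transition-speed models (gamma
marginal model for durations, linear mixed model for gradients, animal as
the random unit).
"""

import ovitrans as ot

base = dict(night_len_h=3.0, n_channels=4, rem_prob=0.0, prewake_delta_frac=1.0)
cfgs = {
    "gradual": ot.SimConfig(ramp_wake_s=120.0, ramp_sleep_s=120.0, **base),
    "abrupt": ot.SimConfig(ramp_wake_s=30.0, ramp_sleep_s=30.0, **base),
}
members, manifest = ot.generate_cohort(cfgs, n_per_group=3, base_seed=400)
print("cohort manifest:")
print(manifest.to_string(index=False))

out = ot.analyse_cohort(members)

print("\nfragmentation table (means +/- SEM over animals, pooled t-test):")
print(ot.fragmentation_table(out["summaries"]).round(3).to_string(index=False))

print("\ntransition-speed models, transitions to wake:")
tbl = ot.transition_metric_models(
    out["speed"], out["variance_peaks"], direction="TO_WAKE"
)
print(tbl.round(4).to_string(index=False))
print("\nBoth groups switch state equally often (fragmentation p >> 0.05), but")
print("the speed metrics separate them: durations shorter and |gradients|")
print("steeper in the abrupt group, mirrored by small p-values per band.")
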