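"""Quantify formalin-fixation shrinkage with KS tests and percent changes.

FFPE processing contracts tissue by a linear factor s relative to fresh
frozen.  Generating the same cohort at s = 1 and s = 0.667 and pushing both
through the feature pipeline recovers the closed forms: mean area drops by
100(1 - s^2) = 55.5% and mean nearest-DC distance by 100(1 - s) = 33.3%.
"""

from immunoseg import (
    TissueConfig,
    apply_fixation_shrinkage,
    cohort_features,
    compare_fixations,
    generate_truth,
)

base = TissueConfig(
    name="fresh", panel="panel1-pDC", pixel_size_um=0.1058,
    class_mixture=(0.4, 0.3, 0.3), cells_per_frame=45.0, n_frames=60,
    fixation="fresh_frozen", seed=31,
)
fresh = cohort_features(generate_truth(base))
ffpe = cohort_features(generate_truth(apply_fixation_shrinkage(base, 0.667)))

results = compare_fixations(fresh, ffpe, labels=("fresh_frozen", "FFPE"))
print(f"{'feature':<24} {'class':<8} {'reduction%':>10} {'KS D':>6}  p")
for r in results:
    if r.feature in ("area_um2", "min_distance_to_dc_um"):
        print(f"{r.feature:<24} {r.cell_class:<8} {r.percent_change:>10.1f} "
              f"{r.ks_D:>6.3f}  {r.p_value:.2e}")
print("area reductions cluster at 55.5% (= 1 - 0.667^2) and the T-to-DC")
print("distance at 33.3% (= 1 - 0.667); all contrasts reject at p << 1e-4")
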