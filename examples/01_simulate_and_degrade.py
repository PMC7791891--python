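"""Generate a synthetic ground-truth cohort and degrade it into predictions.

Builds a small five-class FFPE-like cohort (the single-stain panel: two
T-cell subsets, mDC, pDC, B cells), then applies a detection-degradation
model with per-class miss rates, false positives, and boundary jitter.
"""

from immunoseg import DegradationConfig, dataset_config, degrade, generate_truth

cfg = dataset_config("FFPE_SS", n_frames=10, seed=1)
truth = generate_truth(cfg)

counts = {}
for _, inst in truth.all_instances():
    counts[inst.cell_class] = counts.get(inst.cell_class, 0) + 1
n_truth = sum(counts.values())
print(f"truth cohort: {len(truth.frames)} frames, {n_truth} cells")
print("  per class:", dict(sorted(counts.items())))

dcfg = DegradationConfig(
    detect_prob={"CD4T": 0.90, "CD4negT": 0.85, "mDC": 0.38, "pDC": 0.69, "Bcell": 0.75},
    fp_rate={"CD4T": 1.0, "CD4negT": 1.0},
    jitter=0.08,
    seed=2,
)
pred = degrade(truth, dcfg)
n_pred = sum(len(f.instances) for f in pred.frames)
print(f"predicted cohort: {n_pred} cells "
      f"({n_pred - n_truth:+d} net vs truth: misses minus false positives)")
print("each prediction carries a confidence score; cells below 0.3 are later discarded")
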