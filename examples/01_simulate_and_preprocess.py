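"""Simulate an aligned GC-MS volatile table and preprocess it.

Generates 6 varieties x 10 berry replicates plus blank injections, applies
the detection-height and 10-fold blank filters, TIC-normalizes and
Pareto-scales — the standard route from raw peak areas to a modelling
matrix.
"""

import aromapls as ap

markers, rep_factors, split_markers = ap.plant_hierarchy_markers(
    ap.synth.DEFAULT_CLASS_TREE, n_features=200
)
cfg = ap.PeakSynthConfig(
    planted_markers=markers, replicate_factors=rep_factors, seed=1
)
table, truth = ap.generate_peak_table(cfg)
print(f"generated: {sum(table.is_sample)} sample rows, "
      f"{(~table.is_sample).sum()} blanks, {len(table.features)} features")

filtered, report = ap.filter_features(table, min_height=2500, blank_fold=10)
print(f"filter removed {len(report)} feature(s): "
      f"{report.feature.tolist()[:5]}... (rule: {set(report.rule)})")
print("  -> these are the planted background features:",
      report.feature.tolist() == truth["background_features"])

normalized = ap.tic_normalize(filtered)
print(f"after TIC each row sums to {normalized.areas.sum(axis=1).iloc[0]:.6f}")

scaled = ap.scale_matrix(normalized, method="pareto")
print(f"scaled matrix: {scaled.X.shape[0]} x {scaled.X.shape[1]}, "
      f"column means ~0, Pareto divisor = sqrt(sd) per variable")
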