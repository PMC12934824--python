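"""Denoised cell-type classification on a noisy synthetic tissue.

Runs the full pipeline — 100-cell rare-type filter, per-cell rank z-score,
ANOVA gene selection, standardization, PCA, multinomial logistic classifier
— under five-fold stratified cross-validation.
"""

import plaincell as pc
from plaincell.simulate import simulate_tissue

matrix, truth = simulate_tissue(n_types=6, n_genes=600, cells_per_type=(80, 200),
                                batch_sd=0.5, seed=0)
print("cells per planted type:", truth["cells_per_type"])

report = pc.crossvalidate(matrix, "cell_type", folds=5,
                          n_genes=400, n_pc=20, min_cells=100, seed=0)
print(f"per-fold macro F1: {[round(s, 3) for s in report.fold_scores]}")
print(f"mean macro F1: {report.macro_f1:.3f}")
# Types below the 100-cell filter are excluded before splitting; the macro
# F1 weights every surviving type equally regardless of its abundance.
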