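#!/usr/bin/env python
"""Recompute the published FFA-SVR performance statistics from the packaged
experimental/predicted retention-factor tables (validation-only mode: no
descriptor matrices are needed).

Writes results/published_model_metrics.csv (metric x model) and
results/published_ad_summary.csv (leverage thresholds and worst standardized
residuals), and prints what reproduces and what does not.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from qsrr import fixtures
from qsrr.domain import leverage_threshold, standardized_residuals
from qsrr.pipeline import report_table
from qsrr.validation import evaluate_pairs

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

q = evaluate_pairs(fixtures.load_quinolone_predictions(), p=5)
s = evaluate_pairs(fixtures.load_sulfonamide_predictions(), p=3)
table = report_table({"quinolones FFA-SVR": q, "sulfonamides FFA-SVR": s})
table.to_csv(OUT / "published_model_metrics.csv")
print("Performance metrics recomputed from the packaged prediction tables:")
print(table.to_string(), "\n")

print("Notes:")
print(" * R2/q2 are squared Pearson correlations; this convention reproduces")
print("   the published calibration/CV/prediction statistics to the printed")
print("   precision (the 1-PRESS/SS form does not: it gives ~0.715 for the")
print("   quinolone q2 instead of 0.808).")
print(" * The quinolone calibration Spearman rho recomputes to "
      f"{q.rho_cal:.3f}; the published 0.976 is not attainable from the")
print("   3-decimal table (rank sums are integers), so the original value")
print("   must derive from full-precision predictions ordered differently")
print("   among the near-tied k values around 1.55-1.62.")
print(" * Adjusted R2 by the standard formula gives "
      f"{q.r2_adj:.3f} / {s.r2_adj:.3f}; the published 0.926 / 0.896 do not")
print("   follow that formula with (n=16,p=5) / (n=30,p=3).\n")

rows = []
for name, loader, shape in [
    ("quinolones", fixtures.load_quinolone_predictions, (16, 5)),
    ("sulfonamides", fixtures.load_sulfonamide_predictions, (30, 3)),
]:
    tab = loader()
    worst = {w: float(np.max(np.abs(standardized_residuals(tab.residuals(w)))))
             for w in ("train", "cv", "test")}
    rows.append({
        "model": name,
        "h_star": leverage_threshold(*shape),
        "max_abs_z_cal": round(worst["train"], 3),
        "max_abs_z_cv": round(worst["cv"], 3),
        "max_abs_z_test": round(worst["test"], 3),
    })
ad = pd.DataFrame(rows)
ad.to_csv(OUT / "published_ad_summary.csv", index=False)
print("Applicability-domain summary (h* = 3(p+1)/n and residual extremes):")
print(ad.to_string(index=False))
print("\nh* reproduces both published thresholds (1.125, 0.4) exactly.")
print("Quinolone residuals all sit within +-3 SD; the sulfonamide tables do")
print("NOT support the published no-outlier claim: the 30% acetonitrile rows")
print("of sulfachloropyrazine Na / sulfaclozine reach |z| ~ 3.9-4.0.")
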