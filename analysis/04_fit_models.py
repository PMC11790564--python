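#!/usr/bin/env python
"""Fit the mixed-effects model families over the extracted tables.

Three families, all with per-subject random intercepts on log rCBF:
tissue + location; centred log rVol x location; and per-(location, tissue)
category x session models whose baseline contrasts form the 9-row
growing/new-vs-stagnant table with Benjamini-Hochberg correction.
Writes per-model coefficient CSVs and the contrast table under results/.
"""

from pathlib import Path

import pandas as pd

from wmhperf import pipeline

RESULTS = Path("results")

roi_table = pd.read_csv(RESULTS / "roi_table.csv")
lesion_path = RESULTS / "lesions.csv"
lesion_table = pd.read_csv(lesion_path) if lesion_path.exists() else None

fits = pipeline.fit_all(roi_table, lesion_table)

for name, res in fits.items():
    if hasattr(res, "params"):
        res.params.reset_index(names="term").to_csv(RESULTS / f"model_{name}.csv", index=False)

tl = fits["tissue_location"]
print("tissue x location model (reference NAWM / JV):")
print(tl.params[["estimate", "se", "p"]].round(4).to_string())

if "anova_volume" in fits:
    f_stat, p = fits["anova_volume"]
    print(f"\nANOVA of log WMH volume by location: F = {f_stat:.2f}, p = {p:.3f}")

if "table2" in fits:
    fits["table2"].to_csv(RESULTS / "table2_contrasts.csv", index=False)
    cols = [c for c in ("location", "tissue", "intercept", "growing_diff", "growing_p_corrected") if c in fits["table2"]]
    print("\nbaseline growing-vs-stagnant contrasts by location x tissue:")
    print(fits["table2"][cols].round(4).to_string(index=False))
print("\nnote: this cohort paints no category-dependent perfusion, so the "
      "near-zero growing contrasts are the planted truth; "
      "05_recover_planted_effects.py plants nonzero effects and tests their "
      "recovery at the cohort sizes the estimators are meant for.")
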