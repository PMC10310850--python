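#!/usr/bin/env python
"""Quantify metabolite features by one-point calibration and test FH response.

Converts feature intensities to µM against class-matched internal
standards, then fits concentration ~ exposure per feature at the global,
clinical-background and cell-line levels with BH adjustment.
"""

from pathlib import Path

import pandas as pd

from ffed import metab
from ffed.io import read_sheet

DATA = Path("results/data")
OUT = Path("results/metab")
OUT.mkdir(parents=True, exist_ok=True)

intens = pd.read_csv(DATA / "metab_intensities.csv", index_col=0)
is_map = pd.read_csv(DATA / "metab_is_map.csv")
sheet = read_sheet(DATA / "metab_sheet.csv")
truth = pd.read_csv(DATA / "truth_metab_ratios.csv", index_col=0)["ratio"]

conc = metab.quantify_table(intens, is_map)
conc.to_csv(OUT / "concentrations_um.csv")
print(f"Quantified {conc.shape[0]} features in {conc.shape[1]} samples (µM)")

responsive = set(truth[truth != 1.0].index)
for level in ("global", "background", "cell_line"):
    res = metab.test_metabolites(conc, sheet, level=level)
    res.to_csv(OUT / f"test_{level}.csv")
    sig = res[res["padj"] < 0.05]
    feats = set(sig.index.get_level_values("feature"))
    print(f"{level:11s}: {len(sig)} significant (feature, subset) pairs; "
          f"{len(feats & responsive)}/{len(responsive)} planted FH responders "
          "among them")
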