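"""Internal-standard one-point calibration and per-level metabolite testing.

Direct-infusion ESI-MS intensities are converted to concentrations by
one-point calibration against a class-matched internal standard:
``C = C_IS * (I_metabolite / I_IS)``. Concentrations are then tested per
analysis level — the complete dataset, each clinical background, each
cell line — with an ordinary least-squares fit of
``concentration ~ exposure`` and BH adjustment across features within
each level. Because every intensity is divided by the IS channel of its
own sample, the quantification is invariant to instrument gain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from ffed.simulate import exposure_indicator
from ffed.stats import bh_adjust

__all__ = [
    "quantify_one_point",
    "quantify_table",
    "signal_filter",
    "test_metabolites",
]


def quantify_one_point(i_met: float, i_is: float, c_is: float):
    """One-point calibration: C = C_IS * (I_met / I_IS).

    Returns NaN (feature unquantifiable) when the internal-standard
    intensity is zero.
    """
    i_met = np.asarray(i_met, dtype=float)
    i_is = np.asarray(i_is, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = np.where(i_is > 0, c_is * i_met / i_is, np.nan)
    return conc if conc.shape else float(conc)


def quantify_table(intensities: pd.DataFrame, is_map: pd.DataFrame) -> pd.DataFrame:
    """Quantify every mapped feature against its internal standard.

    ``intensities``: features x samples (IS channels included as rows);
    ``is_map``: columns feature, is_feature, is_concentration_um.
    Returns feature x sample concentrations in µM.
    """
    missing = set(is_map["is_feature"]) - set(intensities.index)
    if missing:
        raise ValueError(f"internal standards absent from the table: {sorted(missing)}")
    rows = {}
    for _, row in is_map.iterrows():
        feat = row["feature"]
        if feat not in intensities.index:
            continue
        rows[feat] = quantify_one_point(
            intensities.loc[feat].to_numpy(dtype=float),
            intensities.loc[row["is_feature"]].to_numpy(dtype=float),
            float(row["is_concentration_um"]),
        )
    return pd.DataFrame(rows, index=intensities.columns).T


def signal_filter(intensities: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Drop features whose median intensity across samples falls below threshold."""
    med = intensities.median(axis=1)
    return intensities[med >= threshold]


def _ols_exposure(conc: np.ndarray, x: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, p, and group means for concentration ~ exposure (0/1)."""
    res = sps.linregress(x.astype(float), conc)
    return (
        float(res.slope),
        float(res.pvalue),
        float(conc[x == 0].mean()),
        float(conc[x == 1].mean()),
    )


def test_metabolites(
    conc: pd.DataFrame,
    sheet: pd.DataFrame,
    level: str = "global",
    factor: str = "FH",
) -> pd.DataFrame:
    """Per-feature OLS exposure test within each subset of the level.

    ``level``: "global" (complete dataset), "background" (one fit per
    clinical background) or "cell_line" (one fit per line). Returns a
    long table (feature, subset, mean_control, mean_treated, effect,
    pvalue, padj) with BH adjustment across features within each subset.
    """
    sheet = sheet.reset_index(drop=True)
    if level == "global":
        subsets = {"all": pd.Series(True, index=sheet.index)}
    elif level == "background":
        subsets = {
            bg: sheet["clinical_background"] == bg
            for bg in sorted(sheet["clinical_background"].unique())
        }
    elif level == "cell_line":
        subsets = {
            ln: sheet["cell_line"] == ln for ln in sorted(sheet["cell_line"].unique())
        }
    else:
        raise ValueError(f"unknown analysis level: {level!r}")

    frames = []
    for name, keep in subsets.items():
        sub_sheet = sheet[keep].reset_index(drop=True)
        x = exposure_indicator(sub_sheet, factor)
        if len(np.unique(x)) < 2:
            raise ValueError(f"exposure constant within subset {name!r}")
        sub = conc[sub_sheet["sample_id"].tolist()]
        rows = []
        for feat, values in sub.iterrows():
            v = values.to_numpy(dtype=float)
            ok = ~np.isnan(v)
            if ok.sum() < 3 or len(np.unique(x[ok])) < 2:
                rows.append({"feature": feat, "subset": name, "mean_control": np.nan,
                             "mean_treated": np.nan, "effect": np.nan, "pvalue": np.nan})
                continue
            slope, p, m0, m1 = _ols_exposure(v[ok], x[ok])
            rows.append({"feature": feat, "subset": name, "mean_control": m0,
                         "mean_treated": m1, "effect": slope, "pvalue": p})
        frame = pd.DataFrame(rows)
        frame["padj"] = bh_adjust(frame["pvalue"].to_numpy())
        frames.append(frame)
    return pd.concat(frames, ignore_index=True).set_index(["feature", "subset"])
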