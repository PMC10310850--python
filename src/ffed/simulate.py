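"""Seeded generators for every input the pipeline consumes.

Each generator emulates the statistical structure of the study's data and
emits a machine-readable ground truth next to it, so downstream stages can
be scored without re-deriving what was planted:

* RNA-seq counts: negative binomial, ``Var = mu + alpha * mu**2``, with a
  mean-dispersion trend ``alpha(mu) = a0/mu + a1``. The per-gene log2 mean
  is baseline + a cell-line offset (drawn with a large SD, so genetic
  background dominates the variance, as in the study's PCA) + sparse
  exposure main effects + aliased interaction effects, all scaled by a
  per-sample library size.
* Exon-bin counts: gene totals multinomially split over bins; switched
  genes move a stated usage fraction from one bin to another under the
  treated level (or in one cell line, to exercise blocking).
* Metabolite features: lognormal intensities with one internal-standard
  channel per lipid class at known concentration; FH-responsive features
  multiplied by a stated fold change in FH-treated samples.
* Spatio-temporal expression: lognormal FPKM-like values over 4 regions x
  8 periods with an additive shift planted in chosen cells, plus RIN
  metadata with a few low values to exercise QC filtering.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_counts",
    "simulate_exon_counts",
    "simulate_metabolites",
    "simulate_spatiotemporal",
    "metab_sample_sheet",
    "exposure_indicator",
    "DEFAULT_REGIONS",
    "DEFAULT_PERIODS",
]

DEFAULT_REGIONS = ["FC", "TC", "HIP", "CBC"]
DEFAULT_PERIODS = [f"P{i}" for i in range(1, 9)]


@dataclass
class SimulationConfig:
    """Knobs for the count simulator; defaults mirror the study's structure."""

    n_genes: int = 2000
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    # dispersion trend alpha(mu) = a0/mu + a1, with lognormal gene noise
    dispersion_a0: float = 2.0
    dispersion_a1: float = 0.05
    dispersion_log_sd: float = 0.2
    cell_line_effect_sd: float = 1.0  # log2 units; dominates exposure effects
    library_size_range: tuple[float, float] = (0.5, 2.0)
    # factor -> {gene_id: log2 fold change (treated vs control)}
    causal_sets: dict = field(default_factory=dict)
    # frozenset({f, g}) -> {gene_id: interaction log2 fold change}
    interaction_effects: dict = field(default_factory=dict)
    seed: int = 0

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class TruthTable:
    """Planted ground truth, zero outside the declared causal sets."""

    gene_effects: pd.DataFrame | None = None  # gene x factor log2FC
    interaction_effects: pd.DataFrame | None = None  # gene x "f:g" log2FC
    exon_switches: pd.DataFrame | None = None  # gene, from_bin, to_bin, fraction, factor
    metabolite_ratios: pd.Series | None = None  # feature -> concentration ratio


def exposure_indicator(sheet: pd.DataFrame, factor: str) -> np.ndarray:
    """0/1 treated indicator for a factor, from the sheet's code column."""
    col = f"{factor}_code"
    if col in sheet.columns:
        return ((sheet[col].to_numpy() + 1) // 2).astype(int)
    levels = sheet[f"{factor}_level"]
    # fall back on label semantics used by the default factor specs
    return levels.isin(["treated", "deprived"]).astype(int).to_numpy()


def _attach_codes(sheet: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """Ensure ±1 code columns exist (derived from level labels if absent)."""
    sheet = sheet.copy()
    for f in factors:
        col = f"{f}_code"
        if col not in sheet.columns:
            treated = sheet[f"{f}_level"].isin(["treated", "deprived"])
            sheet[col] = np.where(treated, 1, -1)
    return sheet


def _sheet_factors(sheet: pd.DataFrame) -> list[str]:
    return [c[: -len("_level")] for c in sheet.columns if c.endswith("_level")]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson mixture: Var = mu + alpha * mu**2."""
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    lam = np.where(
        alpha > 0,
        rng.gamma(np.maximum(1.0 / np.maximum(alpha, 1e-12), 1e-12), mu * alpha),
        mu,
    )
    return rng.poisson(lam)


def simulate_counts(
    config: SimulationConfig, sheet: pd.DataFrame
) -> tuple[pd.DataFrame, TruthTable]:
    """Negative-binomial gene x sample counts for a sample sheet.

    Mean model per gene i, sample j:
    ``mu_ij = s_j * 2 ** (b_i + l_i(line_j) + sum_f x_jf b_if + sum_fg x_jf x_jg g_ifg)``
    with x the 0/1 treated indicator, so a planted effect of 1.0 doubles
    the expected count in treated runs.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    factors = _sheet_factors(sheet)
    n_samples = len(sheet)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    lines = sorted(sheet["cell_line"].unique()) if "cell_line" in sheet else ["line0"]
    line_fx = {
        ln: rng.normal(0.0, config.cell_line_effect_sd, config.n_genes) for ln in lines
    }
    lo, hi = config.library_size_range
    size = rng.uniform(lo, hi, n_samples)

    beta = pd.DataFrame(0.0, index=genes, columns=factors)
    for f, effects in config.causal_sets.items():
        if f in beta.columns:
            for g, b in effects.items():
                beta.loc[g, f] = b
    pair_names = [":".join(sorted(p)) for p in config.interaction_effects]
    gamma = pd.DataFrame(0.0, index=genes, columns=pair_names)
    for pair, effects in config.interaction_effects.items():
        name = ":".join(sorted(pair))
        for g, b in effects.items():
            gamma.loc[g, name] = b

    log2mu = np.tile(baseline[:, None], (1, n_samples))
    if "cell_line" in sheet:
        for j, ln in enumerate(sheet["cell_line"]):
            log2mu[:, j] += line_fx[ln]
    for f in factors:
        x = exposure_indicator(sheet, f)
        log2mu += beta[f].to_numpy()[:, None] * x[None, :]
    for pair in config.interaction_effects:
        fa, fb = sorted(pair)
        if fa in factors and fb in factors:
            x = exposure_indicator(sheet, fa) * exposure_indicator(sheet, fb)
            g = gamma[":".join((fa, fb))].to_numpy()
            log2mu += g[:, None] * x[None, :]

    mu = size[None, :] * 2.0 ** log2mu
    base_mean_count = 2.0 ** baseline
    alpha = (config.dispersion_a0 / base_mean_count + config.dispersion_a1) * np.exp(
        rng.normal(0.0, config.dispersion_log_sd, config.n_genes)
    )
    counts = _nb_draw(rng, mu, alpha[:, None])

    counts_df = pd.DataFrame(counts, index=genes, columns=sheet["sample_id"].tolist())
    truth = TruthTable(gene_effects=beta, interaction_effects=gamma)
    return counts_df, truth


def simulate_exon_counts(
    config: SimulationConfig,
    sheet: pd.DataFrame,
    n_bins: int = 4,
    switch_genes: list[str] | None = None,
    switch_factor: str = "BPA",
    switch_fraction: float = 0.25,
    line_switch_genes: list[str] | None = None,
    line_switch_line: str | None = None,
) -> tuple[pd.DataFrame, TruthTable]:
    """Exon-bin counts: gene totals multinomially split over bins.

    Switched genes move ``switch_fraction`` of their reads from bin 1 to
    bin 2 in samples treated with ``switch_factor``; ``line_switch_genes``
    instead switch in every sample of one cell line (an exposure-unrelated
    isoform difference, used to check that blocking absorbs it).
    """
    totals, _ = simulate_counts(config, sheet)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    genes = list(totals.index)
    switch_genes = list(switch_genes or [])
    line_switch_genes = list(line_switch_genes or [])

    base_props = rng.dirichlet(np.full(n_bins, 5.0), size=len(genes))
    x_treat = (
        exposure_indicator(sheet, switch_factor)
        if f"{switch_factor}_level" in sheet.columns or f"{switch_factor}_code" in sheet.columns
        else np.zeros(len(sheet), dtype=int)
    )
    in_line = (
        (sheet["cell_line"] == line_switch_line).to_numpy()
        if line_switch_line is not None
        else np.zeros(len(sheet), dtype=bool)
    )

    rows, index = [], []
    for gi, g in enumerate(genes):
        props = base_props[gi]
        switched_props = props.copy()
        if n_bins >= 2:
            moved = min(switch_fraction, props[0])
            switched_props[0] -= moved
            switched_props[1] += moved
        mat = np.zeros((n_bins, len(sheet)), dtype=int)
        for j in range(len(sheet)):
            use = props
            if (g in switch_genes and x_treat[j] == 1) or (
                g in line_switch_genes and in_line[j]
            ):
                use = switched_props
            mat[:, j] = rng.multinomial(totals.iloc[gi, j], use)
        for b in range(n_bins):
            index.append((g, f"{g}:E{b + 1:03d}"))
            rows.append(mat[b])

    bins_df = pd.DataFrame(
        np.vstack(rows),
        index=pd.MultiIndex.from_tuples(index, names=["gene", "bin"]),
        columns=totals.columns,
    )
    switches = pd.DataFrame(
        [
            {
                "gene": g,
                "from_bin": f"{g}:E001",
                "to_bin": f"{g}:E002",
                "fraction": switch_fraction,
                "factor": switch_factor if g in switch_genes else f"line:{line_switch_line}",
            }
            for g in switch_genes + line_switch_genes
        ],
        columns=["gene", "from_bin", "to_bin", "fraction", "factor"],
    )
    return bins_df, TruthTable(exon_switches=switches)


def metab_sample_sheet(n_replicates: int = 3) -> pd.DataFrame:
    """The ESI-MS layout: treated/untreated FH x 4 cell lines x 3 technical
    replicates (N = 24)."""
    lines = [
        ("CTRL_Male", "Non-ASD"),
        ("CTRL_Female", "Non-ASD"),
        ("ASD_HNRNPU", "ASD"),
        ("ASD_CASK", "ASD"),
    ]
    rows = []
    for name, bg in lines:
        for code, label in ((-1, "control"), (1, "treated")):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{name}_FH{'pos' if code == 1 else 'neg'}_t{rep}",
                        "cell_line": name,
                        "clinical_background": bg,
                        "replicate": rep,
                        "FH_level": label,
                        "FH_code": code,
                    }
                )
    return pd.DataFrame(rows)


def simulate_metabolites(
    config: SimulationConfig,
    sheet: pd.DataFrame | None = None,
    n_features_per_class: int = 8,
    classes: tuple[str, ...] = ("FA", "PC", "PE", "TG"),
    is_concentration_um: float = 2.0,
    responsive_fold: float = 1.5,
    n_responsive: int = 5,
    noise_log_sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Lognormal feature intensities with internal standards.

    Returns (intensities, is_map, truth). One IS channel per lipid class
    at a fixed known concentration; the first ``n_responsive`` features of
    the first class are multiplied by ``responsive_fold`` in FH-treated
    samples.
    """
    if sheet is None:
        sheet = metab_sample_sheet()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    x = exposure_indicator(sheet, "FH")

    features, is_rows = [], []
    for cls in classes:
        is_id = f"IS_{cls}"
        for i in range(1, n_features_per_class + 1):
            fid = f"{cls} {14 + 2 * i}:{i % 3}"
            features.append((fid, cls))
            is_rows.append({"feature": fid, "is_feature": is_id, "is_concentration_um": is_concentration_um})
    is_map = pd.DataFrame(is_rows)

    base = rng.lognormal(mean=np.log(5e4), sigma=0.8, size=len(features))
    responsive = [f for f, cls in features if cls == classes[0]][:n_responsive]
    intens = {}
    for (fid, cls), b in zip(features, base):
        fold = np.where(x == 1, responsive_fold, 1.0) if fid in responsive else 1.0
        intens[fid] = b * fold * rng.lognormal(0.0, noise_log_sd, len(sheet))
    for cls in classes:
        intens[f"IS_{cls}"] = 1e5 * rng.lognormal(0.0, noise_log_sd / 2, len(sheet))

    table = pd.DataFrame(intens, index=sheet["sample_id"].tolist()).T
    ratios = pd.Series(1.0, index=[f for f, _ in features])
    ratios[responsive] = responsive_fold
    return table, is_map, TruthTable(metabolite_ratios=ratios)


def simulate_spatiotemporal(
    n_genes: int = 500,
    regions: list[str] | None = None,
    periods: list[str] | None = None,
    enriched_group: tuple | None = None,
    n_replicates: int = 3,
    low_rin_frac: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM-like expression over region x period with a planted shift.

    ``enriched_group`` = (genes, regions, periods, shift): the listed
    genes gain ``shift`` FPKM units in every sample of the listed cells.
    RIN is drawn so that about ``low_rin_frac`` of samples fall below 9.
    """
    regions = regions or list(DEFAULT_REGIONS)
    periods = periods or list(DEFAULT_PERIODS)
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]

    meta_rows = []
    for r in regions:
        for p in periods:
            for k in range(1, n_replicates + 1):
                meta_rows.append({"sample_id": f"{r}_{p}_s{k}", "region": r, "period": p})
    meta = pd.DataFrame(meta_rows)
    meta["RIN"] = np.where(
        rng.uniform(size=len(meta)) < low_rin_frac,
        rng.uniform(7.0, 9.0, len(meta)),
        rng.uniform(9.0, 10.0, len(meta)),
    ).round(2)

    gene_scale = rng.lognormal(mean=1.0, sigma=0.4, size=n_genes)
    expr = gene_scale[:, None] * rng.lognormal(0.0, 0.3, (n_genes, len(meta)))
    if enriched_group is not None:
        g_list, r_list, p_list, shift = enriched_group
        gi = [genes.index(g) for g in g_list]
        mask = meta["region"].isin(r_list).to_numpy() & meta["period"].isin(p_list).to_numpy()
        expr[np.ix_(gi, np.where(mask)[0])] += shift
    expr_df = pd.DataFrame(expr, index=genes, columns=meta["sample_id"].tolist())
    return expr_df, meta
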