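"""Negative-binomial GLM differential expression at four stratification levels.

The study's analysis is stratified: Level I tests an exposure's main
effect across all cell lines; Level II restricts to one clinical
background (ASD or Non-ASD); Level III to one cell line (model
``~ exposure``); Level IV tests an aliased two-factor interaction under
``~ cell_line + replicate + interaction + cell_line:interaction``. Each
level yields a per-gene Wald test with Benjamini-Hochberg adjustment at
adj. p < 0.05.

The fitting pipeline is a deliberately compact NB-Wald stack: a
median-of-ratios size factor, a method-of-moments dispersion shrunk
toward a fitted mean-dispersion trend, and an IRLS log-link NB GLM. It
preserves the inferential contract (NB GLM + Wald + BH) without the
Cox-Reid adjustment or MAP fold-change shrinkage found in heavier count
packages; exact numeric parity with those is a non-goal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ffed.simulate import exposure_indicator
from ffed.stats import bh_adjust

__all__ = [
    "RankDeficiencyError",
    "size_factors",
    "estimate_dispersion",
    "fit_glm",
    "run_level",
    "GLMFit",
]

MIN_DISPERSION = 1e-8
MAX_DISPERSION = 10.0
LN2 = np.log(2.0)


class RankDeficiencyError(ValueError):
    """The model matrix is not full column rank — aliased contrasts surface here."""


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean reference.

    Genes with any zero count drop out of the reference (their geometric
    mean is zero); if no gene is expressed everywhere, the estimator
    falls back to the subset of positive counts per sample, with a
    warning.
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log = np.log(mat)
    all_positive = np.isfinite(log).all(axis=1)
    if all_positive.any():
        ref = log[all_positive].mean(axis=1)
        ratios = log[all_positive] - ref[:, None]
        s = np.exp(np.median(ratios, axis=0))
    else:
        warnings.warn(
            "no gene expressed in all samples; using positive-count subset per sample"
        )
        s = np.ones(mat.shape[1])
        for j in range(mat.shape[1]):
            pos = mat[:, j] > 0
            if pos.any():
                ref = np.where(np.isfinite(log[pos]).all(axis=1), log[pos].mean(axis=1), 0.0)
                s[j] = np.exp(np.median(log[pos, j] - ref))
    return pd.Series(s, index=counts.columns, name="size_factor")


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat) == mat.shape[1]:
        return
    # name the offending columns: those that do not raise the rank
    collinear, kept = [], []
    for name in X.columns:
        trial = kept + [name]
        if np.linalg.matrix_rank(X[trial].to_numpy(dtype=float)) == len(trial):
            kept.append(name)
        else:
            collinear.append(name)
    raise RankDeficiencyError(
        f"model matrix is rank deficient; collinear terms: {collinear}"
    )


def estimate_dispersion(
    counts: pd.DataFrame,
    model_matrix: pd.DataFrame,
    size: pd.Series | None = None,
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion (Var = mu + alpha mu^2) by method of moments.

    Raw estimate: residual variance of size-factor-normalized counts
    around an OLS fit of the model matrix, residual-df corrected, minus
    the Poisson part. The raw values are then shrunk on the log scale
    (weight ``shrink_weight`` on the gene, the rest on the trend) toward
    a fitted mean-dispersion trend ``alpha(mu) = a0/mu + a1``, and
    floored at 1e-8.
    """
    if size is None:
        size = size_factors(counts)
    s = size.to_numpy(dtype=float)
    q = counts.to_numpy(dtype=float) / s[None, :]
    X = model_matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more samples than model coefficients")
    hat, *_ = np.linalg.lstsq(X, q.T, rcond=None)
    fitted = np.maximum((X @ hat).T, 1e-8)
    # E[(q - mu)^2] = mu/s + alpha mu^2 per sample; df-corrected moment match
    resid_ss = ((q - fitted) ** 2).sum(axis=1) * (n / (n - p))
    poisson_part = (fitted / s[None, :]).sum(axis=1)
    mu_bar = q.mean(axis=1)
    denom = (fitted**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (resid_ss - poisson_part) / denom
    raw = np.clip(np.nan_to_num(raw, nan=MIN_DISPERSION), MIN_DISPERSION, MAX_DISPERSION)

    # mean-dispersion trend alpha(mu) = a0/mu + a1, least squares on informative genes
    ok = mu_bar > 0
    A = np.column_stack([1.0 / mu_bar[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(A, raw[ok], rcond=None)
    a0, a1 = np.maximum(coef, 0.0)
    with np.errstate(divide="ignore"):
        trend = np.where(mu_bar > 0, a0 / np.maximum(mu_bar, 1e-12) + a1, a1)
    trend = np.clip(trend, MIN_DISPERSION, MAX_DISPERSION)
    shrunk = np.exp(
        shrink_weight * np.log(raw) + (1.0 - shrink_weight) * np.log(trend)
    )
    return pd.Series(np.clip(shrunk, MIN_DISPERSION, MAX_DISPERSION),
                     index=counts.index, name="dispersion")


@dataclass
class GLMFit:
    """Per-gene IRLS result on the natural-log scale."""

    coef: np.ndarray  # genes x p
    cov: np.ndarray  # genes x p x p
    converged: np.ndarray  # bool per gene
    testable: np.ndarray  # bool per gene (False for all-zero genes)


def _irls_single(
    y: np.ndarray,
    X: np.ndarray,
    alpha: float,
    offset: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool]:
    n, p = X.shape
    with np.errstate(divide="ignore"):
        init = np.log(np.maximum(y, 0.5)) - offset
    beta, *_ = np.linalg.lstsq(X, init, rcond=None)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    eta = np.clip(X @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.pinv(info)
    return beta, cov, converged


def fit_glm(
    counts: pd.DataFrame,
    model_matrix: pd.DataFrame,
    dispersions: pd.Series,
    size: pd.Series,
) -> GLMFit:
    """Log-link NB GLM per gene by IRLS with ``log(size factor)`` offset.

    Convergence: max absolute coefficient change < 1e-6 within 100
    iterations; non-convergence is flagged, not fatal. All-zero genes are
    flagged untestable with zero coefficients. A rank-deficient model
    matrix raises :class:`RankDeficiencyError` naming the collinear
    terms — this is how aliased contrasts surface.
    """
    _check_full_rank(model_matrix)
    X = model_matrix.to_numpy(dtype=float)
    offset = np.log(size.to_numpy(dtype=float))
    mat = counts.to_numpy(dtype=float)
    n_genes, p = mat.shape[0], X.shape[1]
    coef = np.zeros((n_genes, p))
    cov = np.zeros((n_genes, p, p))
    converged = np.zeros(n_genes, dtype=bool)
    testable = mat.sum(axis=1) > 0
    alphas = dispersions.to_numpy(dtype=float)
    for i in range(n_genes):
        if not testable[i]:
            continue
        coef[i], cov[i], converged[i] = _irls_single(mat[i], X, alphas[i], offset)
    return GLMFit(coef=coef, cov=cov, converged=converged, testable=testable)


def _model_matrix(
    sheet: pd.DataFrame,
    level: str,
    factor,
    include_blocking: bool = False,
) -> tuple[pd.DataFrame, str]:
    """Build the level's design matrix; returns (matrix, tested column)."""
    n = len(sheet)
    if level in ("I", "II", "III"):
        x = exposure_indicator(sheet, factor)
        cols = {"intercept": np.ones(n), "exposure": x.astype(float)}
        if include_blocking and level in ("I", "II"):
            lines = sorted(sheet["cell_line"].unique())
            for ln in lines[1:]:
                cols[f"line[{ln}]"] = (sheet["cell_line"] == ln).astype(float).to_numpy()
        return pd.DataFrame(cols, index=sheet.index), "exposure"
    if level == "IV":
        fa, fb = sorted(factor)
        inter = (exposure_indicator(sheet, fa) * exposure_indicator(sheet, fb)).astype(float)
        cols = {"intercept": np.ones(n)}
        lines = sorted(sheet["cell_line"].unique())
        for ln in lines[1:]:
            cols[f"line[{ln}]"] = (sheet["cell_line"] == ln).astype(float).to_numpy()
        reps = sorted(sheet["replicate"].unique())
        if len(reps) < 2:
            raise RankDeficiencyError(
                "model matrix is rank deficient; collinear terms: ['replicate'] "
                "(single replicate level — the interaction model is not estimable)"
            )
        for r in reps[1:]:
            cols[f"replicate[{r}]"] = (sheet["replicate"] == r).astype(float).to_numpy()
        cols["interaction"] = inter
        for ln in lines[1:]:
            cols[f"line[{ln}]:interaction"] = cols[f"line[{ln}]"] * inter
        return pd.DataFrame(cols, index=sheet.index), "interaction"
    raise ValueError(f"unknown analysis level: {level!r}")


def run_level(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    level: str,
    factor,
    background: str | None = None,
    cell_line: str | None = None,
    include_blocking: bool = False,
    min_base_mean: float = 5.0,
) -> pd.DataFrame:
    """One stratified differential-expression contrast.

    Level I uses every sample; Level II the samples of one clinical
    background; Level III one cell line (``~ exposure``); Level IV tests
    the interaction coefficient of an aliased factor pair. Genes below
    ``min_base_mean`` normalized mean counts are excluded before BH
    adjustment (independent filtering); their ``padj`` is NaN.

    Returns a table with columns gene, baseMean, log2FoldChange, lfcSE,
    stat, pvalue, padj, dispersion, converged.
    """
    sheet = sheet.reset_index(drop=True)
    if level == "II":
        if background not in ("ASD", "Non-ASD"):
            raise ValueError("level II requires background 'ASD' or 'Non-ASD'")
        keep = sheet["clinical_background"] == background
    elif level == "III":
        if cell_line is None:
            raise ValueError("level III requires a cell line")
        keep = sheet["cell_line"] == cell_line
    elif level == "IV" and background is not None:
        keep = sheet["clinical_background"] == background
    else:
        keep = pd.Series(True, index=sheet.index)
    sub_sheet = sheet[keep].reset_index(drop=True)
    if sub_sheet.empty:
        raise ValueError("analysis subset is empty")
    sub = counts[sub_sheet["sample_id"].tolist()]

    X, test_col = _model_matrix(sub_sheet, level, factor, include_blocking)
    if level != "IV":
        x = X["exposure"]
        if x.nunique() < 2:
            raise ValueError("exposure is constant within the analysed subset")

    s = size_factors(sub)
    disp = estimate_dispersion(sub, X, s)
    fit = fit_glm(sub, X, disp, s)

    j = list(X.columns).index(test_col)
    beta_ln = fit.coef[:, j]
    se_ln = np.sqrt(np.maximum(fit.cov[:, j, j], 0.0))
    log2fc = beta_ln / LN2
    se2 = se_ln / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se_ln > 0, beta_ln / se_ln, 0.0)
    pvalue = 2.0 * sps.norm.sf(np.abs(stat))
    pvalue[~fit.testable] = np.nan

    base_mean = (sub.to_numpy(dtype=float) / s.to_numpy()[None, :]).mean(axis=1)
    p_for_adjust = np.where(base_mean >= min_base_mean, pvalue, np.nan)
    padj = bh_adjust(p_for_adjust)

    return pd.DataFrame(
        {
            "gene": counts.index,
            "baseMean": base_mean,
            "log2FoldChange": np.where(fit.testable, log2fc, 0.0),
            "lfcSE": se2,
            "stat": np.where(fit.testable, stat, 0.0),
            "pvalue": pvalue,
            "padj": padj,
            "dispersion": disp.to_numpy(),
            "converged": fit.converged,
        }
    ).set_index("gene")
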