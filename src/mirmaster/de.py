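"""Negative-binomial differential expression for count matrices.

A compact NB(mean mu, dispersion alpha) log-link GLM core: median-of-
ratios size factors, method-of-moments dispersion with a 1/mean trend
and log-space shrinkage, per-gene Wald tests under a fixed-effect
design (typically ``~ batch + condition``), and Benjamini-Hochberg
adjustment.  The contract is statistical calibration (null p-values
approximately uniform, unbiased fold-change recovery), not numerical
equality with any particular external tool.

Counts are pandas DataFrames (features x samples); designs are built
from a sample sheet with treatment (reference-level) coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
ALPHA_FLOOR = 1e-8
#: gene-wise dispersion is winsorized to trend/RATIO .. trend*RATIO before
#: log-space averaging, so a handful of degenerate moment estimates cannot
#: dominate the shrunken value at small replicate numbers
DISP_WINSOR_RATIO = 8.0
#: the gene-wise weight in the log-space combination is df/(df + DISP_PRIOR_DF):
#: a few residual degrees of freedom lean on the trend, many trust the gene
DISP_PRIOR_DF = 20.0

VALID_TERMS = ("batch", "condition", "assay", "assay:condition")


@dataclass(frozen=True)
class DesignSpec:
    """Model formula terms plus the tested contrast.

    ``formula`` is a subset of {batch, condition, assay,
    assay:condition}; ``contrast`` is (factor, levelA, levelB) and is
    reported as levelA vs levelB (positive log2fc = higher in levelA).
    """

    formula: tuple[str, ...]
    contrast: tuple[str, str, str]

    def __post_init__(self) -> None:
        bad = set(self.formula) - set(VALID_TERMS)
        if bad:
            raise ValueError(f"unknown design term(s): {sorted(bad)}")
        if "condition" not in self.formula:
            raise ValueError("design must include 'condition'")
        if "assay:condition" in self.formula and "assay" not in self.formula:
            raise ValueError("interaction requires the 'assay' main effect")


def size_factors(counts: pd.DataFrame, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    The reference is the per-gene geometric mean over samples; each
    sample's factor is the median ratio to that reference across genes
    positive in every sample.  With no such gene, an optional fallback
    uses a +0.5 pseudo-reference on the geometric-mean (mean-of-log)
    scale.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.ndim != 2 or mat.shape[1] == 0:
        raise ValueError("counts must be a features x samples matrix")
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        if not allow_pseudo_reference:
            raise ValueError(
                "no gene has positive counts in every sample; enable the "
                "pseudo-reference (mean-of-log) fallback"
            )
        mat = mat + 0.5
        all_pos = np.ones(mat.shape[0], dtype=bool)
    logm = np.log(mat[all_pos])
    log_geomean = logm.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logm - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def design_matrix(
    metadata: pd.DataFrame,
    terms: Sequence[str],
    references: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix with treatment coding.

    One intercept column plus indicator columns for every non-reference
    level of each factor term; ``assay:condition`` adds products of the
    corresponding indicators.  Constant factors are dropped with a log
    message (e.g. a single-batch comparison reduces to ``~ condition``).
    """
    references = references or {}
    cols: list[np.ndarray] = [np.ones(len(metadata))]
    names: list[str] = ["intercept"]
    main_dummies: dict[str, dict[str, np.ndarray]] = {}
    for term in terms:
        if ":" in term:
            continue
        levels = sorted(metadata[term].astype(str).unique())
        if len(levels) < 2:
            logger.info("design: dropping constant factor %r", term)
            main_dummies[term] = {}
            continue
        ref = references.get(term, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from factor {term!r}")
        dummies = {}
        for lev in levels:
            if lev == ref:
                continue
            ind = (metadata[term].astype(str) == lev).to_numpy(dtype=float)
            dummies[lev] = ind
            cols.append(ind)
            names.append(f"{term}_{lev}")
        main_dummies[term] = dummies
    for term in terms:
        if ":" not in term:
            continue
        f1, f2 = term.split(":")
        for lev1, d1 in main_dummies.get(f1, {}).items():
            for lev2, d2 in main_dummies.get(f2, {}).items():
                cols.append(d1 * d2)
                names.append(f"{f1}_{lev1}:{f2}_{lev2}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not full rank")
    return X, names


def _design_cells(metadata: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    factors = sorted({f for t in terms for f in t.split(":")})
    keys = metadata[factors].astype(str).agg("|".join, axis=1)
    return pd.factorize(keys)[0]


def estimate_dispersion(
    counts: pd.DataFrame,
    sf: pd.Series,
    cells: np.ndarray,
    shrink_weight: float | None = None,
) -> pd.DataFrame:
    """Per-gene NB dispersion: moments within design cells, trend, shrinkage.

    Gene-wise estimate: within each design cell with >= 2 replicates,
    alpha_c = (var(q) - xi*mean(q)) / mean(q)^2 on normalized counts
    q = y/s with xi = mean(1/s) (the Poisson part scaled for unequal
    depth); pooled across cells with df weights and floored at 1e-8.
    Trend: least squares of alpha ~ a0 + a1/mean over genes with
    normalized mean > 1.  Final: geometric interpolation between the
    winsorized gene-wise value and the trend with gene-wise weight
    df/(df + 20) unless ``shrink_weight`` is given — moment estimates
    from a handful of replicates are noisy enough to destroy Wald
    calibration if trusted, so low-df fits lean on the trend.  All-zero
    genes get NA and are excluded from testing.
    """
    y = counts.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    q = y / s
    G = y.shape[0]
    num = np.zeros(G)
    den = np.zeros(G)
    base_mean = q.mean(axis=1)
    for c in np.unique(cells):
        idx = np.flatnonzero(cells == c)
        if len(idx) < 2:
            continue
        qc = q[:, idx]
        m = qc.mean(axis=1)
        v = qc.var(axis=1, ddof=1)
        xi = np.mean(1.0 / s[idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - xi * m) / np.square(m)
        ok = m > 0
        w = len(idx) - 1
        num[ok] += w * a[ok]
        den[ok] += w
    alpha_gw = np.full(G, np.nan)
    tested = den > 0
    alpha_gw[tested] = np.maximum(num[tested] / den[tested], ALPHA_FLOOR)
    # mean-dispersion trend on informative genes
    fit_mask = tested & (base_mean > 1.0)
    if fit_mask.sum() >= 2:
        A = np.column_stack([np.ones(fit_mask.sum()), 1.0 / base_mean[fit_mask]])
        coef, *_ = np.linalg.lstsq(A, alpha_gw[fit_mask], rcond=None)
        a0, a1 = coef
    else:
        a0, a1 = (np.nanmedian(alpha_gw[tested]) if tested.any() else 0.1), 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_trend = np.maximum(a0 + a1 / base_mean, ALPHA_FLOOR)
    alpha_trend[~tested] = np.nan
    if shrink_weight is None:
        total_df = sum(
            max(0, np.sum(cells == c) - 1) for c in np.unique(cells)
        )
        shrink_weight = total_df / (total_df + DISP_PRIOR_DF)
    gw_wins = np.clip(alpha_gw, alpha_trend / DISP_WINSOR_RATIO, alpha_trend * DISP_WINSOR_RATIO)
    alpha_final = np.exp(
        shrink_weight * np.log(gw_wins) + (1.0 - shrink_weight) * np.log(alpha_trend)
    )
    return pd.DataFrame(
        {"alpha_gw": alpha_gw, "alpha_trend": alpha_trend, "alpha_final": alpha_final},
        index=counts.index,
    )


def _irls_nb(
    y: np.ndarray,
    alpha: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for NB log-link GLMs with fixed per-gene dispersion.

    Returns (beta (G,p), se (G,p), converged (G,)).
    """
    G, n = y.shape
    p = X.shape[1]
    mu = np.maximum(y, 0.0) + 0.5
    eta = np.log(mu)
    beta = np.zeros((G, p))
    converged = np.zeros(G, dtype=bool)
    XtWX = np.empty((G, p, p))
    ridge = 1e-10 * np.eye(p)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        W = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset) + (y - mu) / mu
        XtWX = np.einsum("gn,ni,nj->gij", W, X, X) + ridge
        XtWz = np.einsum("gn,gn,ni->gi", W, z, X)
        beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        step = np.abs(beta_new - beta).max(axis=1)
        converged |= step < tol
        beta = beta_new
        eta = np.clip(beta @ X.T, -30.0, 30.0) + offset
        mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("gn,ni,nj->gij", W, X, X) + ridge
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(np.maximum(np.einsum("gii->gi", cov), 0.0))
    return beta, se, converged


def nb_wald(
    counts: pd.DataFrame,
    sf: pd.Series,
    dispersions: pd.DataFrame,
    X: np.ndarray,
    coef_names: list[str],
    coef: str,
    cells: np.ndarray | None = None,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Per-gene NB Wald test for one design coefficient.

    Fits every gene's NB GLM (log link, size-factor offset, dispersion
    fixed at ``alpha_final``) and tests ``coef = 0`` with a two-sided
    normal tail.  Genes with an all-zero design cell are refit with a
    +0.5 pseudocount (separation guard) and flagged; non-converged
    genes and all-zero genes get NA p-values.
    """
    y = counts.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    offset = np.log(s)
    alpha = dispersions["alpha_final"].to_numpy(dtype=float)
    coef_idx = coef_names.index(coef)
    G = y.shape[0]
    base_mean = (y / s).mean(axis=1)

    testable = ~np.isnan(alpha)
    log2fc = np.full(G, np.nan)
    se_out = np.full(G, np.nan)
    wald = np.full(G, np.nan)
    pval = np.full(G, np.nan)
    flagged = np.zeros(G, dtype=bool)
    if testable.any():
        yt = y[testable].copy()
        if cells is not None:
            # separation guard: a design cell with all zeros sends the MLE to -inf
            for c in np.unique(cells):
                idx = np.flatnonzero(cells == c)
                sep = (yt[:, idx] == 0).all(axis=1)
                if sep.any():
                    yt[sep] += 0.5
                    flagged[np.flatnonzero(testable)[sep]] = True
        beta, se, conv = _irls_nb(yt, alpha[testable], X, offset, max_iter=max_iter)
        b = beta[:, coef_idx]
        e = se[:, coef_idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            w = b / e
        pv = 2.0 * stats.norm.sf(np.abs(w))
        pv[~conv] = np.nan
        ti = np.flatnonzero(testable)
        log2fc[ti] = b / LN2
        se_out[ti] = e / LN2
        wald[ti] = w
        pval[ti] = pv
        flagged[ti[~conv]] = True
    res = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": log2fc,
            "se": se_out,
            "wald": wald,
            "p": pval,
            "padj": bh_adjust(pval),
            "flagged": flagged,
        },
        index=counts.index,
    )
    res.index.name = "gene_id"
    return res


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NA entries are excluded from the test count m and stay NA; output
    is capped at 1 with cumulative-minimum monotonicity enforced.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[valid] = restored
    return out


def significant_features(
    results: pd.DataFrame,
    padj_max: float = 0.05,
    abs_lfc_min: float = 0.5,
    basemean_min: float = 500.0,
) -> tuple[list[str], list[str]]:
    """Split results into up/down feature lists at strict thresholds.

    All inequalities strict: padj < padj_max, |log2fc| > abs_lfc_min,
    baseMean > basemean_min.
    """
    ok = (results["padj"] < padj_max) & (results["baseMean"] > basemean_min)
    up = results.index[ok & (results["log2fc"] > abs_lfc_min)].tolist()
    down = results.index[ok & (results["log2fc"] < -abs_lfc_min)].tolist()
    return up, down


def run_de(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    design: DesignSpec,
    allow_pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Full DE pass for one contrast: normalize, disperse, test, adjust.

    The contrast's level B is the design reference, so the reported
    log2fc is levelA vs levelB.  Samples are subset to the two contrast
    levels; constant factors (e.g. one batch) drop out of the design.
    """
    factor, level_a, level_b = design.contrast
    if factor != "condition":
        raise ValueError("run_de tests condition contrasts; use ptr for interactions")
    meta = metadata.set_index("sample").loc[list(counts.columns)].reset_index()
    keep = meta["condition"].isin([level_a, level_b])
    meta = meta.loc[keep].reset_index(drop=True)
    sub = counts[meta["sample"]]
    sf = size_factors(sub, allow_pseudo_reference=allow_pseudo_reference)
    if level_a == level_b:
        base_mean = (sub.to_numpy(dtype=float) / sf.to_numpy()).mean(axis=1)
        res = pd.DataFrame(
            {"baseMean": base_mean, "log2fc": 0.0, "se": np.nan, "wald": 0.0,
             "p": 1.0, "padj": 1.0, "flagged": False},
            index=sub.index,
        )
        res.index.name = "gene_id"
        return res
    terms = [t for t in design.formula if t in ("batch", "condition")]
    X, names = design_matrix(meta, terms, references={"condition": level_b})
    cells = _design_cells(meta, terms)
    disp = estimate_dispersion(sub, sf, cells)
    return nb_wald(sub, sf, disp, X, names, f"condition_{level_a}", cells=cells)


def qc_transform_and_pca(
    counts: pd.DataFrame,
    sf: pd.Series,
    batch: pd.Series | None = None,
    n_pcs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2(normalized+1) transform, optional batch-mean removal, PCA, Pearson r.

    Batch removal subtracts per-gene batch means (re-centred on the
    grand mean).  PCA uses SVD of the gene-centred matrix with a
    deterministic sign convention: the gene with the largest |loading|
    on each component is given a positive loading.  Returns
    (sample coordinates, sample-pair Pearson correlation matrix).
    """
    t = np.log2(counts.to_numpy(dtype=float) / sf.to_numpy() + 1.0)
    if batch is not None:
        b = np.asarray(batch.astype(str))
        grand = t.mean(axis=1, keepdims=True)
        adj = t.copy()
        for lev in np.unique(b):
            idx = np.flatnonzero(b == lev)
            adj[:, idx] = t[:, idx] - t[:, idx].mean(axis=1, keepdims=True) + grand
        t = adj
    corr = pd.DataFrame(np.corrcoef(t, rowvar=False), index=counts.columns, columns=counts.columns)
    centered = (t - t.mean(axis=1, keepdims=True)).T  # samples x genes
    k = min(n_pcs, centered.shape[0], centered.shape[1])
    u, sv, vt = np.linalg.svd(centered, full_matrices=False)
    u, sv, vt = u[:, :k], sv[:k], vt[:k]
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    coords = pd.DataFrame(u * sv, index=counts.columns,
                          columns=[f"PC{i + 1}" for i in range(k)])
    return coords, corr
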