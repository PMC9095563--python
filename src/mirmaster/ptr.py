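"""Transcriptional vs post-transcriptional integration (GPS/LPS calls).

Nascent transcription (run-on signal over gene bodies) and steady-state
mRNA (RNA-seq) measure different layers of regulation: a gene whose
mRNA falls while its transcription is flat has gained post-
transcriptional suppression (GPS); the mirror case has lost it (LPS).
The integration is a joint NB fit over both assays with an
assay x condition interaction: the interaction coefficient is the
difference between the steady-state and transcriptional responses, and
its Wald test supplies the per-gene post-transcriptional p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import de

logger = logging.getLogger(__name__)

CATEGORIES = ("GPS", "LPS", "transcriptional", "unchanged", "untestable")

#: classification thresholds: the PTR screen is deliberately permissive
#: (padj 0.2) while the transcriptional call uses the stricter DE cutoffs
PTR_PADJ = 0.2
PTR_BASEMEAN = 100.0
PTR_ABS_LFC = 0.5
TRANSCRIPTIONAL_PADJ = 0.05
TRANSCRIPTIONAL_ABS_LFC = 0.5


def two_factor_test(
    rna_counts: pd.DataFrame,
    chro_counts: pd.DataFrame,
    metadata: pd.DataFrame,
    condition_a: str,
    condition_b: str,
) -> pd.DataFrame:
    """Joint two-assay NB fit; Wald test on the assay:condition interaction.

    Samples of both assays for the two conditions are concatenated;
    the design is ``~ assay + condition + assay:condition`` (plus batch
    when both assays carry more than one batch).  Size factors are
    computed within assay because sequencing depth is not comparable
    across assays.  The reference assay is the transcriptional one, so
    the interaction coefficient estimates (steady-state effect) minus
    (transcriptional effect).  Returns per-gene interaction log2fc,
    p and BH padj; genes absent or all-zero in either assay are NA
    (untestable).
    """
    shared = rna_counts.index.intersection(chro_counts.index)
    meta = metadata[metadata["condition"].isin([condition_a, condition_b])
                    & metadata["assay"].isin(["rna", "chro"])].reset_index(drop=True)
    rna_samples = meta.loc[meta["assay"] == "rna", "sample"].tolist()
    chro_samples = meta.loc[meta["assay"] == "chro", "sample"].tolist()
    if not rna_samples or not chro_samples:
        raise ValueError("both assays must have samples for the contrast")
    rna = rna_counts.loc[shared, rna_samples]
    chro = chro_counts.loc[shared, chro_samples]
    sf = pd.concat([de.size_factors(rna, allow_pseudo_reference=True),
                    de.size_factors(chro, allow_pseudo_reference=True)])
    joint = pd.concat([rna, chro], axis=1)
    meta = meta.set_index("sample").loc[joint.columns].reset_index()
    terms = ["assay", "condition", "assay:condition"]
    batch_in_both = (meta.groupby("assay")["batch"].nunique() > 1).all()
    if batch_in_both:
        terms = ["batch"] + terms
    X, names = de.design_matrix(
        meta, terms, references={"assay": "chro", "condition": condition_b}
    )
    cells = de._design_cells(meta, ["assay", "condition"])
    disp = de.estimate_dispersion(joint, sf, cells)
    # a gene all-zero within one assay has no within-assay information:
    # mark untestable rather than leaning on the pseudocount refit
    zero_one_assay = (rna.sum(axis=1) == 0) | (chro.sum(axis=1) == 0)
    disp.loc[zero_one_assay, "alpha_final"] = np.nan
    coef = f"assay_rna:condition_{condition_a}"
    res = de.nb_wald(joint, sf, disp, X, names, coef, cells=cells)
    out = res.rename(columns={"log2fc": "interaction_log2fc",
                              "p": "interaction_p", "padj": "interaction_padj"})
    missing = rna_counts.index.union(chro_counts.index).difference(shared)
    if len(missing):
        pad = pd.DataFrame(np.nan, index=missing, columns=out.columns)
        out = pd.concat([out, pad]).loc[rna_counts.index.union(chro_counts.index)]
    return out[["baseMean", "interaction_log2fc", "interaction_p", "interaction_padj"]]


def classify_ptr(
    interaction: pd.DataFrame,
    chro_results: pd.DataFrame,
    rna_results: pd.DataFrame,
    ptr_padj: float = PTR_PADJ,
    ptr_basemean: float = PTR_BASEMEAN,
    ptr_abs_lfc: float = PTR_ABS_LFC,
    transcriptional_padj: float = TRANSCRIPTIONAL_PADJ,
    transcriptional_abs_lfc: float = TRANSCRIPTIONAL_ABS_LFC,
) -> pd.DataFrame:
    """Assign each gene one regulatory category.

    GPS: interaction padj < 0.2, transcription flat (chro baseMean >
    100 and chro padj > 0.2), steady-state decreased (rna baseMean >
    100, rna padj < 0.2, rna log2fc < -0.5).  LPS mirrors with rna
    log2fc > 0.5.  transcriptional: chro padj < 0.05 and |chro log2fc|
    > 0.5.  Genes failing all three are unchanged; genes with any NA
    component are untestable.  Categories are mutually exclusive in
    that priority order.
    """
    genes = rna_results.index.union(chro_results.index).union(interaction.index)
    cols = pd.DataFrame(index=genes)
    cols["interaction_padj"] = interaction["interaction_padj"].reindex(genes)
    cols["chro_padj"] = chro_results["padj"].reindex(genes)
    cols["chro_lfc"] = chro_results["log2fc"].reindex(genes)
    cols["chro_baseMean"] = chro_results["baseMean"].reindex(genes)
    cols["rna_padj"] = rna_results["padj"].reindex(genes)
    cols["rna_lfc"] = rna_results["log2fc"].reindex(genes)
    cols["rna_baseMean"] = rna_results["baseMean"].reindex(genes)

    na = cols[["interaction_padj", "chro_padj", "chro_lfc", "chro_baseMean",
               "rna_padj", "rna_lfc", "rna_baseMean"]].isna().any(axis=1)
    ptr_core = (
        (cols["interaction_padj"] < ptr_padj)
        & (cols["chro_baseMean"] > ptr_basemean)
        & (cols["chro_padj"] > ptr_padj)
        & (cols["rna_baseMean"] > ptr_basemean)
        & (cols["rna_padj"] < ptr_padj)
    )
    gps = ptr_core & (cols["rna_lfc"] < -ptr_abs_lfc)
    lps = ptr_core & (cols["rna_lfc"] > ptr_abs_lfc)
    transcriptional = (
        (cols["chro_padj"] < transcriptional_padj)
        & (cols["chro_lfc"].abs() > transcriptional_abs_lfc)
    )
    category = pd.Series("unchanged", index=genes)
    category[transcriptional.fillna(False)] = "transcriptional"
    category[lps.fillna(False)] = "LPS"
    category[gps.fillna(False)] = "GPS"
    category[na] = "untestable"
    cols.insert(0, "category", category)
    cols.index.name = "gene_id"
    return cols


def concordance_report(
    rna_results: pd.DataFrame,
    chro_results: pd.DataFrame,
    basemean_min: float = 500.0,
) -> dict:
    """Pearson r between steady-state and transcriptional log2fc.

    Restricted to shared genes with RNA baseMean above the filter
    (high-expression genes, where fold-change estimates are stable).
    Returns {"r": float | nan, "n_genes": int}.
    """
    shared = rna_results.index.intersection(chro_results.index)
    rna = rna_results.loc[shared]
    chro = chro_results.loc[shared]
    mask = (rna["baseMean"] > basemean_min) & rna["log2fc"].notna() & chro["log2fc"].notna()
    n = int(mask.sum())
    if n < 3:
        logger.warning("concordance: only %d genes pass the filter; reporting NA", n)
        return {"r": float("nan"), "n_genes": n}
    r, _ = stats.pearsonr(rna.loc[mask, "log2fc"], chro.loc[mask, "log2fc"])
    return {"r": float(r), "n_genes": n}
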