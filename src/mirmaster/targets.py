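"""Canonical miRNA seed-site detection and gene-list enrichment.

Seed matching follows the canonical vocabulary: with ``match7`` the
DNA reverse complement of the seed (miRNA nucleotides 2-8),

* 8mer      = match7 followed by A  (pairs seed 2-8 plus a t1 A),
* 7mer-m8   = match7 alone,
* 7mer-A1   = match7[1:] followed by A (pairs seed 2-7 plus a t1 A).

A gene list is scored by its density of conserved rat sites
(sites per gene), and significance comes from a Monte-Carlo null:
random same-size gene lists drawn from the expressed background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import SPECIES, MirnaRecord, UtrRecord

logger = logging.getLogger(__name__)

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def seed_match7(seed: str) -> str:
    """DNA reverse complement of a 7-nt seed (RNA or DNA alphabet)."""
    if len(seed) != 7:
        raise ValueError(f"seed must be 7 nt, got {len(seed)}")
    return seed.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TargetSite:
    """One seed-match locus in a 3'UTR."""

    gene_id: str
    mirna_id: str
    site_type: str
    utr_pos: int
    species_support: frozenset[str] = frozenset()


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_seed_sites(utr: UtrRecord, mirna: MirnaRecord) -> list[TargetSite]:
    """All canonical seed sites of one miRNA in one UTR (single species).

    At overlapping loci only the highest-priority type is reported
    (8mer > 7mer-m8 > 7mer-A1): an 8mer at position p subsumes the
    7mer-m8 at p and the 7mer-A1 at p+1.  N bases never match.
    """
    m7 = seed_match7(mirna.seed)
    seq = utr.sequence
    eight = m7 + "A"
    sites: list[TargetSite] = []
    pos8 = set(_find_all(seq, eight))
    for p in sorted(pos8):
        sites.append(TargetSite(utr.gene_id, mirna.mirna_id, "8mer", p))
    for p in _find_all(seq, m7):
        if p not in pos8:
            sites.append(TargetSite(utr.gene_id, mirna.mirna_id, "7mer-m8", p))
    a1 = m7[1:] + "A"
    for p in _find_all(seq, a1):
        if (p - 1) not in pos8:
            sites.append(TargetSite(utr.gene_id, mirna.mirna_id, "7mer-A1", p))
    sites.sort(key=lambda s: (s.utr_pos, SITE_TYPES.index(s.site_type)))
    return sites


def find_sites_all(
    utrs: dict[tuple[str, str], UtrRecord],
    mirnas: dict[str, MirnaRecord],
) -> pd.DataFrame:
    """Site table over every (gene, species, miRNA) with a UTR present."""
    rows = []
    for (gene_id, species), utr in utrs.items():
        for mirna in mirnas.values():
            for s in find_seed_sites(utr, mirna):
                rows.append((gene_id, species, mirna.mirna_id, s.site_type, s.utr_pos))
    return pd.DataFrame(rows, columns=["gene_id", "species", "mirna_id", "site_type", "utr_pos"])


def conserved_sites(
    site_table: pd.DataFrame, required_other_species: int = 2
) -> pd.DataFrame:
    """Rat sites supported by presence in other species.

    A rat site counts as conserved when, for the same (gene, miRNA),
    at least ``required_other_species`` of {human, mouse, dog} carry at
    least one canonical site of any type.  Conservation is presence-
    based per gene, not position-aligned; a species with no UTR for the
    gene simply does not support it.  Returns the rat rows with a
    ``species_support`` column (comma-joined, always containing rat)
    and a boolean ``conserved``.
    """
    rat = site_table[site_table["species"] == "rat"].copy()
    others = site_table[site_table["species"] != "rat"]
    support = (
        others.groupby(["gene_id", "mirna_id"])["species"]
        .agg(lambda s: sorted(set(s)))
        .to_dict()
    )
    sup_lists = [
        ["rat"] + support.get((g, m), [])
        for g, m in zip(rat["gene_id"], rat["mirna_id"])
    ]
    rat["species_support"] = [",".join(s) for s in sup_lists]
    rat["conserved"] = [len(s) - 1 >= required_other_species for s in sup_lists]
    return rat


def site_counts(conserved: pd.DataFrame) -> pd.DataFrame:
    """Conserved-rat-site count per (gene, miRNA), wide (genes x miRNAs)."""
    kept = conserved[conserved["conserved"]]
    if kept.empty:
        return pd.DataFrame()
    return (
        kept.groupby(["gene_id", "mirna_id"]).size().unstack(fill_value=0)
    )


def score_list(
    gene_list: list[str], mirna_id: str, counts: pd.DataFrame
) -> float:
    """Conserved-site density: sites for this miRNA across the list / list size.

    Genes without a rat UTR (or without sites) contribute zero to the
    numerator but stay in the denominator.
    """
    if not gene_list:
        raise ValueError("empty gene list")
    if counts.empty or mirna_id not in counts.columns:
        return 0.0
    col = counts[mirna_id]
    total = int(col.reindex(gene_list).fillna(0).sum())
    return total / len(gene_list)


@dataclass(frozen=True)
class EnrichmentResult:
    """Monte-Carlo enrichment of one miRNA's conserved targets in a gene list."""

    mirna_id: str
    list_size: int
    observed_score: float
    null_scores: np.ndarray
    p_emp: float
    frac_targeted: float
    padj: float = float("nan")


def perm_pvalue(null_scores: np.ndarray, observed: float) -> float:
    """Plus-one permutation p with ties counted against the list (>=)."""
    null_scores = np.asarray(null_scores, dtype=float)
    return (np.count_nonzero(null_scores >= observed) + 1) / (null_scores.size + 1)


def empirical_p(
    gene_list: list[str],
    mirna_id: str,
    background: list[str],
    counts: pd.DataFrame,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> EnrichmentResult:
    """Permutation p-value for one miRNA's target density in a gene list.

    The null draws ``n_perm`` lists of the same size uniformly without
    replacement from the background universe; ties count against the
    list (>=) and a +1 pseudocount keeps the p-value off zero:
    p = (#{null >= observed} + 1) / (n_perm + 1).
    """
    if len(background) <= len(gene_list):
        raise ValueError(
            f"background ({len(background)}) must exceed list size ({len(gene_list)})"
        )
    rng = np.random.default_rng(rng_seed)
    observed = score_list(gene_list, mirna_id, counts)
    if counts.empty or mirna_id not in counts.columns:
        bg_counts = np.zeros(len(background))
    else:
        bg_counts = counts[mirna_id].reindex(background).fillna(0).to_numpy(dtype=float)
    k = len(gene_list)
    nbg = len(background)
    if n_perm * nbg <= 20_000_000:
        # vectorized draws without replacement: k smallest of a random key per row
        keys = rng.random((n_perm, nbg))
        idx = np.argpartition(keys, k, axis=1)[:, :k]
        null = bg_counts[idx].sum(axis=1) / k
    else:
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = bg_counts[rng.choice(nbg, size=k, replace=False)].sum() / k
    p = perm_pvalue(null, observed)
    if counts.empty or mirna_id not in counts.columns:
        frac = 0.0
    else:
        frac = float((counts[mirna_id].reindex(gene_list).fillna(0) > 0).mean())
    return EnrichmentResult(mirna_id, k, observed, null, p, frac)


def enrich_gps(
    gps_genes: list[str],
    mirna_ids: list[str],
    background: list[str],
    counts: pd.DataFrame,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Score every candidate miRNA against one gene list; BH across miRNAs.

    ``mirna_ids`` is typically the significantly up-regulated miRNAs of
    the matching contrast, and ``gps_genes`` the GPS calls; each miRNA
    gets its own permutation stream derived from ``rng_seed``.  Returns
    a table sorted by p_emp with columns mirna_id, list_size,
    observed_score, p_emp, padj, frac_targeted.
    """
    from .de import bh_adjust

    if not gps_genes:
        logger.warning("enrich_gps: empty gene list; nothing to test")
        return pd.DataFrame(columns=["mirna_id", "list_size", "observed_score",
                                     "p_emp", "padj", "frac_targeted"])
    seeds = np.random.SeedSequence(rng_seed).spawn(len(mirna_ids))
    rows = []
    for mirna_id, ss in zip(mirna_ids, seeds):
        res = empirical_p(gps_genes, mirna_id, background, counts,
                          n_perm=n_perm, rng_seed=int(ss.generate_state(1)[0] % (2**31)))
        rows.append((mirna_id, res.list_size, res.observed_score, res.p_emp, res.frac_targeted))
    out = pd.DataFrame(rows, columns=["mirna_id", "list_size", "observed_score",
                                      "p_emp", "frac_targeted"])
    out["padj"] = bh_adjust(out["p_emp"].to_numpy())
    out = out[["mirna_id", "list_size", "observed_score", "p_emp", "padj", "frac_targeted"]]
    return out.sort_values(["p_emp", "mirna_id"], kind="stable").reset_index(drop=True)
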