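"""Single-base polymerase-position signal -> per-gene count matrix.

Nascent run-on signal is represented as single-base BED records (the
base marking the 3' end of the nascent RNA).  A record is counted for a
gene when chromosome and strand match and the position falls inside the
truncated gene body, half-open: ``body_start <= pos < body_end``.  A
record inside several overlapping eligible bodies counts once per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel

logger = logging.getLogger(__name__)

VALID_CONDITIONS = frozenset({"control", "iAs", "MAs", "treated"})
VALID_ASSAYS = frozenset({"rna", "chro", "mirna"})


@dataclass(frozen=True)
class SignalRecord:
    """One collapsed polymerase position: a single stranded base with a weight."""

    chrom: str
    pos: int
    strand: str
    weight: int = 1


def read_signal_bed(path: str | Path) -> list[SignalRecord]:
    """Read single-base BED6 signal (score column = collapsed read weight).

    Every interval must have length exactly 1.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     dtype={"chrom": str, "strand": str})
    bad = df.index[(df["end"] - df["start"]) != 1]
    if len(bad):
        i = int(bad[0])
        raise ValueError(
            f"{path}: record {i + 1} ({df.loc[i, 'chrom']}:{df.loc[i, 'start']}-"
            f"{df.loc[i, 'end']}) has interval length != 1"
        )
    return [SignalRecord(r.chrom, int(r.start), r.strand, int(r.score))
            for r in df.itertuples(index=False)]


def count_signal(
    signal: Iterable[SignalRecord], genes: Mapping[str, GeneModel]
) -> pd.Series:
    """Sum signal weights over each eligible truncated gene body.

    Returns a Series indexed by gene_id (eligible genes only, input
    order preserved).  Implementation sorts positions per
    (chrom, strand) once and resolves each body by binary search, so
    overlapping bodies are each credited independently.
    """
    eligible = [g for g in genes.values() if g.eligible]
    counts = pd.Series(0, index=[g.gene_id for g in eligible], dtype=np.int64)
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for rec in signal:
        by_key.setdefault((rec.chrom, rec.strand), []).append((rec.pos, rec.weight))
    sorted_keys = {}
    for key, rows in by_key.items():
        arr = np.asarray(rows, dtype=np.int64)
        order = np.argsort(arr[:, 0], kind="stable")
        pos = arr[order, 0]
        csum = np.concatenate([[0], np.cumsum(arr[order, 1])])
        sorted_keys[key] = (pos, csum)
    n_overlap_flagged = 0
    for g in eligible:
        entry = sorted_keys.get((g.chrom, g.strand))
        if entry is None or g.body_length == 0:
            continue
        pos, csum = entry
        lo = np.searchsorted(pos, g.body_start, side="left")
        hi = np.searchsorted(pos, g.body_end, side="left")
        counts[g.gene_id] = int(csum[hi] - csum[lo])
    # flag multi-gene overlap once per call (each overlapped gene keeps its count)
    spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for g in eligible:
        spans.setdefault((g.chrom, g.strand), []).append((g.body_start, g.body_end))
    for key, ivals in spans.items():
        ivals.sort()
        for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                n_overlap_flagged += 1
    if n_overlap_flagged:
        logger.info("count_signal: %d overlapping eligible gene-body pairs; "
                    "signal in overlaps is credited to every gene", n_overlap_flagged)
    return counts


def count_signal_naive(
    signal: Iterable[SignalRecord], genes: Mapping[str, GeneModel]
) -> pd.Series:
    """Brute-force per-record scan; the oracle for :func:`count_signal`."""
    eligible = [g for g in genes.values() if g.eligible]
    counts = pd.Series(0, index=[g.gene_id for g in eligible], dtype=np.int64)
    for rec in signal:
        for g in eligible:
            if (rec.chrom == g.chrom and rec.strand == g.strand
                    and g.body_start <= rec.pos < g.body_end):
                counts[g.gene_id] += rec.weight
    return counts


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check a sample sheet (columns sample, condition, batch, assay [, path])."""
    required = {"sample", "condition", "batch", "assay"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if metadata["sample"].duplicated().any():
        dup = metadata.loc[metadata["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicated sample id: {dup}")
    bad_cond = set(metadata["condition"]) - VALID_CONDITIONS
    if bad_cond:
        raise ValueError(f"unknown condition(s): {sorted(bad_cond)}; "
                         f"expected one of {sorted(VALID_CONDITIONS)}")
    bad_assay = set(metadata["assay"]) - VALID_ASSAYS
    if bad_assay:
        raise ValueError(f"unknown assay(s): {sorted(bad_assay)}")
    return metadata


def assemble_matrix(
    per_sample_counts: Mapping[str, pd.Series], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Stack per-sample count vectors into a features x samples matrix.

    Column order follows metadata row order; every sample in the
    metadata must have counts over an identical gene universe.
    """
    validate_metadata(metadata)
    samples = list(metadata["sample"])
    missing = [s for s in samples if s not in per_sample_counts]
    if missing:
        raise ValueError(f"metadata sample(s) with no counts: {missing}")
    universe = None
    for s in samples:
        idx = per_sample_counts[s].index
        if universe is None:
            universe = idx
        elif not universe.equals(idx):
            raise ValueError(f"sample {s}: gene universe differs from first sample")
    mat = pd.DataFrame({s: per_sample_counts[s] for s in samples})
    if (mat.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return mat


def count_samples_from_metadata(
    metadata: pd.DataFrame, genes: Mapping[str, GeneModel]
) -> pd.DataFrame:
    """Count every chro sample listed in a metadata sheet (path column)."""
    chro_meta = metadata[metadata["assay"] == "chro"]
    per_sample = {}
    for row in chro_meta.itertuples(index=False):
        per_sample[row.sample] = count_signal(read_signal_bed(row.path), genes)
    return assemble_matrix(per_sample, chro_meta)
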