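"""Gene-model, 3'UTR and miRNA ingestion.

Coordinates are internal 0-based half-open throughout; GTF input is
converted from its native 1-based closed convention on parsing.  Gene
bodies are truncated to remove the promoter-proximal polymerase pause
region (first 500 bp downstream of the TSS by default), and genes whose
annotated span is shorter than 1 kb are flagged ineligible for nascent
transcription counting because the truncation biases against them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

SPECIES = ("rat", "human", "mouse", "dog")

#: default width of the excluded pause region downstream of the TSS (bp)
TSS_EXCLUSION = 500
#: genes with an annotated span shorter than this are excluded (bp)
MIN_GENE_LENGTH = 1000


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene span plus its truncated counting window.

    ``start``/``end`` are the full annotated span; ``body_start``/
    ``body_end`` the window used for polymerase-position counting
    (equal to the span until :func:`truncate_gene_body` is applied).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    body_start: int
    body_end: int
    eligible: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end ({self.start}, {self.end})")
        if self.body_start < self.start or self.body_end > self.end:
            raise ValueError(f"{self.gene_id}: body window outside gene span")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def body_length(self) -> int:
        return max(0, self.body_end - self.body_start)


@dataclass(frozen=True)
class UtrRecord:
    """A 3'UTR sequence (mRNA sense strand, DNA alphabet) for one species."""

    gene_id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {SPECIES}")
        if not self.sequence:
            raise ValueError(f"{self.gene_id}/{self.species}: empty UTR sequence")


@dataclass(frozen=True)
class MirnaRecord:
    """A mature miRNA; the seed is nucleotides 2-8 of the mature sequence."""

    mirna_id: str
    mature_sequence: str
    seed: str = field(init=False)

    def __post_init__(self) -> None:
        if len(self.mature_sequence) < 8:
            raise ValueError(f"{self.mirna_id}: mature sequence shorter than 8 nt")
        object.__setattr__(self, "seed", self.mature_sequence[1:8])


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_gtf(path: str | Path) -> dict[str, GeneModel]:
    """Parse a GTF into untruncated gene models keyed by gene_id.

    ``gene`` features are used directly; when a gene_id appears only as
    transcript/exon features the gene span is the union of those spans
    (nascent signal covers the whole locus, so the union is the right
    counting substrate).  GTF 1-based closed coordinates become 0-based
    half-open.  Duplicate ``gene`` records with conflicting coordinates
    are an error.
    """
    path = Path(path)
    gene_rows: dict[str, tuple[str, str, int, int]] = {}
    union_rows: dict[str, tuple[str, str, int, int]] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            try:
                start = int(start_s) - 1  # 1-based closed -> 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            attrs = _parse_gtf_attributes(attr)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            if feature == "gene":
                prev = gene_rows.get(gene_id)
                if prev is not None and prev != (chrom, strand, start, end):
                    raise ValueError(
                        f"{path}:{lineno}: duplicate gene record for {gene_id} with conflicting coordinates"
                    )
                gene_rows[gene_id] = (chrom, strand, start, end)
            else:
                prev = union_rows.get(gene_id)
                if prev is None:
                    union_rows[gene_id] = (chrom, strand, start, end)
                else:
                    pchrom, pstrand, pstart, pend = prev
                    if (pchrom, pstrand) != (chrom, strand):
                        raise ValueError(
                            f"{path}:{lineno}: {gene_id} spans multiple chromosomes/strands"
                        )
                    union_rows[gene_id] = (chrom, strand, min(pstart, start), max(pend, end))
    if n_lines == 0:
        logger.warning("GTF %s contains no feature lines", path)
    rows = dict(union_rows)
    rows.update(gene_rows)  # explicit gene records win
    return {
        gid: GeneModel(gid, chrom, strand, start, end, start, end)
        for gid, (chrom, strand, start, end) in rows.items()
    }


def truncate_gene_body(
    gene: GeneModel,
    tss_exclusion: int = TSS_EXCLUSION,
    min_gene_length: int = MIN_GENE_LENGTH,
    length_filter_on_body: bool = False,
) -> GeneModel:
    """Remove the pause region downstream of the TSS and apply the length filter.

    On the + strand the TSS is ``start`` so the body becomes
    ``[start + tss_exclusion, end)``; on the - strand it mirrors to
    ``[start, end - tss_exclusion)``.  A gene is eligible when its full
    annotated span is at least ``min_gene_length`` (strictly shorter
    genes are excluded); set ``length_filter_on_body`` to assess the
    truncated body length instead.  Idempotent.
    """
    if gene.strand == "+":
        body_start = min(gene.start + tss_exclusion, gene.end)
        body_end = gene.end
    else:
        body_start = gene.start
        body_end = max(gene.end - tss_exclusion, gene.start)
    measured = (body_end - body_start) if length_filter_on_body else (gene.end - gene.start)
    eligible = measured >= min_gene_length and body_end > body_start
    return replace(gene, body_start=body_start, body_end=body_end, eligible=eligible)


def truncate_all(
    genes: Mapping[str, GeneModel], **kwargs
) -> dict[str, GeneModel]:
    return {gid: truncate_gene_body(g, **kwargs) for gid, g in genes.items()}


def write_bodies_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Export truncated gene bodies as BED6 (eligible genes only)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.body_start, g.gene_id)):
            if not g.eligible:
                continue
            fh.write(f"{g.chrom}\t{g.body_start}\t{g.body_end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_bodies_bed(path: str | Path) -> dict[str, GeneModel]:
    """Re-read a gene-body BED6; spans equal the body windows."""
    out: dict[str, GeneModel] = {}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    for row in df.itertuples(index=False):
        out[row.name] = GeneModel(row.name, row.chrom, row.strand,
                                  int(row.start), int(row.end), int(row.start), int(row.end))
    return out


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def load_utrs(paths: Mapping[str, str | Path]) -> dict[tuple[str, str], UtrRecord]:
    """Load per-species 3'UTR FASTAs keyed by (gene_id, species).

    The gene identifier is the first whitespace-delimited header token
    (files are pre-keyed by a shared cross-species identifier).
    Sequences are uppercased with U normalized to T; a per-species
    duplicate gene keeps its longest sequence.
    """
    missing = [sp for sp in paths if not Path(paths[sp]).exists()]
    if missing:
        raise FileNotFoundError(
            f"UTR FASTA missing for species: {', '.join(sorted(missing))} "
            f"(required species: {', '.join(SPECIES)})"
        )
    records: dict[tuple[str, str], UtrRecord] = {}
    for species, path in paths.items():
        for rec in SeqIO.parse(str(path), "fasta"):
            gene_id = rec.id.split()[0]
            seq = _normalize_seq(str(rec.seq))
            if not seq:
                logger.warning("empty UTR for %s/%s skipped", gene_id, species)
                continue
            key = (gene_id, species)
            if key in records:
                if len(seq) <= len(records[key].sequence):
                    logger.warning("duplicate UTR for %s/%s: keeping longest", gene_id, species)
                    continue
                logger.warning("duplicate UTR for %s/%s: keeping longest", gene_id, species)
            records[key] = UtrRecord(gene_id, species, seq)
    return records


def load_mirnas(path: str | Path) -> dict[str, MirnaRecord]:
    """Load mature miRNA sequences; seed = positions 2-8 of the mature strand.

    RNA or DNA alphabet accepted; stored in RNA alphabet internally.
    Sequences shorter than 8 nt cannot carry a seed and are rejected
    with a warning.
    """
    out: dict[str, MirnaRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        if len(seq) < 8:
            logger.warning("miRNA %s mature sequence < 8 nt: rejected", rec.id)
            continue
        out[rec.id] = MirnaRecord(rec.id, seq)
    return out
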