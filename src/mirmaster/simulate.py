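"""Fully self-contained synthetic multi-omics study.

Emulates the study design the pipeline targets: three assays (steady-
state RNA, nascent run-on signal, small RNA) over control vs treated
with replicates and batches, negative-binomial counts sharing per-gene
baseline means across the RNA and nascent assays, and planted truth:

* transcriptional genes shift in both assays (concordant),
* GPS genes fall only at the mRNA level (gain of post-transcriptional
  suppression), LPS genes rise only at the mRNA level,
* one "master" miRNA is up-regulated in the small-RNA assay and its
  conserved seed sites are planted into most GPS genes' 3'UTRs, with a
  low background targeting rate everywhere else.

Nascent signal is emitted as single-base BED records placed uniformly
inside the truncated gene bodies, so gene-body counting reproduces the
intended count matrix integer-exactly.  Everything is reproducible
from one seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, MirnaRecord, UtrRecord, SPECIES, truncate_gene_body
from .targets import seed_match7

logger = logging.getLogger(__name__)

GENE_CLASSES = ("transcriptional_up", "transcriptional_down", "GPS", "LPS", "null")
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults describe a small but realistic desk-scale study: 2000
    genes, 20 miRNAs, 3 replicates per group in 2 batches, NB
    dispersion 0.05, planted |log2fc| of 1.5, 100 GPS genes of which
    80% carry conserved master-miRNA sites against a 5% background
    targeting rate.
    """

    n_genes: int = 2000
    n_mirnas: int = 20
    n_per_group: int = 3
    conditions: tuple[str, str] = ("control", "treated")
    batches: tuple[str, ...] = ("batch1", "batch2")
    mean_log_range: tuple[float, float] = (np.log(100.0), np.log(2000.0))
    alpha: float = 0.05
    frac_transcriptional: float = 0.10
    frac_ptr_gps: float = 0.05
    frac_ptr_lps: float = 0.05
    effect_lfc: float = 1.5
    master_mirna_id: str = "syn-miR-01"
    n_up_mirnas_extra: int = 2
    n_down_mirnas: int = 3
    gps_target_rate: float = 0.8
    background_target_rate: float = 0.05
    utr_len: int = 500
    batch_sigma: float = 0.1
    depth_sigma: float = 0.15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = self.frac_transcriptional + self.frac_ptr_gps + self.frac_ptr_lps
        if total > 1.0:
            raise ValueError(f"planted fractions sum to {total} > 1")
        for name in ("gps_target_rate", "background_target_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect_lfc < 0:
            raise ValueError("effect_lfc must be >= 0")
        if self.n_genes < 1 or self.n_mirnas < 1 or self.n_per_group < 1:
            raise ValueError("n_genes, n_mirnas and n_per_group must be positive")


@dataclass
class SimTruth:
    """Planted ground truth: per-gene class and effects, per-miRNA class, sites."""

    gene_truth: pd.DataFrame   # gene_id, class, rna_lfc, chro_lfc
    mirna_truth: pd.DataFrame  # mirna_id, class, lfc
    site_truth: pd.DataFrame   # gene_id, mirna_id, species, n_sites, conserved


@dataclass
class SimStudy:
    """In-memory synthetic study plus its ground truth."""

    cfg: SimConfig
    genes: dict[str, GeneModel]
    rna_counts: pd.DataFrame
    chro_counts: pd.DataFrame
    mirna_counts: pd.DataFrame
    metadata: pd.DataFrame
    utrs: dict[tuple[str, str], UtrRecord]
    mirnas: dict[str, MirnaRecord]
    truth: SimTruth
    chro_positions: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _make_mirnas(rng: np.random.Generator, cfg: SimConfig) -> dict[str, MirnaRecord]:
    """Random 22-nt matures with mutually non-colliding seed motifs."""
    mirnas: dict[str, MirnaRecord] = {}
    motifs: list[str] = []  # accepted 8mer strings (m7 + A)
    i = 0
    while len(mirnas) < cfg.n_mirnas:
        i += 1
        if i > 10000:
            raise RuntimeError("could not generate non-colliding miRNA seeds")
        mature_dna = "".join(_random_seq(rng, 22))
        mature = mature_dna.replace("T", "U")
        seed = mature[1:8]
        m7 = seed_match7(seed)
        eight, a1 = m7 + "A", m7[1:] + "A"
        clash = any(
            m7 in prev or a1 in prev or p7 in eight or pa1 in eight
            for prev in motifs
            for p7, pa1 in [(prev[:-1], prev[1:])]
        )
        if clash:
            continue
        mid = f"syn-miR-{len(mirnas) + 1:02d}"
        mirnas[mid] = MirnaRecord(mid, mature)
        motifs.append(eight)
    return mirnas


def _clean_backbone(rng: np.random.Generator, seq: np.ndarray, motifs: list[str]) -> np.ndarray:
    """Mutate bases until no motif occurs anywhere in the sequence."""
    s = "".join(seq)
    for _ in range(200):
        hit = -1
        for m in motifs:
            j = s.find(m)
            if j != -1:
                hit = j
                break
        if hit == -1:
            return np.array(list(s))
        k = hit + int(rng.integers(0, 7))
        old = s[k]
        choices = [b for b in "ACGT" if b != old]
        s = s[:k] + choices[int(rng.integers(0, 3))] + s[k + 1:]
    raise RuntimeError("backbone cleaning did not converge")


def _plant_utr(
    rng: np.random.Generator,
    utr_len: int,
    clean_motifs: list[str],
    plants: list[str],
) -> str | None:
    """One UTR: cleaned random backbone with the given 8-mer motifs planted.

    Returns None when non-overlapping placement fails (caller retries).
    """
    seq = _clean_backbone(rng, _random_seq(rng, utr_len), clean_motifs)
    taken: list[tuple[int, int]] = []
    for motif in plants:
        placed = False
        for _ in range(50):
            p = int(rng.integers(0, utr_len - len(motif) + 1))
            span = (p, p + len(motif))
            if all(span[1] <= s or span[0] >= e for s, e in taken):
                seq[span[0]:span[1]] = list(motif)
                taken.append(span)
                placed = True
                break
        if not placed:
            return None
    return "".join(seq)


def _verify_counts(seq: str, mirnas: dict[str, MirnaRecord],
                   expected: dict[str, int]) -> bool:
    from .annotation import UtrRecord as _U
    from .targets import find_seed_sites
    rec = _U("tmp", "rat", seq)
    for mid, mir in mirnas.items():
        n = len(find_seed_sites(rec, mir))
        if n != expected.get(mid, 0):
            return False
    return True


def simulate_study(cfg: SimConfig) -> SimStudy:
    """Generate the complete synthetic study (annotation, counts, UTRs, truth)."""
    rng = np.random.default_rng(cfg.rng_seed)
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]

    # --- gene models on one synthetic chromosome, all passing the length filter
    genes: dict[str, GeneModel] = {}
    cursor = 1000
    lengths = rng.integers(1500, 6001, size=cfg.n_genes)
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    for gid, length, strand in zip(gene_ids, lengths, strands):
        g = GeneModel(gid, "chrSyn1", str(strand), cursor, cursor + int(length),
                      cursor, cursor + int(length))
        genes[gid] = truncate_gene_body(g)
        cursor += int(length) + 200

    # --- planted gene classes (deterministic counts, random assignment)
    n_tr = int(round(cfg.frac_transcriptional * cfg.n_genes))
    n_gps = int(round(cfg.frac_ptr_gps * cfg.n_genes))
    n_lps = int(round(cfg.frac_ptr_lps * cfg.n_genes))
    order = rng.permutation(cfg.n_genes)
    classes = np.array(["null"] * cfg.n_genes, dtype=object)
    tr_idx = order[:n_tr]
    classes[tr_idx[: n_tr // 2]] = "transcriptional_up"
    classes[tr_idx[n_tr // 2:]] = "transcriptional_down"
    classes[order[n_tr:n_tr + n_gps]] = "GPS"
    classes[order[n_tr + n_gps:n_tr + n_gps + n_lps]] = "LPS"

    e = cfg.effect_lfc
    rna_lfc = np.select(
        [classes == "transcriptional_up", classes == "transcriptional_down",
         classes == "GPS", classes == "LPS"],
        [e, -e, -e, e], default=0.0)
    chro_lfc = np.select(
        [classes == "transcriptional_up", classes == "transcriptional_down"],
        [e, -e], default=0.0)
    gene_truth = pd.DataFrame({"gene_id": gene_ids, "class": classes,
                               "rna_lfc": rna_lfc, "chro_lfc": chro_lfc}).set_index("gene_id")

    # --- metadata for all three assays
    rows = []
    for assay in ("rna", "chro", "mirna"):
        for cond in cfg.conditions:
            for i in range(cfg.n_per_group):
                rows.append((f"{assay}_{cond}{i + 1}", cond,
                             cfg.batches[i % len(cfg.batches)], assay, ""))
    metadata = pd.DataFrame(rows, columns=["sample", "condition", "batch", "assay", "path"])

    # --- NB count matrices
    lo, hi = cfg.mean_log_range
    base_mean = np.exp(rng.uniform(lo, hi, size=cfg.n_genes))
    batch_factor = {
        (b, a): np.exp(rng.normal(0.0, cfg.batch_sigma, size=cfg.n_genes))
        for a in ("rna", "chro") for b in cfg.batches
    }
    treated = cfg.conditions[1]

    def nb_matrix(meta: pd.DataFrame, means: np.ndarray, lfc: np.ndarray,
                  per_batch: bool) -> pd.DataFrame:
        cols = {}
        for r in meta.itertuples(index=False):
            depth = np.exp(rng.normal(0.0, cfg.depth_sigma))
            mu = means * depth * np.power(2.0, lfc * (r.condition == treated))
            if per_batch:
                mu = mu * batch_factor[(r.batch, r.assay)]
            r_nb = 1.0 / cfg.alpha
            cols[r.sample] = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
        return pd.DataFrame(cols)

    rna_meta = metadata[metadata["assay"] == "rna"]
    chro_meta = metadata[metadata["assay"] == "chro"]
    mirna_meta = metadata[metadata["assay"] == "mirna"]
    rna_counts = nb_matrix(rna_meta, base_mean, rna_lfc, True).set_axis(gene_ids, axis=0)
    chro_counts = nb_matrix(chro_meta, base_mean * 0.8, chro_lfc, True).set_axis(gene_ids, axis=0)

    # --- small-RNA assay: master + a few extra DE miRNAs
    mirnas = _make_mirnas(rng, cfg)
    mirna_ids = list(mirnas)
    m_class = np.array(["null"] * cfg.n_mirnas, dtype=object)
    m_lfc = np.zeros(cfg.n_mirnas)
    master_idx = mirna_ids.index(cfg.master_mirna_id)
    up_extra = [i for i in range(cfg.n_mirnas) if i != master_idx][: cfg.n_up_mirnas_extra]
    down = [i for i in range(cfg.n_mirnas)
            if i != master_idx and i not in up_extra][: cfg.n_down_mirnas]
    m_class[master_idx] = "master_up"
    m_lfc[master_idx] = e
    for i in up_extra:
        m_class[i], m_lfc[i] = "up", e
    for i in down:
        m_class[i], m_lfc[i] = "down", -e
    mirna_mean = np.exp(rng.uniform(np.log(2000.0), np.log(20000.0), size=cfg.n_mirnas))
    mirna_counts = nb_matrix(mirna_meta, mirna_mean, m_lfc, False).set_axis(mirna_ids, axis=0)
    mirna_truth = pd.DataFrame({"mirna_id": mirna_ids, "class": m_class,
                                "lfc": m_lfc}).set_index("mirna_id")

    # --- nascent signal positions, uniform within truncated bodies
    chro_positions: dict[str, dict[str, np.ndarray]] = {}
    for sample in chro_counts.columns:
        per_gene = {}
        for gid in gene_ids:
            g = genes[gid]
            c = int(chro_counts.loc[gid, sample])
            per_gene[gid] = g.body_start + rng.integers(0, g.body_length, size=c)
        chro_positions[sample] = per_gene

    # --- 3'UTRs with planted conserved seed sites
    other_species = [s for s in SPECIES if s != "rat"]
    motifs8 = {mid: seed_match7(m.seed) + "A" for mid, m in mirnas.items()}
    clean_motifs = [m for mid, mir in mirnas.items()
                    for m in (seed_match7(mir.seed), seed_match7(mir.seed)[1:] + "A")]
    utrs: dict[tuple[str, str], UtrRecord] = {}
    site_rows = []
    for gi, gid in enumerate(gene_ids):
        plant_species: dict[str, list[str]] = {sp: [] for sp in SPECIES}
        expected_rat: dict[str, int] = {}
        for mid in mirna_ids:
            p_cons = (cfg.gps_target_rate
                      if (mid == cfg.master_mirna_id and classes[gi] == "GPS")
                      else cfg.background_target_rate)
            conserved = rng.random() < p_cons
            rat_only = rng.random() < cfg.background_target_rate
            n_rat = int(conserved) + int(rat_only)
            if conserved:
                chosen = list(rng.choice(other_species, size=2, replace=False))
                for sp in chosen:
                    plant_species[sp].append(motifs8[mid])
                    site_rows.append((gid, mid, sp, 1, True))
            if n_rat:
                plant_species["rat"].extend([motifs8[mid]] * n_rat)
                expected_rat[mid] = n_rat
                site_rows.append((gid, mid, "rat", n_rat, conserved))
        for sp in SPECIES:
            for _ in range(20):
                seq = _plant_utr(rng, cfg.utr_len, clean_motifs, plant_species[sp])
                if seq is None:
                    continue
                if sp == "rat" and not _verify_counts(seq, mirnas, expected_rat):
                    continue
                utrs[(gid, sp)] = UtrRecord(gid, sp, seq)
                break
            else:
                raise RuntimeError(f"could not build UTR for {gid}/{sp}")
    site_truth = pd.DataFrame(site_rows, columns=["gene_id", "mirna_id", "species",
                                                  "n_sites", "conserved"])
    truth = SimTruth(gene_truth, mirna_truth, site_truth)
    return SimStudy(cfg, genes, rna_counts, chro_counts, mirna_counts,
                    metadata, utrs, mirnas, truth, chro_positions)


def write_study(study: SimStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every study artifact in the formats the pipeline consumes.

    GTF annotation, per-sample nascent-signal BED6 (score = collapsed
    weight), counts TSVs per assay, per-species UTR FASTA, miRNA FASTA,
    metadata TSV (with BED paths filled in), and the truth tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    gtf = outdir / "annotation.gtf"
    with open(gtf, "w") as fh:
        for gid in study.rna_counts.index:
            g = study.genes[gid]
            fh.write(f'{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t'
                     f'gene_id "{gid}";\n')
    paths["gtf"] = gtf

    meta = study.metadata.copy()
    for sample, per_gene in study.chro_positions.items():
        bed = outdir / f"signal_{sample}.bed"
        with open(bed, "w") as fh:
            for gid in study.chro_counts.index:
                g = study.genes[gid]
                pos, weight = np.unique(per_gene[gid], return_counts=True)
                for p, w in zip(pos, weight):
                    fh.write(f"{g.chrom}\t{p}\t{p + 1}\t.\t{w}\t{g.strand}\n")
        meta.loc[meta["sample"] == sample, "path"] = str(bed)
        paths[f"bed_{sample}"] = bed

    for name, df in (("rna", study.rna_counts), ("chro", study.chro_counts),
                     ("mirna", study.mirna_counts)):
        p = outdir / f"counts_{name}.tsv"
        df.rename_axis("feature_id").to_csv(p, sep="\t")
        paths[f"counts_{name}"] = p

    for sp in SPECIES:
        p = outdir / f"utr_{sp}.fa"
        with open(p, "w") as fh:
            for (gid, s), rec in study.utrs.items():
                if s == sp:
                    fh.write(f">{gid}\n{rec.sequence}\n")
        paths[f"utr_{sp}"] = p

    p = outdir / "mirnas.fa"
    with open(p, "w") as fh:
        for mid, rec in study.mirnas.items():
            fh.write(f">{mid}\n{rec.mature_sequence}\n")
    paths["mirnas"] = p

    mp = outdir / "metadata.tsv"
    meta.to_csv(mp, sep="\t", index=False)
    paths["metadata"] = mp

    study.truth.gene_truth.to_csv(outdir / "truth_genes.tsv", sep="\t")
    study.truth.mirna_truth.to_csv(outdir / "truth_mirnas.tsv", sep="\t")
    study.truth.site_truth.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(asdict(study.cfg), fh, indent=2, sort_keys=True, default=str)
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    return paths


def evaluate_recovery(
    ptr_calls: pd.DataFrame,
    enrichment: pd.DataFrame,
    truth: SimTruth,
) -> dict:
    """Compare pipeline calls with the planted truth.

    Sensitivity and false-discovery rate per planted category, plus the
    rank (1 = most enriched) and empirical p of the planted master
    miRNA in the enrichment table.
    """
    calls = ptr_calls["category"]
    tg = truth.gene_truth
    if not set(calls.index) <= set(tg.index):
        raise ValueError("gene universe of calls does not match the truth table")
    out: dict = {}
    mapping = {"GPS": ["GPS"], "LPS": ["LPS"],
               "transcriptional": ["transcriptional_up", "transcriptional_down"]}
    for cat, truth_classes in mapping.items():
        planted = set(tg.index[tg["class"].isin(truth_classes)])
        called = set(calls.index[calls == cat])
        tp = len(planted & called)
        out[cat] = {
            "n_planted": len(planted),
            "n_called": len(called),
            "sensitivity": tp / len(planted) if planted else float("nan"),
            "fdr": (len(called) - tp) / len(called) if called else 0.0,
        }
    master = tg.attrs.get("master") if tg.attrs else None
    master = master or truth.mirna_truth.index[truth.mirna_truth["class"] == "master_up"]
    master_id = master[0] if len(master) else None
    if master_id is not None and len(enrichment) and master_id in set(enrichment["mirna_id"]):
        ranked = enrichment.sort_values(["p_emp", "mirna_id"], kind="stable").reset_index(drop=True)
        rank = int(ranked.index[ranked["mirna_id"] == master_id][0]) + 1
        row = ranked[ranked["mirna_id"] == master_id].iloc[0]
        out["master_mirna"] = {"mirna_id": master_id, "rank": rank,
                               "p_emp": float(row["p_emp"]),
                               "frac_targeted": float(row["frac_targeted"])}
    else:
        out["master_mirna"] = {"mirna_id": master_id, "rank": None,
                               "p_emp": None, "frac_targeted": None}
    return out
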