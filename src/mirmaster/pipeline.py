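"""End-to-end orchestration: counting -> DE -> integration -> enrichment.

The pipeline ties the stages together for one or more treatment-vs-
control contrasts: nascent-signal gene-body counting, per-assay NB
differential expression (``~ batch + condition``, the batch term
dropping out automatically for single-batch comparisons), the
two-assay interaction test with GPS/LPS classification, and conserved
seed-site enrichment of the GPS genes against the up-regulated miRNAs
of the matching contrast.  All stage outputs are persisted as TSV, a
JSON summary captures the headline numbers, and one global seed fans
out deterministically to every stochastic stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, chro, de, ptr, targets

logger = logging.getLogger(__name__)

#: default thresholds, echoed into every summary for provenance
DEFAULTS = {
    "tss_exclusion": 500,
    "min_gene_length": 1000,
    "de_padj": 0.05,
    "de_abs_lfc": 0.5,
    "de_basemean": 500.0,
    "ptr_padj": 0.2,
    "ptr_basemean": 100.0,
    "ptr_abs_lfc": 0.5,
    "transcriptional_padj": 0.05,
    "transcriptional_abs_lfc": 0.5,
    "n_perm": 1000,
    "required_other_species": 2,
    "background_basemean": 100.0,
}

_PATH_KEYS = ("gtf", "metadata", "counts_rna", "counts_mirna", "mirna_fasta")


@dataclass
class PipelineConfig:
    """Validated run configuration (paths, contrasts, thresholds, seed)."""

    gtf: str
    metadata: str
    counts_rna: str
    counts_mirna: str
    mirna_fasta: str
    utr_fastas: dict[str, str]
    outdir: str
    contrasts: list[tuple[str, str]] = field(default_factory=lambda: [("treated", "control")])
    counts_chro: str | None = None
    rng_seed: int = 0
    params: dict = field(default_factory=lambda: dict(DEFAULTS))


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML config; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"gtf", "metadata", "counts_rna", "counts_mirna", "counts_chro",
             "mirna_fasta", "utr_fastas", "outdir", "contrasts", "rng_seed", "params"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    params = dict(DEFAULTS)
    bad = set(raw.get("params", {})) - set(DEFAULTS)
    if bad:
        raise ValueError(f"unknown params key(s): {sorted(bad)}")
    params.update(raw.get("params", {}))
    for key in ("de_padj", "ptr_padj", "transcriptional_padj"):
        if not 0 < params[key] <= 1:
            raise ValueError(f"{key} must be in (0, 1], got {params[key]}")
    for key in ("n_perm", "tss_exclusion", "min_gene_length", "required_other_species"):
        if params[key] < 1:
            raise ValueError(f"{key} must be >= 1, got {params[key]}")
    missing = [k for k in ("gtf", "metadata", "counts_rna", "counts_mirna",
                           "mirna_fasta", "utr_fastas", "outdir") if k not in raw]
    if missing:
        raise ValueError(f"config missing required key(s): {missing}")
    for key in _PATH_KEYS:
        if not Path(raw[key]).exists():
            raise FileNotFoundError(f"config path for {key!r} does not exist: {raw[key]}")
    for sp, p in raw["utr_fastas"].items():
        if sp not in annotation.SPECIES:
            raise ValueError(f"unknown UTR species {sp!r}")
        if not Path(p).exists():
            raise FileNotFoundError(f"UTR FASTA for {sp} does not exist: {p}")
    contrasts = [tuple(c) for c in raw.get("contrasts", [("treated", "control")])]
    return PipelineConfig(
        gtf=raw["gtf"], metadata=raw["metadata"], counts_rna=raw["counts_rna"],
        counts_mirna=raw["counts_mirna"], mirna_fasta=raw["mirna_fasta"],
        utr_fastas=raw["utr_fastas"], outdir=raw["outdir"], contrasts=contrasts,
        counts_chro=raw.get("counts_chro"), rng_seed=int(raw.get("rng_seed", 0)),
        params=params,
    )


def stage_seed(rng_seed: int, label: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global seed."""
    h = np.random.SeedSequence([rng_seed, abs(hash_label(label))])
    return int(h.generate_state(1)[0] % (2**31))


def hash_label(label: str) -> int:
    # stable across processes (unlike built-in hash on str)
    out = 0
    for ch in label:
        out = (out * 131 + ord(ch)) % (2**31 - 1)
    return out


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def analyze_contrast(
    rna_counts: pd.DataFrame,
    chro_counts: pd.DataFrame,
    mirna_counts: pd.DataFrame,
    metadata: pd.DataFrame,
    mirna_site_counts: pd.DataFrame,
    genes_with_rat_utr: set[str],
    level_a: str,
    level_b: str,
    params: dict,
    rng_seed: int,
) -> dict:
    """All per-contrast analysis on in-memory matrices.

    Returns a dict with the per-assay DE tables, significant feature
    lists, interaction results, PTR classification, concordance and
    the GPS enrichment table.
    """
    spec = de.DesignSpec(("batch", "condition"), ("condition", level_a, level_b))
    res = {}
    res["de_rna"] = de.run_de(rna_counts, metadata[metadata["assay"] == "rna"], spec)
    res["de_chro"] = de.run_de(chro_counts, metadata[metadata["assay"] == "chro"], spec)
    res["de_mirna"] = de.run_de(mirna_counts, metadata[metadata["assay"] == "mirna"], spec,
                                allow_pseudo_reference=True)
    sig = de.significant_features(
        res["de_mirna"], params["de_padj"], params["de_abs_lfc"], params["de_basemean"])
    res["mirnas_up"], res["mirnas_down"] = sig
    res["genes_up"], res["genes_down"] = de.significant_features(
        res["de_rna"], params["de_padj"], params["de_abs_lfc"], params["de_basemean"])
    res["interaction"] = ptr.two_factor_test(
        rna_counts, chro_counts, metadata, level_a, level_b)
    res["ptr"] = ptr.classify_ptr(
        res["interaction"], res["de_chro"], res["de_rna"],
        ptr_padj=params["ptr_padj"], ptr_basemean=params["ptr_basemean"],
        ptr_abs_lfc=params["ptr_abs_lfc"],
        transcriptional_padj=params["transcriptional_padj"],
        transcriptional_abs_lfc=params["transcriptional_abs_lfc"])
    res["concordance"] = ptr.concordance_report(res["de_rna"], res["de_chro"],
                                                basemean_min=params["de_basemean"])
    gps = res["ptr"].index[res["ptr"]["category"] == "GPS"].tolist()
    background = sorted(
        set(res["de_rna"].index[res["de_rna"]["baseMean"] > params["background_basemean"]])
        & genes_with_rat_utr
    )
    res["gps_genes"] = gps
    res["background"] = background
    res["enrichment"] = targets.enrich_gps(
        gps, res["mirnas_up"], background, mirna_site_counts,
        n_perm=params["n_perm"], rng_seed=rng_seed)
    return res


def analyze_study(study, params: dict | None = None, rng_seed: int = 0,
                  level_a: str = "treated", level_b: str = "control") -> dict:
    """Run the per-contrast analysis directly on an in-memory study.

    Convenience wrapper around :func:`analyze_contrast` for simulated
    studies (no files touched): computes the conserved-site index from
    the study's UTRs and miRNAs, then analyses one contrast.
    """
    params = {**DEFAULTS, **(params or {})}
    site_table = targets.find_sites_all(study.utrs, study.mirnas)
    conserved = targets.conserved_sites(
        site_table, required_other_species=params["required_other_species"])
    counts_by_mirna = targets.site_counts(conserved)
    rat_genes = {g for (g, sp) in study.utrs if sp == "rat"}
    seed = stage_seed(rng_seed, f"enrich:{level_a}:{level_b}")
    return analyze_contrast(
        study.rna_counts, study.chro_counts, study.mirna_counts, study.metadata,
        counts_by_mirna, rat_genes, level_a, level_b, params, seed)


def run_all(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline and persist every stage output.

    Returns the summary dict (also written to ``<outdir>/summary.json``).
    Any stage failure raises with the stage name; partial outputs stay
    on disk for inspection.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mirmaster")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "setup"
    try:
        logger.info("parameters: %s", json.dumps(cfg.params, sort_keys=True))
        logger.info("rng_seed: %d", cfg.rng_seed)
        stage = "annotation"
        genes = annotation.truncate_all(
            annotation.parse_gtf(cfg.gtf),
            tss_exclusion=cfg.params["tss_exclusion"],
            min_gene_length=cfg.params["min_gene_length"])
        annotation.write_bodies_bed(genes.values(), outdir / "gene_bodies.bed")
        metadata = pd.read_csv(cfg.metadata, sep="\t")
        chro.validate_metadata(metadata)

        stage = "chro-count"
        if cfg.counts_chro:
            chro_counts = read_counts_tsv(cfg.counts_chro)
        else:
            chro_counts = chro.count_samples_from_metadata(metadata, genes)
            chro_counts.rename_axis("feature_id").to_csv(outdir / "counts_chro.tsv", sep="\t")
        rna_counts = read_counts_tsv(cfg.counts_rna)
        mirna_counts = read_counts_tsv(cfg.counts_mirna)

        stage = "target-sites"
        utrs = annotation.load_utrs(cfg.utr_fastas)
        mirnas = annotation.load_mirnas(cfg.mirna_fasta)
        site_table = targets.find_sites_all(utrs, mirnas)
        conserved = targets.conserved_sites(
            site_table, required_other_species=cfg.params["required_other_species"])
        conserved.to_csv(outdir / "sites_rat.tsv", sep="\t", index=False)
        counts_by_mirna = targets.site_counts(conserved)
        rat_genes = {g for (g, sp) in utrs if sp == "rat"}

        summary: dict = {"rng_seed": cfg.rng_seed, "params": cfg.params, "contrasts": {}}
        for level_a, level_b in cfg.contrasts:
            stage = f"contrast {level_a} vs {level_b}"
            seed = stage_seed(cfg.rng_seed, f"enrich:{level_a}:{level_b}")
            res = analyze_contrast(rna_counts, chro_counts, mirna_counts, metadata,
                                   counts_by_mirna, rat_genes, level_a, level_b,
                                   cfg.params, seed)
            tag = f"{level_a}_vs_{level_b}"
            for key in ("de_rna", "de_chro", "de_mirna"):
                res[key].to_csv(outdir / f"{key}_{tag}.tsv", sep="\t")
            res["interaction"].rename_axis("gene_id").to_csv(
                outdir / f"interaction_{tag}.tsv", sep="\t")
            res["ptr"].to_csv(outdir / f"ptr_{tag}.tsv", sep="\t")
            res["enrichment"].to_csv(outdir / f"enrichment_{tag}.tsv", sep="\t", index=False)
            cat_counts = res["ptr"]["category"].value_counts().to_dict()
            top = (res["enrichment"].iloc[0].to_dict()
                   if len(res["enrichment"]) else None)
            summary["contrasts"][tag] = {
                "n_mirnas_up": len(res["mirnas_up"]),
                "n_mirnas_down": len(res["mirnas_down"]),
                "n_genes_up": len(res["genes_up"]),
                "n_genes_down": len(res["genes_down"]),
                "n_gps": int(cat_counts.get("GPS", 0)),
                "n_lps": int(cat_counts.get("LPS", 0)),
                "n_transcriptional": int(cat_counts.get("transcriptional", 0)),
                "concordance_r": res["concordance"]["r"],
                "concordance_n": res["concordance"]["n_genes"],
                "enrichment_seed": seed,
                "top_mirna": ({"mirna_id": top["mirna_id"], "p_emp": top["p_emp"],
                               "frac_targeted": top["frac_targeted"]} if top else None),
            }
        stage = "summary"
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=True)
            fh.write("\n")
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}; partial outputs in "
                           f"{outdir}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
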