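import pandas as pd
import pytest
import yaml

from mirmaster import pipeline, simulate

ACCEPTANCE_SEED = 1


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study: 2000 genes, 20 miRNAs, 3/group, 100 GPS."""
    return simulate.simulate_study(simulate.SimConfig(rng_seed=ACCEPTANCE_SEED))


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast unit-level checks."""
    cfg = simulate.SimConfig(n_genes=300, n_mirnas=8, utr_len=300, rng_seed=7)
    return simulate.simulate_study(cfg)


@pytest.fixture(scope="session")
def study_dir(default_study, tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    paths = simulate.write_study(default_study, out)
    return out, paths


def _write_config(paths, outdir, seed, path):
    cfg = {
        "gtf": str(paths["gtf"]),
        "metadata": str(paths["metadata"]),
        "counts_rna": str(paths["counts_rna"]),
        "counts_mirna": str(paths["counts_mirna"]),
        "mirna_fasta": str(paths["mirnas"]),
        "utr_fastas": {sp: str(paths[f"utr_{sp}"]) for sp in ("rat", "human", "mouse", "dog")},
        "outdir": str(outdir),
        "rng_seed": seed,
        "contrasts": [["treated", "control"]],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)
    return path


@pytest.fixture(scope="session")
def pipeline_runs(study_dir, tmp_path_factory):
    """The full pipeline executed twice with one seed on the default study.

    Returns (run_dir_a, run_dir_b, summary_a, summary_b); reused by the
    recovery and determinism acceptance checks.
    """
    study_out, paths = study_dir
    base = tmp_path_factory.mktemp("runs")
    summaries = []
    dirs = []
    for tag in ("a", "b"):
        outdir = base / tag
        cfg_path = _write_config(paths, outdir, ACCEPTANCE_SEED, base / f"cfg_{tag}.yaml")
        cfg = pipeline.validate_config(cfg_path)
        summaries.append(pipeline.run_all(cfg))
        dirs.append(outdir)
    return dirs[0], dirs[1], summaries[0], summaries[1]


@pytest.fixture(scope="session")
def pipeline_result(pipeline_runs, default_study):
    """PTR calls + enrichment of the first pipeline run, with truth metrics."""
    run_a, _, summary, _ = pipeline_runs
    calls = pd.read_csv(run_a / "ptr_treated_vs_control.tsv", sep="\t", index_col=0)
    enrichment = pd.read_csv(run_a / "enrichment_treated_vs_control.tsv", sep="\t")
    metrics = simulate.evaluate_recovery(calls, enrichment, default_study.truth)
    return {"calls": calls, "enrichment": enrichment, "metrics": metrics,
            "summary": summary}
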