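"""End-to-end pipeline orchestration.

Runs preprocessing -> differential expression -> regulatory networks ->
fibrosis selection -> survival/ROC evaluation from a declarative config,
writing every stage output plus a JSON manifest (seed, thresholds, per-stage
counts).  Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de import de_genes, de_test
from .fibrosis import select_fibrosis_genes
from .matrix import ExpressionMatrix
from .network import (build_coregulatory_network, build_lnc_mrna_network,
                      build_mir_mrna_network, find_ffls, integrate_targets,
                      node_degree_report)
from .preprocess import filter_low_expression, filter_missing_mirna
from .simulate import CohortSpec, SyntheticCohort, generate_cohort, read_fixture
from .survival import (cox_univariate, kaplan_meier, log_rank, median_split,
                       roc_analysis, survival_gene_screen)

log = logging.getLogger("hfomics")


@dataclasses.dataclass
class PipelineConfig:
    """Declarative pipeline configuration.

    ``input_dir`` may be the string ``"synthetic"``, in which case a cohort
    is generated in memory from ``cohort`` (a :class:`CohortSpec` field
    mapping) using ``seed``.
    """

    input_dir: str = "synthetic"
    output_dir: str = "hfomics_out"
    seed: int = 42
    log2fc_min: float = 1.0
    de_alpha: float = 0.05
    correlation_alpha: float = 0.05
    target_consensus_min: int = 2
    fpkm_min: float = 1.0
    low_expression_frac: float = 0.8
    mirna_max_missing: float = 0.1
    lasso_lambda: float | None = None
    lasso_cv_folds: int = 5
    survival_stream: str = "hf_onset"
    cohort: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.log2fc_min <= 0 or self.de_alpha <= 0 or self.correlation_alpha <= 0:
            raise ValueError("thresholds must be positive")
        if self.input_dir != "synthetic" and not Path(self.input_dir).exists():
            raise FileNotFoundError(self.input_dir)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _load_dataset(config: PipelineConfig) -> SyntheticCohort:
    if config.input_dir == "synthetic":
        spec = CohortSpec(**{**config.cohort, "seed": config.seed})
        return generate_cohort(spec)
    return read_fixture(config.input_dir)


def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": {k: v for k, v in dataclasses.asdict(config).items()},
                      "stages": {}}

    def stage(name):
        log.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    try:
        ds = _load_dataset(config)
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"[load] {exc}") from exc

    # ---- preprocessing ----
    st = stage("preprocess")
    mrna = filter_low_expression(ds.mrna, config.fpkm_min,
                                 config.low_expression_frac)
    mirna = filter_missing_mirna(ds.mirna, config.mirna_max_missing)
    lncrna = ds.lncrna
    st["n_mrna"] = mrna.n_genes
    st["n_lncrna"] = lncrna.n_genes
    st["n_mirna"] = mirna.n_genes

    # ---- differential expression ----
    st = stage("differential_expression")
    de_tables = {}
    for name, mat in (("mrna", mrna), ("lncrna", lncrna), ("mirna", mirna)):
        tab = de_test(mat, alpha=config.de_alpha, log2fc_min=config.log2fc_min)
        de_tables[name] = tab
        _write_tsv(tab, out / f"de_{name}.tsv")
        st[f"n_de_{name}"] = int(tab["is_de"].sum())
    degs = de_genes(de_tables["mrna"])
    delncs = de_genes(de_tables["lncrna"])
    demirs = de_genes(de_tables["mirna"])

    # ---- regulatory networks ----
    st = stage("network")
    targets = integrate_targets(ds.targets, ds.validated)
    _write_tsv(targets, out / "integrated_targets.tsv")
    mir_net = build_mir_mrna_network(demirs, degs, targets, mirna, mrna,
                                     alpha=config.correlation_alpha)
    lnc_net = build_lnc_mrna_network(delncs, degs, lncrna, mrna,
                                     alpha=config.correlation_alpha)
    co_net = build_coregulatory_network(mir_net, lnc_net, mirna, lncrna,
                                        alpha=config.correlation_alpha)
    for net, name in ((mir_net, "mir_mrna"), (lnc_net, "lnc_mrna"),
                      (co_net, "co_regulatory")):
        _write_tsv(net.edge_table(), out / f"network_{name}.tsv")
        net.to_sif(out / f"network_{name}.sif")
        st[f"n_edges_{name}"] = net.n_edges
    ffls = find_ffls(co_net)
    _write_tsv(pd.DataFrame([dataclasses.asdict(f) for f in ffls],
                            columns=["mirna", "lncrna", "mrna"]),
               out / "ffls.tsv")
    _write_tsv(node_degree_report(co_net), out / "node_degrees.tsv")
    st["n_ffls"] = len(ffls)

    # ---- fibrosis selection ----
    st = stage("fibrosis")
    if len(degs) and len(ds.fibrosis) >= config.lasso_cv_folds:
        fit = select_fibrosis_genes(mrna.hf_samples(), ds.fibrosis, degs,
                                    cv_folds=config.lasso_cv_folds,
                                    seed=config.seed, lam=config.lasso_lambda)
        _write_tsv(fit.coefficient_table(), out / "fibrosis_genes.tsv")
        st["lambda"] = fit.lam
        st["n_selected"] = fit.n_selected
        fibrosis_genes = fit.selected
    else:
        st["n_selected"] = 0
        fibrosis_genes = []

    # ---- survival / biomarker ----
    st = stage("survival")
    screen = survival_gene_screen(mrna.hf_samples(), ds.survival,
                                  stream=config.survival_stream)
    _write_tsv(screen, out / "survival_screen.tsv")
    sig = screen[(screen["p"] < 0.05) & screen["gene"].isin(fibrosis_genes)]
    st["n_survival_genes"] = int(len(sig))
    summary: dict = {}
    if len(sig):
        marker = sig.sort_values(["p", "gene"]).iloc[0]["gene"]
        st["marker"] = marker
        surv = ds.survival[ds.survival["stream"] == config.survival_stream]
        surv = surv.set_index("patient_id")
        expr = mrna.hf_samples().values.loc[marker]
        common = [s for s in expr.index if s in surv.index]
        groups = median_split(expr.loc[common])
        km_rows = []
        for gname in ("high", "low"):
            ids = groups.index[groups == gname]
            km = kaplan_meier(surv.loc[ids, "time_months"],
                              surv.loc[ids, "event"])
            t, s = km.step_function()
            km_rows.append(pd.DataFrame({"group": gname, "time": t, "survival": s}))
        _write_tsv(pd.concat(km_rows, ignore_index=True), out / "km_curves.tsv")
        hi = groups.index[groups == "high"]
        lo = groups.index[groups == "low"]
        lr = log_rank(surv.loc[hi, "time_months"], surv.loc[hi, "event"],
                      surv.loc[lo, "time_months"], surv.loc[lo, "event"])
        summary["marker"] = marker
        summary["log_rank_p"] = lr.p
    roc = roc_analysis(ds.plasma["col1a1_ng_ml"], ds.plasma["group"])
    _write_tsv(roc.curve, out / "roc_curve.tsv")
    summary["auc"] = roc.auc
    summary["cutoff_ng_ml"] = roc.cutoff
    summary["sensitivity"] = roc.sensitivity
    summary["specificity"] = roc.specificity
    if "time_months" in ds.plasma.columns:
        high = (ds.plasma["col1a1_ng_ml"] >= roc.cutoff).astype(float)
        cox = cox_univariate(ds.plasma["time_months"],
                             np.ones(len(ds.plasma), dtype=int), high)
        summary["hr"] = cox.hr
        summary["hr_ci"] = [cox.ci_low, cox.ci_high]
        summary["hr_p"] = cox.p
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    st.update({k: v for k, v in summary.items() if not isinstance(v, list)})

    manifest_path = out / "manifest.json"
    manifest["output_checksums"] = checksum_dir(out, exclude={"manifest.json"})
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def checksum_dir(path, exclude=frozenset()) -> dict[str, str]:
    """SHA-256 of every file directly under ``path`` (sorted by name)."""
    out = {}
    for f in sorted(Path(path).iterdir()):
        if f.is_file() and f.name not in exclude:
            out[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    return out


# ---------------------------------------------------------------------------
# input validation


EXPECTED_SCHEMAS = {
    "samples.tsv": ["sample_id", "condition"],
    "fibrosis.tsv": ["sample_id", "fibrosis_percent"],
    "survival.tsv": ["patient_id", "time_months", "event", "stream"],
    "plasma.tsv": ["patient_id", "col1a1_ng_ml", "group"],
}


def validate_inputs(dir_path) -> pd.DataFrame:
    """Schema check of a fixture directory.

    Returns a report DataFrame (file, n_rows, violations); an empty
    ``violations`` string means the file passed.
    """
    d = Path(dir_path)
    rows = []
    for name, cols in EXPECTED_SCHEMAS.items():
        f = d / name
        if not f.exists():
            rows.append((name, 0, "missing file"))
            continue
        df = pd.read_csv(f, sep="\t")
        problems = [f"missing column {c}" for c in cols if c not in df.columns]
        id_col = cols[0]
        if id_col in df.columns:
            dup_mask = df.duplicated(subset=[id_col])
            if name == "survival.tsv" and "stream" in df.columns:
                dup_mask = df.duplicated(subset=[id_col, "stream"])
            if dup_mask.any():
                problems.append(f"duplicate {id_col}")
        if name == "fibrosis.tsv" and "fibrosis_percent" in df.columns:
            vals = df["fibrosis_percent"]
            if ((vals < 0) | (vals > 100)).any():
                problems.append("fibrosis_percent outside [0, 100]")
        if name == "survival.tsv" and "time_months" in df.columns:
            if (df["time_months"] <= 0).any():
                problems.append("non-positive time_months")
        rows.append((name, len(df), "; ".join(problems)))
    for expr in sorted(d.glob("expression_*.tsv")):
        df = pd.read_csv(expr, sep="\t", index_col=0)
        problems = []
        if df.index.has_duplicates:
            problems.append("duplicate gene ids")
        if df.columns.has_duplicates:
            problems.append("duplicate sample ids")
        if (df.to_numpy(dtype=float) < 0).any():
            problems.append("negative abundances")
        rows.append((expr.name, len(df), "; ".join(problems)))
    return pd.DataFrame(rows, columns=["file", "n_rows", "violations"])
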