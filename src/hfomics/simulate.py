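"""Synthetic heart-failure cohort generator with planted ground truth.

Emulates the statistical structure the analysis assumes: a discovery cohort
of left-ventricle expression profiles (21 HF vs 9 control by default) at
three molecular levels, a histological fibrosis percentage driven by a
sparse linear model over a few genes, per-patient time-to-transplant
anti-correlated with one marker gene, and a 139-patient plasma validation
cohort split 29 (transplanted within a year of HF onset) vs 110.

Every planted feature — differentially expressed genes and their log2 fold
changes, miRNA->mRNA repressions, lncRNA->mRNA co-regulations,
miRNA-lncRNA-mRNA feed-forward triples, fibrosis coefficients, the survival
marker, plasma class labels — is recorded in a :class:`GroundTruth` object
so recovery can be measured exactly.

Model summary
-------------
* mRNA / lncRNA abundances are log-normal on the FPKM scale: per-gene
  baseline log2 mean ~ Uniform[0, 8], biological noise N(0, 0.5) in log2
  units.  Planted DE genes shift the HF group mean by their log2 fold
  change.
* miRNA abundances follow the same log-normal latent model and are then
  observed as negative-binomial read counts (dispersion 0.2) at a library
  size of 1e6 per sample.
* A planted repression rebuilds the target's biological noise as a
  variance-preserving mixture ``(eps - effect * z(regulator)) /
  sqrt(1 + effect^2)`` where z standardises the regulator's latent log2
  values *within each condition group*: the within-group sd stays at 0.5
  log2 units while the regulator-target correlation is
  ``-effect / sqrt(1 + effect^2)`` (about -0.89 at the default effect
  2.0).  Group means — hence planted fold changes — are untouched, so DE
  recovery and edge recovery are simultaneously attainable.
  Co-regulation uses ``+effect`` instead.
* Fibrosis percentage (HF samples with histology only) is
  ``50 + sum_g beta_g * z(log2 expr_g) + N(0, sd)`` clipped to [0, 100].
* Time to transplant is ``T0 * exp(-gamma * z(marker)) + noise`` months,
  truncated positive; every patient reaches transplant (no censoring).
* Plasma marker concentrations are class-conditional normals with equal
  spread; the separation delta is chosen so the designed AUC is
  ``Phi(delta / sqrt(2))``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .matrix import ExpressionMatrix

TOOLS = ("pita", "miranda", "targetscan")


# ---------------------------------------------------------------------------
# specifications


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the study design this generator emulates: 21 HF vs 9
    control discovery samples, fibrosis histology available for 18 of the
    21 HF samples, and a 139-patient plasma cohort split 29 early / 110
    late, with a designed plasma AUC of 0.789.
    """

    n_hf: int = 21
    n_control: int = 9
    n_mrna: int = 500
    n_lnc: int = 120
    n_mir: int = 150
    de_fraction: float = 0.1
    de_log2fc_range: tuple[float, float] = (1.5, 3.0)
    planted_edges: int = 15          # per regulator class (miRNA and lncRNA)
    planted_ffls: int = 2
    edge_effect: float = 2.0
    fibrosis_k: int = 5
    fibrosis_beta_range: tuple[float, float] = (2.0, 4.0)
    fibrosis_noise_sd: float = 2.0   # percentage points
    n_fibrosis: int | None = 18
    survival_marker: str | None = None
    survival_gamma: float = 0.6
    survival_t0: float = 24.0        # months
    survival_noise_sd: float = 1.0   # months
    plasma_n: int = 139
    plasma_n_early: int = 29
    plasma_auc: float = 0.789
    # late-group mean chosen so the designed decision threshold (midpoint
    # of the two class means) sits at 256.5 ng/ml for the default AUC
    plasma_mean_late: float = 222.4  # ng/ml
    plasma_sd: float = 60.0
    mirna_missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_hf=self.n_hf, n_control=self.n_control,
                      n_mrna=self.n_mrna, n_lnc=self.n_lnc, n_mir=self.n_mir,
                      plasma_n=self.plasma_n, plasma_n_early=self.plasma_n_early)
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not 0.0 < self.de_fraction < 1.0:
            raise ValueError("de_fraction must lie in (0, 1)")
        if self.n_hf + self.n_control < 4:
            raise ValueError("need at least 4 samples in total")
        if self.plasma_n_early > self.plasma_n:
            raise ValueError("plasma_n_early exceeds plasma_n")
        n_de_mrna = self.n_de("mRNA")
        n_de_lnc = self.n_de("lncRNA")
        n_de_mir = self.n_de("miRNA")
        needed_targets = 2 * self.planted_edges + self.planted_ffls
        if needed_targets > n_de_mrna:
            raise ValueError(
                f"planted edge count needs {needed_targets} distinct DE mRNA "
                f"targets but only {n_de_mrna} are available")
        if self.planted_edges + self.planted_ffls > n_de_mir * n_de_mrna:
            raise ValueError("planted miRNA edges exceed available node pairs")
        if self.planted_ffls > 0 and (n_de_mir == 0 or n_de_lnc == 0):
            raise ValueError("feed-forward triples need DE miRNAs and lncRNAs")
        if self.fibrosis_k > n_de_mrna:
            raise ValueError("fibrosis_k exceeds the number of DE mRNAs")
        n_fib = self.n_fibrosis if self.n_fibrosis is not None else self.n_hf
        if not 2 <= n_fib <= self.n_hf:
            raise ValueError("n_fibrosis must lie in [2, n_hf]")

    def n_de(self, level: str) -> int:
        n = {"mRNA": self.n_mrna, "lncRNA": self.n_lnc, "miRNA": self.n_mir}[level]
        return max(1, int(round(self.de_fraction * n)))


@dataclasses.dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    true_de: dict[str, dict[str, float]]          # level -> gene -> log2fc
    true_edges: list[tuple[str, str, str]]        # (regulator, target, sign)
    true_ffls: list[tuple[str, str, str]]         # (miRNA, lncRNA, mRNA)
    true_fibrosis: dict[str, float]               # gene -> beta (std units)
    fibrosis_intercept: float
    fibrosis_samples: list[str]
    true_marker: str
    plasma_class: dict[str, str]                  # patient -> le_1yr / gt_1yr

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["true_edges"] = [list(e) for e in self.true_edges]
        payload["true_ffls"] = [list(t) for t in self.true_ffls]
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["true_edges"] = [tuple(e) for e in d["true_edges"]]
        d["true_ffls"] = [tuple(t) for t in d["true_ffls"]]
        return cls(**d)

    def edges_of_kind(self, reg_prefix: str, tgt_prefix: str):
        return [(r, t, s) for r, t, s in self.true_edges
                if r.startswith(reg_prefix) and t.startswith(tgt_prefix)]


@dataclasses.dataclass
class SyntheticCohort:
    """Everything :func:`generate_cohort` produces."""

    spec: CohortSpec
    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    samples: pd.DataFrame          # sample_id -> condition, sex, age
    fibrosis: pd.DataFrame         # sample_id, fibrosis_percent
    survival: pd.DataFrame         # patient_id, time_months, event, stream
    plasma: pd.DataFrame           # patient_id, col1a1_ng_ml, group, time_months
    targets: dict[str, pd.DataFrame]   # tool -> (mirna_id, gene_id)
    validated: pd.DataFrame            # (mirna_id, gene_id)
    truth: GroundTruth


# ---------------------------------------------------------------------------
# generation helpers


BIO_SD = 0.5  # biological noise, log2 units


def _group_z(latent_row: np.ndarray, is_hf: np.ndarray) -> np.ndarray:
    """Standardise within each condition group (zero group means, unit sd)."""
    out = np.empty_like(latent_row)
    for mask in (is_hf, ~is_hf):
        v = latent_row[mask]
        sd = v.std()
        out[mask] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    return out


def _latent_parts(rng, n_genes, n_samples, is_hf, de_genes_idx, log2fc):
    """Systematic part (baseline + DE shift) and unit-variance noise."""
    base = rng.uniform(0.0, 8.0, size=n_genes)
    systematic = np.repeat(base[:, None], n_samples, axis=1)
    for idx, fc in zip(de_genes_idx, log2fc):
        systematic[idx, is_hf] += fc
    eps = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    return systematic, eps


def _regulated_row(systematic_row, eps_row, contribs):
    """Row with noise correlated to its regulators, variance preserved.

    ``contribs`` is a list of (coefficient, group-standardised regulator)
    pairs.  The within-group sd stays at BIO_SD while the within-group
    correlation with regulator i is ``c_i / sqrt(1 + sum c^2)`` — effect
    2.0 gives |rho| ~ 0.89.  Group means (hence fold changes) are
    untouched, so planted DE calls remain recoverable.
    """
    total = sum(c * z for c, z in contribs)
    norm = np.sqrt(1.0 + sum(c * c for c, _ in contribs))
    return systematic_row + BIO_SD * (total + eps_row) / norm


def _pick_de(rng, n_genes: int, n_de: int, lo: float, hi: float):
    idx = np.sort(rng.choice(n_genes, size=n_de, replace=False))
    mags = rng.uniform(lo, hi, size=n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    return idx, mags * signs


def _nb_counts(rng, latent: np.ndarray, dispersion: float, libsize: float):
    rel = np.exp2(latent)
    mu = rel / rel.sum(axis=0, keepdims=True) * libsize
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam).astype(float)


# ---------------------------------------------------------------------------
# main entry point


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground truth.

    Identical specs (including seed) produce identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n = spec.n_hf + spec.n_control
    sample_ids = [f"D{i+1:02d}" for i in range(spec.n_hf)] + \
                 [f"C{i+1:02d}" for i in range(spec.n_control)]
    is_hf = np.array([s.startswith("D") for s in sample_ids])
    condition = pd.Series(np.where(is_hf, "HF", "control"),
                          index=pd.Index(sample_ids, name="sample_id"))

    genes = {
        "mRNA": [f"GENE{i+1:04d}" for i in range(spec.n_mrna)],
        "lncRNA": [f"LNC{i+1:04d}" for i in range(spec.n_lnc)],
        "miRNA": [f"MIR{i+1:04d}" for i in range(spec.n_mir)],
    }

    # planted DE structure and latent log2 matrices, one level at a time
    lo, hi = spec.de_log2fc_range
    systematic, eps, latent, true_de = {}, {}, {}, {}
    for level, ids in genes.items():
        idx, fcs = _pick_de(rng, len(ids), spec.n_de(level), lo, hi)
        systematic[level], eps[level] = _latent_parts(
            rng, len(ids), n, is_hf, idx, fcs)
        latent[level] = systematic[level] + BIO_SD * eps[level]
        true_de[level] = {ids[i]: float(fc) for i, fc in zip(idx, fcs)}

    de_mrna = list(true_de["mRNA"])
    de_lnc = list(true_de["lncRNA"])
    de_mir = list(true_de["miRNA"])
    gidx = {lvl: {g: i for i, g in enumerate(ids)} for lvl, ids in genes.items()}

    # planted regulatory structure: FFL triples first, then plain edges,
    # each on its own distinct DE mRNA target
    tgt_pool = list(rng.permutation(de_mrna))
    true_edges: list[tuple[str, str, str]] = []
    true_ffls: list[tuple[str, str, str]] = []
    eff = spec.edge_effect

    def _apply(level, gene, contribs):
        i = gidx[level][gene]
        latent[level][i] = _regulated_row(systematic[level][i],
                                          eps[level][i], contribs)

    for k in range(spec.planted_ffls):
        m = de_mir[k % len(de_mir)]
        l = de_lnc[k % len(de_lnc)]
        g = tgt_pool.pop()
        zm = _group_z(latent["miRNA"][gidx["miRNA"][m]], is_hf)
        _apply("lncRNA", l, [(-0.8 * eff, zm)])
        zl = _group_z(latent["lncRNA"][gidx["lncRNA"][l]], is_hf)
        _apply("mRNA", g, [(-eff, zm), (eff, zl)])
        true_edges += [(m, g, "negative"), (l, g, "positive"), (m, l, "negative")]
        true_ffls.append((m, l, g))

    for k in range(spec.planted_edges):
        m = de_mir[(spec.planted_ffls + k) % len(de_mir)]
        g = tgt_pool.pop()
        zm = _group_z(latent["miRNA"][gidx["miRNA"][m]], is_hf)
        _apply("mRNA", g, [(-eff, zm)])
        true_edges.append((m, g, "negative"))

    for k in range(spec.planted_edges):
        l = de_lnc[(spec.planted_ffls + k) % len(de_lnc)]
        g = tgt_pool.pop()
        zl = _group_z(latent["lncRNA"][gidx["lncRNA"][l]], is_hf)
        _apply("mRNA", g, [(eff, zl)])
        true_edges.append((l, g, "positive"))

    # observed abundances
    fpkm = {lvl: np.exp2(latent[lvl]) for lvl in ("mRNA", "lncRNA")}
    counts = _nb_counts(rng, latent["miRNA"], dispersion=0.2, libsize=1e6)
    if spec.mirna_missing_rate > 0:
        mask = rng.random(counts.shape) < spec.mirna_missing_rate
        counts = np.where(mask, np.nan, counts)

    mats = {
        "mRNA": ExpressionMatrix("mRNA", pd.DataFrame(
            fpkm["mRNA"], index=genes["mRNA"], columns=sample_ids), condition),
        "lncRNA": ExpressionMatrix("lncRNA", pd.DataFrame(
            fpkm["lncRNA"], index=genes["lncRNA"], columns=sample_ids), condition),
        "miRNA": ExpressionMatrix("miRNA", pd.DataFrame(
            counts, index=genes["miRNA"], columns=sample_ids), condition),
    }

    # fibrosis: sparse linear model over standardised log2 expression of the
    # HF samples that have histology
    n_fib = spec.n_fibrosis if spec.n_fibrosis is not None else spec.n_hf
    hf_ids = [s for s in sample_ids if s.startswith("D")]
    fib_samples = sorted(rng.choice(hf_ids, size=n_fib, replace=False))
    remaining = [g for g in tgt_pool if g not in set(t for _, t, _ in true_edges)]
    if len(remaining) >= spec.fibrosis_k:
        fib_pool = remaining
    else:
        fib_pool = de_mrna
    fib_genes = sorted(rng.choice(fib_pool, size=spec.fibrosis_k, replace=False))
    blo, bhi = spec.fibrosis_beta_range
    betas = rng.uniform(blo, bhi, size=spec.fibrosis_k) * \
        rng.choice([-1.0, 1.0], size=spec.fibrosis_k)
    log2_fib = np.log2(mats["mRNA"].values.loc[fib_genes, fib_samples].to_numpy())
    z = (log2_fib - log2_fib.mean(axis=1, keepdims=True)) / \
        log2_fib.std(axis=1, keepdims=True)
    intercept = 50.0
    fib_vals = intercept + betas @ z
    if spec.fibrosis_noise_sd > 0:
        fib_vals = fib_vals + rng.normal(0.0, spec.fibrosis_noise_sd, size=n_fib)
    fib_vals = np.clip(fib_vals, 0.0, 100.0)
    fibrosis = pd.DataFrame({"sample_id": fib_samples,
                             "fibrosis_percent": fib_vals})

    # survival: time to transplant decreasing in the marker gene
    marker = spec.survival_marker
    if marker is None:
        pos = [g for g, b in zip(fib_genes, betas) if b > 0]
        marker = pos[0] if pos else fib_genes[int(np.argmax(np.abs(betas)))]
    if marker not in gidx["mRNA"]:
        raise ValueError(f"survival marker {marker!r} is not a generated mRNA")
    log2_marker = np.log2(mats["mRNA"].values.loc[marker, hf_ids].to_numpy())
    zm = (log2_marker - log2_marker.mean()) / log2_marker.std()
    t_onset = spec.survival_t0 * np.exp(-spec.survival_gamma * zm)
    t_onset = np.maximum(t_onset + rng.normal(0.0, spec.survival_noise_sd,
                                              size=spec.n_hf), 0.5)
    t_symptom = t_onset + rng.uniform(2.0, 12.0, size=spec.n_hf)
    survival = pd.DataFrame({
        "patient_id": hf_ids * 2,
        "time_months": np.concatenate([t_symptom, t_onset]),
        "event": 1,
        "stream": ["initial_symptom"] * spec.n_hf + ["hf_onset"] * spec.n_hf,
    })

    # plasma validation cohort: class-conditional normals with designed AUC
    delta = float(np.sqrt(2.0) * norm.ppf(spec.plasma_auc))
    labels = np.array(["le_1yr"] * spec.plasma_n_early +
                      ["gt_1yr"] * (spec.plasma_n - spec.plasma_n_early))
    labels = rng.permutation(labels)
    early = labels == "le_1yr"
    conc = rng.normal(spec.plasma_mean_late, spec.plasma_sd, size=spec.plasma_n)
    conc[early] += delta * spec.plasma_sd
    conc = np.maximum(conc, 1.0)
    t_plasma = np.where(early, rng.uniform(1.0, 12.0, size=spec.plasma_n),
                        rng.uniform(13.0, 72.0, size=spec.plasma_n))
    patient_ids = [f"P{i+1:03d}" for i in range(spec.plasma_n)]
    plasma = pd.DataFrame({"patient_id": patient_ids,
                           "col1a1_ng_ml": conc,
                           "group": labels,
                           "time_months": t_plasma})

    # miRNA-target evidence files: every planted miRNA->mRNA/lncRNA pair is
    # supported by >= 2 predictors; decoy pairs are mostly single-tool
    targets, validated = _target_evidence(rng, true_edges, genes)

    sex = np.where(is_hf, rng.random(n) < 13 / 21, True)
    age = np.where(is_hf, rng.normal(34.6, 15.9, size=n),
                   rng.normal(41.7, 4.0, size=n))
    samples = pd.DataFrame({
        "condition": condition.to_numpy(),
        "sex": np.where(sex, "male", "female"),
        "age": np.clip(age, 18.0, 75.0).round(1),
    }, index=condition.index)

    truth = GroundTruth(
        true_de=true_de,
        true_edges=true_edges,
        true_ffls=true_ffls,
        true_fibrosis={g: float(b) for g, b in zip(fib_genes, betas)},
        fibrosis_intercept=intercept,
        fibrosis_samples=list(fib_samples),
        true_marker=marker,
        plasma_class=dict(zip(patient_ids, labels)),
    )
    return SyntheticCohort(spec, mats["mRNA"], mats["lncRNA"], mats["miRNA"],
                           samples, fibrosis, survival, plasma,
                           targets, validated, truth)


def _target_evidence(rng, true_edges, genes):
    """Build per-tool predicted target lists plus a validated list."""
    mir_pairs = [(r, t) for r, t, _ in true_edges if r.startswith("MIR")
                 and t.startswith("GENE")]
    tool_sets: dict[str, set] = {tool: set() for tool in TOOLS}
    validated_pairs: set = set()
    for pair in mir_pairs:
        k = 2 + int(rng.random() < 0.4)
        for tool in rng.choice(TOOLS, size=k, replace=False):
            tool_sets[tool].add(pair)
        if rng.random() < 0.15:
            validated_pairs.add(pair)
    # decoys: random non-planted pairs, mostly supported by a single tool
    n_decoy = 3 * max(len(mir_pairs), 1)
    taken = set(mir_pairs)
    made = 0
    while made < n_decoy:
        pair = (str(rng.choice(genes["miRNA"])), str(rng.choice(genes["mRNA"])))
        if pair in taken:
            continue
        taken.add(pair)
        u = rng.random()
        k = 1 if u < 0.5 else (2 if u < 0.85 else 3)
        for tool in rng.choice(TOOLS, size=k, replace=False):
            tool_sets[tool].add(pair)
        if rng.random() < 0.05:
            validated_pairs.add(pair)
        made += 1
    targets = {tool: pd.DataFrame(sorted(pairs),
                                  columns=["mirna_id", "gene_id"])
               for tool, pairs in tool_sets.items()}
    validated = pd.DataFrame(sorted(validated_pairs),
                             columns=["mirna_id", "gene_id"])
    return targets, validated


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(dataset: SyntheticCohort, dir_path) -> list[Path]:
    """Write a cohort to TSV/JSON files; round-trips via :func:`read_fixture`."""
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str, index=False):
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        written.append(path)

    for mat, name in ((dataset.mrna, "expression_mrna.tsv"),
                      (dataset.lncrna, "expression_lncrna.tsv"),
                      (dataset.mirna, "expression_mirna.tsv")):
        df = mat.values.copy()
        df.index.name = "gene_id"
        _write(df, name, index=True)
    _write(dataset.samples.reset_index(), "samples.tsv")
    _write(dataset.fibrosis, "fibrosis.tsv")
    _write(dataset.survival, "survival.tsv")
    _write(dataset.plasma, "plasma.tsv")
    for tool, df in dataset.targets.items():
        _write(df, f"targets_{tool}.tsv")
    _write(dataset.validated, "validated_targets.tsv")
    truth_path = out / "truth.json"
    dataset.truth.to_json(truth_path)
    written.append(truth_path)
    return written


def read_fixture(dir_path) -> SyntheticCohort:
    """Read a cohort written by :func:`write_fixture` (spec not recoverable)."""
    d = Path(dir_path)
    samples = pd.read_csv(d / "samples.tsv", sep="\t").set_index("sample_id")
    condition = samples["condition"]

    def _mat(name, level):
        df = pd.read_csv(d / name, sep="\t", index_col=0,
                         float_precision="round_trip")
        df.index = df.index.astype(str)
        return ExpressionMatrix(level, df, condition.copy())

    targets = {tool: pd.read_csv(d / f"targets_{tool}.tsv", sep="\t")
               for tool in TOOLS}
    truth_file = d / "truth.json"
    truth = GroundTruth.from_json(truth_file) if truth_file.exists() else None
    return SyntheticCohort(
        spec=None,
        mrna=_mat("expression_mrna.tsv", "mRNA"),
        lncrna=_mat("expression_lncrna.tsv", "lncRNA"),
        mirna=_mat("expression_mirna.tsv", "miRNA"),
        samples=samples,
        fibrosis=pd.read_csv(d / "fibrosis.tsv", sep="\t", float_precision="round_trip"),
        survival=pd.read_csv(d / "survival.tsv", sep="\t", float_precision="round_trip"),
        plasma=pd.read_csv(d / "plasma.tsv", sep="\t", float_precision="round_trip"),
        targets=targets,
        validated=pd.read_csv(d / "validated_targets.tsv", sep="\t"),
        truth=truth,
    )
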