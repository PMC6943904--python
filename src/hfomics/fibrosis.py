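"""Fibrosis-associated gene selection.

Two complementary analyses link gene expression to the histological
fibrosis percentage of HF samples:

* a correlation-set comparison: per-gene Spearman correlations with
  fibrosis for named gene sets (e.g. DE genes vs literature sets) plus a
  size-matched random set, and
* an L1-penalised (lasso) regression of fibrosis percentage on
  standardised expression, solved by cyclic coordinate descent with the
  penalty weight chosen by k-fold cross-validation.  Genes with non-zero
  coefficients are the selected fibrosis genes.

The lasso solver minimises ``(1/2n)||y - b0 - X beta||^2 + lambda ||beta||_1``
and is written here in full: coordinate updates by soft-thresholding,
convergence when the largest coefficient change in a sweep falls below
1e-8, and a KKT verification utility used by the test-suite on every fit.
The p > n regime (more candidate genes than samples) is accepted.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .stats import spearman

MAX_SWEEPS = 200_000
TOL = 1e-8

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is an optional accelerator
    njit = None


@dataclasses.dataclass
class LassoFit:
    """Result of a lasso fit on standardised predictors.

    ``beta`` is on the standardised-predictor scale (response units per SD
    of log2 expression); ``beta_raw`` is rescaled to the original predictor
    units.  ``selected`` lists genes with non-zero coefficients.
    """

    lam: float
    genes: list[str]
    beta: np.ndarray
    beta_raw: np.ndarray
    intercept: float
    selected: list[str]
    cv_lambdas: np.ndarray | None = None
    cv_mse: np.ndarray | None = None
    seed: int | None = None

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.genes,
            "beta_standardized": self.beta,
            "beta_raw": self.beta_raw,
            "selected": self.beta != 0.0,
        })


def soft_threshold(z: float | np.ndarray, lam: float):
    """S(z, lam) = sign(z) * max(|z| - lam, 0)."""
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is zero: max|X'(y-ybar)|/n."""
    n = X.shape[0]
    r = y - y.mean()
    return float(np.max(np.abs(X.T @ r)) / n)


def _cd_sweeps(G, c, diag, beta, lam, tol, max_sweeps):
    """Cyclic coordinate-descent passes on the covariance formulation.

    Mutates ``beta`` in place; returns the number of passes used, or -1 on
    non-convergence.  A full pass over all coordinates alternates with
    passes restricted to the current non-zero (active) set.
    """
    p = beta.shape[0]
    q = c - G @ beta                 # (1/n) X' r for the current beta
    sweeps = 0
    while sweeps < max_sweeps:
        # full pass
        max_delta = 0.0
        for j in range(p):
            dj = diag[j]
            if dj == 0.0:
                continue
            bj = beta[j]
            z = q[j] + dj * bj
            new = np.sign(z) * max(abs(z) - lam, 0.0) / dj
            if new != bj:
                q -= G[:, j] * (new - bj)
                beta[j] = new
                if abs(new - bj) > max_delta:
                    max_delta = abs(new - bj)
        sweeps += 1
        if max_delta < tol:
            return sweeps
        # active-set passes
        active = np.nonzero(beta)[0]
        while sweeps < max_sweeps:
            max_delta = 0.0
            for j in active:
                dj = diag[j]
                if dj == 0.0:
                    continue
                bj = beta[j]
                z = q[j] + dj * bj
                new = np.sign(z) * max(abs(z) - lam, 0.0) / dj
                if new != bj:
                    q -= G[:, j] * (new - bj)
                    beta[j] = new
                    if abs(new - bj) > max_delta:
                        max_delta = abs(new - bj)
            sweeps += 1
            if max_delta < tol:
                break
    return -1 if sweeps >= max_sweeps else sweeps


if njit is not None:
    _cd_sweeps = njit(cache=False)(_cd_sweeps)


def coordinate_descent_lasso(X: np.ndarray, y: np.ndarray, lam: float,
                             beta0: np.ndarray | None = None,
                             max_sweeps: int = MAX_SWEEPS,
                             tol: float = TOL):
    """Cyclic coordinate descent for the lasso.

    X must have centred columns (the intercept is then the response mean).
    Convergence: no coefficient changes by ``tol`` or more during a full
    pass.  Returns ``(beta, intercept)``; raises on non-convergence.
    """
    n, p = X.shape
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    intercept = float(y.mean())
    yc = y - intercept
    G = np.ascontiguousarray(X.T @ X / n)
    c = X.T @ yc / n
    diag = np.diag(G).copy()
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    sweeps = _cd_sweeps(G, c, diag, beta, float(lam), float(tol),
                        int(max_sweeps))
    if sweeps < 0:
        raise RuntimeError(
            f"lasso failed to converge after {max_sweeps} sweeps "
            f"(lambda={lam:.3g})")
    return beta, intercept


def kkt_violation(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                  intercept: float, lam: float) -> float:
    """Largest violation of the lasso KKT subgradient conditions.

    For active coefficients ``(1/n) X_j' r`` must equal ``lam * sign(beta_j)``;
    for zero coefficients its magnitude must not exceed ``lam``.
    Returns the worst absolute violation (0 for an exact solution).
    """
    n = X.shape[0]
    grad = X.T @ (y - intercept - X @ beta) / n
    active = beta != 0.0
    v_active = np.abs(grad[active] - lam * np.sign(beta[active]))
    v_zero = np.maximum(np.abs(grad[~active]) - lam, 0.0)
    parts = np.concatenate([v_active, v_zero, [0.0]])
    return float(parts.max())


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def lasso_fit(X: np.ndarray, y: np.ndarray, lam: float,
              genes: list[str] | None = None) -> LassoFit:
    """Fit the lasso at a single penalty on standardised predictors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be samples x genes aligned with y")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    Xs, _, sd = _standardize(X)
    beta, intercept = coordinate_descent_lasso(Xs, y, lam)
    genes = genes if genes is not None else [f"x{j}" for j in range(X.shape[1])]
    selected = [g for g, b in zip(genes, beta) if b != 0.0]
    return LassoFit(lam=lam, genes=list(genes), beta=beta,
                    beta_raw=beta / sd, intercept=intercept, selected=selected)


def lasso_path(Xs: np.ndarray, y: np.ndarray, n_lambdas: int = 50,
               decades: float = 3.0) -> np.ndarray:
    """Log-spaced penalty path from lambda_max down ``decades`` decades."""
    lmax = lambda_max(Xs, y)
    if lmax == 0.0:
        raise ValueError("degenerate response: lambda_max is zero")
    return np.geomspace(lmax, lmax * 10.0**-decades, n_lambdas)


def cv_mse_path(Xs: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
                cv_folds: int, seed: int) -> np.ndarray:
    """Mean cross-validated squared error per penalty (warm-started)."""
    n = Xs.shape[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, cv_folds)
    sse = np.zeros(len(lambdas))
    for hold in folds:
        train = np.setdiff1d(order, hold, assume_unique=False)
        Xtr, ytr = Xs[train], y[train]
        Xte, yte = Xs[hold], y[hold]
        beta = np.zeros(Xs.shape[1])
        for i, lam in enumerate(lambdas):
            beta, b0 = coordinate_descent_lasso(Xtr, ytr, lam, beta0=beta)
            resid = yte - b0 - Xte @ beta
            sse[i] += (resid**2).sum()
    return sse / n


def select_fibrosis_genes(mat_hf: ExpressionMatrix, fibrosis: pd.DataFrame,
                          candidates, cv_folds: int = 5, seed: int = 0,
                          lam: float | None = None,
                          n_lambdas: int = 50) -> LassoFit:
    """Lasso selection of fibrosis-associated genes among candidate DEGs.

    Expression is log2-transformed and standardised per gene; the response
    stays in fibrosis percentage points.  Unless ``lam`` is given, the
    penalty minimising k-fold cross-validated MSE along a log-spaced path
    (3 decades below lambda_max) is used; ties go to the larger (sparser)
    penalty.  The model is refit on all samples at the chosen penalty.
    """
    candidates = [g for g in candidates]
    missing = [g for g in candidates if g not in mat_hf.values.index]
    if missing:
        raise ValueError(f"candidate genes absent from matrix: {missing[:5]}")
    fib = fibrosis.set_index("sample_id")["fibrosis_percent"]
    common = [s for s in mat_hf.sample_ids if s in fib.index]
    if len(common) < cv_folds:
        raise ValueError("fewer fibrosis samples than CV folds")
    y = fib.loc[common].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: fibrosis is constant")
    X = np.log2(mat_hf.values.loc[candidates, common].to_numpy(dtype=float).T
                + 1.0)
    Xs, _, sd = _standardize(X)
    if lam is None:
        lambdas = lasso_path(Xs, y, n_lambdas=n_lambdas)
        mse = cv_mse_path(Xs, y, lambdas, cv_folds, seed)
        best = mse.min()
        # ties (within numerical noise) resolved toward the sparser model;
        # lambdas are sorted descending so take the first near-minimum
        lam = float(lambdas[np.argmax(mse <= best * (1 + 1e-10))])
        cv_lambdas, cv_mse = lambdas, mse
    else:
        cv_lambdas = cv_mse = None
    beta, intercept = coordinate_descent_lasso(Xs, y, lam)
    selected = [g for g, b in zip(candidates, beta) if b != 0.0]
    return LassoFit(lam=lam, genes=candidates, beta=beta, beta_raw=beta / sd,
                    intercept=intercept, selected=selected,
                    cv_lambdas=cv_lambdas, cv_mse=cv_mse, seed=seed)


def correlation_set_comparison(mat_hf: ExpressionMatrix,
                               fibrosis: pd.DataFrame,
                               gene_sets: dict[str, set],
                               n_random: int | None = None,
                               seed: int = 0) -> dict[str, pd.DataFrame]:
    """Per-set distributions of gene-fibrosis Spearman correlations.

    For each named gene set, the Spearman rho (and p) of every member gene
    against fibrosis percentage across the samples with histology.  A
    size-matched ``random`` set (size of the first set, or ``n_random``)
    drawn from the matrix genes is appended for reference.
    """
    fib = fibrosis.set_index("sample_id")["fibrosis_percent"]
    common = [s for s in mat_hf.sample_ids if s in fib.index]
    if len(common) < 3:
        raise ValueError("need at least 3 samples with fibrosis data")
    y = fib.loc[common].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    def _set_table(genes) -> pd.DataFrame:
        rows = []
        for g in sorted(genes):
            if g not in mat_hf.values.index:
                warnings.warn(f"gene {g} absent from matrix; dropped")
                continue
            x = mat_hf.values.loc[g, common].to_numpy(dtype=float)
            try:
                rho, p = spearman(x, y)
            except ValueError:
                continue
            rows.append((g, rho, p))
        return pd.DataFrame(rows, columns=["gene", "rho", "p"])

    out = {name: _set_table(genes) for name, genes in gene_sets.items()}
    size = n_random if n_random is not None else \
        (len(next(iter(gene_sets.values()))) if gene_sets else 0)
    if size:
        random_genes = rng.choice(mat_hf.gene_ids, size=min(size, mat_hf.n_genes),
                                  replace=False)
        out["random"] = _set_table(random_genes)
    return out
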