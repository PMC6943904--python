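"""Survival and biomarker evaluation.

Links gene expression and plasma marker concentrations to time-to-heart-
transplant: per-gene Pearson screening against survival time, Kaplan-Meier
curves for median-split groups with the Mantel-Cox log-rank test, a
univariate Cox proportional-hazards fit (Newton-Raphson on the Breslow
partial likelihood) for hazard ratios with Wald intervals, ROC analysis
with the Youden-index optimal cutoff, qRT-PCR relative quantification by
the 2^-ddCt rule, and the cohort-summary statistics (Welch t-test for
continuous covariates, Fisher's exact test for 2x2 counts).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import ExpressionMatrix
from .stats import pearson, welch_ttest


# ---------------------------------------------------------------------------
# containers


@dataclasses.dataclass
class KMEstimate:
    """Product-limit survival estimate."""

    times: np.ndarray           # distinct event times, ascending
    survival: np.ndarray        # S(t) just after each event time
    at_risk: np.ndarray         # risk-set size at each event time
    n_events: np.ndarray

    def step_function(self):
        """(t, S) points for a right-continuous step plot, starting at (0, 1)."""
        t = np.concatenate([[0.0], self.times])
        s = np.concatenate([[1.0], self.survival])
        return t, s


@dataclasses.dataclass
class LogRankResult:
    chi_square: float
    p: float
    n_groups: tuple[int, int]


@dataclasses.dataclass
class CoxFit:
    coef: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_events: int
    converged: bool


@dataclasses.dataclass
class ROCResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    curve: pd.DataFrame    # threshold, fpr, tpr


# ---------------------------------------------------------------------------
# screening and grouping


def survival_gene_screen(mat_hf: ExpressionMatrix, surv: pd.DataFrame,
                         stream: str = "hf_onset",
                         events_only: bool = True) -> pd.DataFrame:
    """Per-gene Pearson correlation between expression and survival time.

    Censored records are excluded by default (the emulated study observed
    transplantation for every patient).  Returns a DataFrame with columns
    gene, r, p; constant-expression genes get NaN and a ``flagged`` mark.
    """
    sub = surv[surv["stream"] == stream] if "stream" in surv.columns else surv
    if events_only and "event" in sub.columns:
        sub = sub[sub["event"] == 1]
    sub = sub.set_index("patient_id")["time_months"]
    common = [s for s in mat_hf.sample_ids if s in sub.index]
    if len(common) < 3:
        raise ValueError("need at least 3 patients with expression and time")
    t = sub.loc[common].to_numpy(dtype=float)
    rows = []
    for g in mat_hf.gene_ids:
        x = mat_hf.values.loc[g, common].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append((g, np.nan, np.nan, True))
            continue
        r, p = pearson(x, t)
        rows.append((g, r, p, False))
    return pd.DataFrame(rows, columns=["gene", "r", "p", "flagged"])


def median_split(values: pd.Series) -> pd.Series:
    """Dichotomise at the median: ``high`` for values >= median, else ``low``.

    Ties at the median go to the high group.  Raises if all values are
    identical (a single group is not a split).
    """
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise ValueError("need at least 2 patients")
    if values.nunique() == 1:
        raise ValueError("all values identical: cannot split at the median")
    med = float(values.median())
    return pd.Series(np.where(values >= med, "high", "low"),
                     index=values.index)


# ---------------------------------------------------------------------------
# survival estimation and tests


def _check_surv(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be 1-d of equal length")
    if (time <= 0).any():
        raise ValueError("times must be positive")
    return time, event


def kaplan_meier(time, event) -> KMEstimate:
    """Product-limit estimator of the survival function.

    Censored observations (event = 0) leave the risk set without an event
    step.  The estimate is defined at distinct event times.
    """
    time, event = _check_surv(time, event)
    n = time.size
    order = np.lexsort((1 - event, time))
    time, event = time[order], event[order]
    etimes, surv, at_risk, n_ev = [], [], [], []
    s = 1.0
    for t in np.unique(time[event == 1]):
        r = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d / r
        etimes.append(t)
        surv.append(s)
        at_risk.append(r)
        n_ev.append(d)
    return KMEstimate(np.array(etimes), np.array(surv),
                      np.array(at_risk), np.array(n_ev))


def log_rank(time_a, event_a, time_b, event_b) -> LogRankResult:
    """Mantel-Cox two-group log-rank test.

    Chi-square statistic ``(O - E)^2 / V`` with the hypergeometric variance
    at each distinct event time; p from chi-square with 1 df.
    """
    ta, ea = _check_surv(time_a, event_a)
    tb, eb = _check_surv(time_b, event_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("need at least one event")
    all_t = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_t:
        n1 = np.sum(ta >= t)
        n2 = np.sum(tb >= t)
        d1 = np.sum((ta == t) & (ea == 1))
        d2 = np.sum((tb == t) & (eb == 1))
        n, d = n1 + n2, d1 + d2
        if n < 1:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        chi, p = 0.0, 1.0
    else:
        chi = o_minus_e**2 / var
        p = float(sps.chi2.sf(chi, df=1))
    return LogRankResult(float(chi), p, (ta.size, tb.size))


def cox_univariate(time, event, covariate, max_iter: int = 100,
                   tol: float = 1e-10) -> CoxFit:
    """Univariate Cox proportional-hazards fit.

    Newton-Raphson maximisation of the Breslow partial likelihood; Wald
    95% interval ``exp(coef +/- 1.96 se)``.  A diverging coefficient
    (monotone likelihood / complete separation) is reported with
    ``converged=False``.
    """
    time, event = _check_surv(time, event)
    x = np.asarray(covariate, dtype=float)
    if x.shape != time.shape:
        raise ValueError("covariate must align with time")
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    if np.ptp(x) == 0:
        raise ValueError("covariate does not vary")
    order = np.argsort(time)
    time, event, x = time[order], event[order], x[order]
    etimes = np.unique(time[event == 1])

    def derivatives(beta):
        """Log-likelihood, score and information under Breslow ties."""
        w = np.exp(beta * x)
        ll = score = info = 0.0
        for t in etimes:
            risk = time >= t
            ev = (time == t) & (event == 1)
            d = ev.sum()
            s0 = w[risk].sum()
            s1 = (w[risk] * x[risk]).sum()
            s2 = (w[risk] * x[risk]**2).sum()
            ll += beta * x[ev].sum() - d * np.log(s0)
            score += x[ev].sum() - d * s1 / s0
            info += d * (s2 / s0 - (s1 / s0)**2)
        return ll, score, info

    beta, converged = 0.0, False
    for _ in range(max_iter):
        ll, score, info = derivatives(beta)
        if info <= 0:
            break
        step = score / info
        # step-halving keeps the likelihood non-decreasing
        while abs(step) > 1e-12:
            if derivatives(beta + step)[0] >= ll - 1e-12:
                break
            step /= 2.0
        beta += step
        if abs(step) < tol:
            converged = True
            break
    if abs(beta) > 20:
        converged = False
    _, _, info = derivatives(beta)
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2.0 * sps.norm.sf(abs(z)))
    return CoxFit(coef=float(beta), se=float(se), hr=float(np.exp(beta)),
                  ci_low=float(np.exp(beta - 1.96 * se)),
                  ci_high=float(np.exp(beta + 1.96 * se)),
                  p=p, n_events=int(event.sum()), converged=converged)


# ---------------------------------------------------------------------------
# ROC / cutoff


def roc_analysis(values, labels, positive: str = "le_1yr") -> ROCResult:
    """ROC of a continuous marker against a binary outcome.

    AUC is the Mann-Whitney concordance (ties count 1/2).  The reported
    cutoff maximises the Youden index J = sensitivity + specificity - 1
    over midpoints between consecutive sorted unique values (plus the two
    infinite thresholds); ties in J are broken toward the lower cutoff.
    A value is called positive when it is >= the cutoff.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present")
    xp, xn = values[pos], values[~pos]
    # concordance AUC
    greater = (xp[:, None] > xn[None, :]).sum()
    equal = (xp[:, None] == xn[None, :]).sum()
    auc = (greater + 0.5 * equal) / (xp.size * xn.size)
    # candidate thresholds
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[np.inf], uniq[::-1], mids[::-1], [-np.inf]])
    thresholds = np.unique(thresholds)[::-1]
    tpr = np.array([(xp >= c).mean() for c in thresholds])
    fpr = np.array([(xn >= c).mean() for c in thresholds])
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    cand = np.concatenate([[np.inf], mids, [-np.inf]])
    j = np.array([(xp >= c).mean() - (xn >= c).mean() for c in cand])
    best = j.max()
    # ties toward the lower cutoff
    cutoff = float(cand[j >= best - 1e-12].min())
    sens = float((xp >= cutoff).mean())
    spec = float((xn < cutoff).mean())
    return ROCResult(float(auc), cutoff, sens, spec, curve)


def trapezoid_auc(curve: pd.DataFrame) -> float:
    """Area under the (fpr, tpr) curve by the trapezoid rule."""
    df = curve.sort_values("fpr", kind="stable")
    return float(np.trapezoid(df["tpr"], df["fpr"]))


# ---------------------------------------------------------------------------
# group comparison, qPCR and cohort summary


def group_mean_compare(a, b) -> dict:
    """Welch comparison of two measurement groups, summarised as mean +/- SEM."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 measurements")
    t, p = welch_ttest(a, b)
    return {
        "mean_a": float(a.mean()), "sem_a": float(a.std(ddof=1) / np.sqrt(a.size)),
        "mean_b": float(b.mean()), "sem_b": float(b.std(ddof=1) / np.sqrt(b.size)),
        "t": t, "p": p,
    }


def ddct_fold_change(ct_target, ct_reference, is_control) -> np.ndarray:
    """Relative expression by the 2^-ddCt rule.

    dCt = Ct_target - Ct_reference per sample; ddCt subtracts the mean dCt
    of the control group; fold change is 2^-ddCt (so the control-group
    *mean ddCt* is zero and its mean fold change on the log scale is 1).
    """
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    is_control = np.asarray(is_control, dtype=bool)
    if np.isnan(ct_reference).any():
        raise ValueError("reference-gene Ct values are required for every sample")
    if not is_control.any():
        raise ValueError("need at least one control sample")
    dct = ct_target - ct_reference
    ddct = dct - dct[is_control].mean()
    return np.exp2(-ddct)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 table.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("expected a 2x2 table of non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def cohort_summary(samples: pd.DataFrame, condition_col: str = "condition",
                   case_label: str = "HF") -> pd.DataFrame:
    """Cohort characteristics table.

    Categorical covariates are reported as count (percentage of the case
    denominator); continuous covariates as mean +/- SD per condition with
    a Welch t-test p-value where both groups have >= 2 values.
    """
    if condition_col not in samples.columns:
        raise ValueError(f"missing column {condition_col!r}")
    case = samples[samples[condition_col] == case_label]
    ctrl = samples[samples[condition_col] != case_label]
    n_case = len(case)
    rows = []
    for col in samples.columns:
        if col == condition_col:
            continue
        series = samples[col].dropna()
        if series.empty:
            continue
        if pd.api.types.is_numeric_dtype(series):
            a = case[col].dropna().to_numpy(dtype=float)
            b = ctrl[col].dropna().to_numpy(dtype=float)
            p = welch_ttest(a, b)[1] if a.size >= 2 and b.size >= 2 else np.nan
            rows.append({
                "covariate": col, "category": "",
                "summary": f"{a.mean():.1f} ± {a.std(ddof=1):.1f}",
                "count": a.size, "percent": np.nan, "p": p,
            })
        else:
            for cat in sorted(series.unique()):
                k = int((case[col] == cat).sum())
                rows.append({
                    "covariate": col, "category": str(cat),
                    "summary": f"{k} ({100 * k / n_case:.1f})",
                    "count": k, "percent": 100.0 * k / n_case, "p": np.nan,
                })
    return pd.DataFrame(rows, columns=["covariate", "category", "summary",
                                       "count", "percent", "p"])


def percentage(k: int, n: int, decimals: int = 1) -> float:
    """Percentage of ``k`` out of ``n`` rounded to ``decimals`` places."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, decimals)
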