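"""Patient-level myeloid classification, ratio statistic, ROC and survival.

Myeloid cells are classed by precedence: C5aR1hi (C5AR1 detected), then
CD86hi (CD86 high — top 25% of expressing cells by default — with C5AR1,
CD163 and MRC1 not expressed), then "other".  The per-patient outcome
covariate is the pseudocounted C5aR1hi/CD86hi count ratio; patients at or
above the cohort's upper quartile form the high-risk group.  Prediction of
non-response uses the Mann-Whitney identity AUC = U / (n1 * n2); survival
comparison uses Kaplan-Meier curves with the two-group log-rank test, and
effect sizes come from a univariate Cox proportional-hazards fit
(Newton-Raphson on the Breslow partial likelihood, Wald CI from the
observed information).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MyeloidClassRule",
    "classify_myeloid",
    "ratio_statistic",
    "stratify_quartile",
    "roc_auc",
    "km_logrank",
    "plot_km",
    "cox_univariate",
    "CoxResult",
]


@dataclass(frozen=True)
class MyeloidClassRule:
    """Class definitions and precedence for patient myeloid cells."""

    c5ar1_gene: str = "C5AR1"
    cd86_gene: str = "CD86"
    excluded_genes: tuple[str, ...] = ("C5AR1", "CD163", "MRC1")
    high_quantile: float = 0.75       # "high" = top 25% of expressing cells
    high_mode: str = "expressing_quantile"  # or "detected"


def classify_myeloid(
    expression: pd.DataFrame,
    rule: MyeloidClassRule | None = None,
) -> pd.Series:
    """Per-cell class in {C5aR1hi, CD86hi, other} with recorded precedence.

    ``expression`` is a cells x genes frame of one patient's myeloid cells.
    Precedence: any detected C5AR1 -> C5aR1hi; else high CD86 with none of
    the excluded markers detected -> CD86hi; else other.
    """
    rule = rule or MyeloidClassRule()
    needed = {rule.c5ar1_gene, rule.cd86_gene, *rule.excluded_genes}
    missing = needed - set(expression.columns)
    if missing:
        raise ValueError(f"required gene(s) missing: {sorted(missing)}")

    c5 = expression[rule.c5ar1_gene].to_numpy(float)
    cd86 = expression[rule.cd86_gene].to_numpy(float)
    if rule.high_mode == "detected":
        cd86_high = cd86 > 0
    else:
        expressing = cd86[cd86 > 0]
        if expressing.size:
            cut = np.quantile(expressing, rule.high_quantile)
            cd86_high = cd86 >= cut
        else:
            cd86_high = np.zeros(len(cd86), bool)
    excluded_detected = (
        expression[list(rule.excluded_genes)].to_numpy(float) > 0
    ).any(axis=1)

    labels = np.full(len(expression), "other", object)
    labels[cd86_high & ~excluded_detected] = "CD86hi"
    labels[c5 > 0] = "C5aR1hi"  # precedence: C5aR1hi wins
    return pd.Series(labels, index=expression.index, name="myeloid_class")


def ratio_statistic(
    c5ar1_hi: int | np.ndarray,
    cd86_hi: int | np.ndarray,
    pseudocount: float = 1.0,
) -> float | np.ndarray:
    """Pseudocounted C5aR1hi/CD86hi count ratio (no division by zero)."""
    c5 = np.asarray(c5ar1_hi, float)
    cd = np.asarray(cd86_hi, float)
    if (c5 < 0).any() or (cd < 0).any():
        raise ValueError("counts must be nonnegative")
    if pseudocount == 0 and (cd == 0).any():
        raise ZeroDivisionError("zero CD86hi count with pseudocount 0")
    out = (c5 + pseudocount) / (cd + pseudocount)
    return float(out) if out.ndim == 0 else out


def stratify_quartile(ratios) -> pd.Series:
    """Upper-quartile split: high iff ratio >= cohort 75th percentile.

    The quantile uses linear interpolation; ties at the cutoff go to the
    high group.  A degenerate cohort (all ratios equal) is entirely "high"
    and flagged with a warning.
    """
    r = pd.Series(ratios, dtype=float)
    if len(r) < 4:
        raise ValueError("quartile stratification needs at least 4 patients")
    cut = float(np.quantile(r.to_numpy(), 0.75))
    if r.nunique() == 1:
        warnings.warn("all ratios identical; the whole cohort is 'high'")
    groups = pd.Series(np.where(r >= cut, "high", "rest"), index=r.index,
                       name="group")
    groups.attrs["cutoff"] = cut
    groups.attrs["n_high"] = int((groups == "high").sum())
    groups.attrs["n_rest"] = int((groups == "rest").sum())
    return groups


def roc_auc(scores, outcomes, positive="NE") -> tuple[float, float]:
    """AUC (Mann-Whitney U / n1 n2, ties count 1/2) + two-sided p.

    ``outcomes`` is binary; ``positive`` marks the class the score should
    rank high (by default NE, non-responders).  The p-value is the
    tie-corrected normal approximation of the Mann-Whitney test.
    """
    s = np.asarray(scores, float)
    y = np.asarray(outcomes)
    is_pos = (y == positive) if y.dtype.kind in "OUS" else y.astype(bool)
    pos, neg = s[is_pos], s[~is_pos]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided",
                             method="asymptotic")
    auc = float(res.statistic) / (len(pos) * len(neg))
    return auc, float(res.pvalue)


def km_logrank(times, events, groups):
    """Kaplan-Meier curves per group + two-group log-rank test.

    Returns ``(curves, chi2, p)`` where ``curves`` maps group label to the
    lifelines KaplanMeierFitter survival function (a DataFrame).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(groups)
    if e.sum() < 1:
        raise ValueError("log-rank needs at least one event")
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("log-rank comparison needs exactly two groups")

    curves = {}
    for lab in labels:
        m = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m], label=str(lab))
        curves[str(lab)] = kmf.survival_function_
    m0 = g == labels[0]
    res = logrank_test(t[m0], t[~m0], event_observed_A=e[m0],
                       event_observed_B=e[~m0])
    return curves, float(res.test_statistic), float(res.p_value)


def plot_km(curves: dict, ax=None, title: str | None = None):
    """Step plot of Kaplan-Meier survival curves from km_logrank."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, sf in curves.items():
        ax.step(sf.index, sf.iloc[:, 0], where="post", label=label)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax


@dataclass
class CoxResult:
    """Univariate Cox proportional-hazards estimates."""

    beta: float
    se: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    n: int
    n_events: int
    converged: bool
    separated: bool
    n_iter: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": [self.beta], "se(coef)": [self.se],
            "HR": [self.hazard_ratio],
            "HR 95% CI low": [self.ci_low], "HR 95% CI high": [self.ci_high],
            "n": [self.n], "events": [self.n_events],
        }, index=["covariate"])


def _breslow_derivatives(beta: float, t: np.ndarray, e: np.ndarray,
                         x: np.ndarray) -> tuple[float, float, float]:
    """Log partial likelihood, score and information under Breslow ties."""
    order = np.argsort(-t, kind="stable")  # descending time
    ts, es, xs = t[order], e[order], x[order]
    eta = beta * xs
    w = np.exp(eta)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * xs)
    cwx2 = np.cumsum(w * xs * xs)
    # risk set of an event at time ti = all with t >= ti; with descending
    # sort those are the first j entries where ts[j] >= ti.  Tied times
    # share the full risk set (Breslow).
    loglik = score = info = 0.0
    i = 0
    n = len(ts)
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        # entries i..j-1 share time ts[i]; risk set = first j entries
        d_idx = [k for k in range(i, j) if es[k] == 1]
        if d_idx:
            s0, s1, s2 = cw[j - 1], cwx[j - 1], cwx2[j - 1]
            for k in d_idx:
                loglik += eta[k] - np.log(s0)
                score += xs[k] - s1 / s0
                info += s2 / s0 - (s1 / s0) ** 2
        i = j
    return loglik, score, info


def cox_univariate(
    times, events, covariate,
    max_iter: int = 50,
    tol: float = 1e-9,
    alpha: float = 0.05,
) -> CoxResult:
    """Newton-Raphson univariate Cox fit (Breslow ties, Wald CI).

    Raises on non-convergence; monotone partial likelihood (perfect
    separation of event order by the covariate) is detected via a runaway
    coefficient and flagged.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    x = np.asarray(covariate, float)
    if t.shape != e.shape or t.shape != x.shape:
        raise ValueError("times, events and covariate must align")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    if e.sum() < 2:
        raise ValueError("need at least 2 events")

    beta = 0.0
    separated = False
    converged = False
    it = 0
    loglik, score, info = _breslow_derivatives(beta, t, e, x)
    for it in range(1, max_iter + 1):
        if info <= 0:
            separated = True
            break
        step = float(np.clip(score / info, -5.0, 5.0))
        # damped Newton: halve the step until the partial likelihood improves
        new_beta = beta + step
        new_ll, new_sc, new_info = _breslow_derivatives(new_beta, t, e, x)
        halvings = 0
        while new_ll < loglik and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_sc, new_info = _breslow_derivatives(new_beta, t, e, x)
            halvings += 1
        beta, loglik, score, info = new_beta, new_ll, new_sc, new_info
        if abs(beta) > 50.0 / max(np.std(x), 1e-12):
            separated = True
            break
        if abs(step) < tol:
            converged = True
            break
    if separated:
        warnings.warn("monotone partial likelihood: covariate separates event order")
    elif not converged:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(last beta={beta:.4g})"
        )

    _, _, info = _breslow_derivatives(beta, t, e, x)
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return CoxResult(
        beta=float(beta), se=se, hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - zcrit * se)),
        ci_high=float(np.exp(beta + zcrit * se)),
        n=len(t), n_events=int(e.sum()),
        converged=converged, separated=separated, n_iter=it,
    )
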