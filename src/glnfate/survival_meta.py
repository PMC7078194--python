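"""Median-split survival analysis and fixed/random-effects meta-analytic pooling.

For each cohort and gene, subjects are dichotomized at the median expression
level, the hazard ratio (high vs low) is estimated by maximizing the Cox
partial likelihood for the single binary covariate (Efron tie handling), and
per-cohort log hazard ratios are pooled by inverse-variance (fixed-effect) or
DerSimonian-Laird (random-effects) weighting, with Cochran's Q, tau^2 and I^2
quantifying between-cohort heterogeneity.  Integration across organs uses the
random-effects model.  Kaplan-Meier curves and the log-rank test are provided
for per-cohort display, via lifelines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

__all__ = [
    "SubjectRecord",
    "Cohort",
    "CohortEffect",
    "PooledEffect",
    "median_split",
    "cox_hr",
    "km_logrank",
    "pool_effects",
    "integrate_enzymes",
    "read_cohorts",
]

_Z975 = norm.ppf(0.975)


@dataclass(frozen=True)
class SubjectRecord:
    time_months: float
    event: int
    expression: Mapping[str, float]

    def __post_init__(self):
        if self.time_months <= 0:
            raise ValueError("follow-up time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


@dataclass
class Cohort:
    cohort_id: str
    organ: str
    data: pd.DataFrame  # columns: time_months, event, one column per gene

    def __post_init__(self):
        if not {"time_months", "event"} <= set(self.data.columns):
            raise ValueError("cohort frame needs time_months and event columns")
        if len(self.data) < 2 or self.data["event"].sum() < 1:
            raise ValueError("cohort needs >= 2 subjects and >= 1 event")

    @property
    def genes(self) -> List[str]:
        return [c for c in self.data.columns if c not in ("time_months", "event", "subject_id")]

    @property
    def max_followup_months(self) -> float:
        return float(self.data["time_months"].max())


@dataclass(frozen=True)
class CohortEffect:
    cohort_id: str
    organ: str
    log_hr: float
    se: float
    n_subjects: int
    n_events: int
    separation: bool = False

    @property
    def finite(self) -> bool:
        return math.isfinite(self.log_hr) and math.isfinite(self.se) and self.se > 0


@dataclass(frozen=True)
class PooledEffect:
    model: str  # "fixed" | "random"
    log_hr: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    tau2: float
    i2: float  # percent
    k: int
    n_subjects: int

    @property
    def hr(self) -> float:
        return math.exp(self.log_hr)

    @property
    def hr_ci(self) -> Tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


def median_split(expression: Sequence[float]) -> np.ndarray:
    """High/low labels at the median: value > median -> high (1), <= median -> low (0).

    Ties at the median go to the low group (documented convention).
    """
    x = np.asarray(expression, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two subjects to split")
    if np.all(x == x[0]):
        raise ValueError("constant expression: degenerate median split")
    med = float(np.median(x))
    labels = (x > med).astype(int)
    if labels.sum() == 0 or labels.sum() == x.size:
        # all mass at/under the median on one side (heavily tied data)
        raise ValueError("median split produced an empty group (too many ties)")
    return labels


def _efron_terms(groups: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Aggregate per-event-time risk/death counts for the Efron likelihood.

    Returns (m1, a, b): m1 = events in group 1; per log-term coefficients so
    that l(beta) = m1*beta - sum log(a + b e^beta).
    """
    order = np.argsort(times, kind="stable")
    times, events, groups = times[order], events[order], groups[order]
    n = len(times)
    a_list: List[float] = []
    b_list: List[float] = []
    m1 = 0.0
    i = 0
    while i < n:
        t = times[i]
        j = i
        while j < n and times[j] == t:
            j += 1
        ev = events[i:j].astype(bool)
        d = int(ev.sum())
        if d > 0:
            # risk set: all with time >= t (sorted ascending, so indices i..n)
            n1r = float(groups[i:].sum())
            n0r = float(len(times) - i - n1r)
            d1 = float(groups[i:j][ev].sum())
            d0 = float(d - d1)
            m1 += d1
            for r in range(d):
                frac = r / d
                a_list.append(n0r - frac * d0)
                b_list.append(n1r - frac * d1)
        i = j
    return m1, np.asarray(a_list), np.asarray(b_list)


def cox_partial_loglik(beta: float, groups, times, events) -> float:
    """Efron-approximation Cox partial log-likelihood for a binary covariate."""
    groups = np.asarray(groups, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    m1, a, b = _efron_terms(groups, times, events)
    return float(m1 * beta - np.log(a + b * math.exp(beta)).sum())


def cox_hr(
    groups: Sequence[int],
    times: Sequence[float],
    events: Sequence[int],
    cohort_id: str = "",
    organ: str = "",
    beta_bound: float = 15.0,
) -> CohortEffect:
    """Cox proportional-hazards estimate for one binary covariate (high vs low).

    Newton iteration on the Efron partial likelihood; the model-based SE is
    the inverse observed information.  Monotone likelihood (separation, e.g.
    all events in one group with no overlap in risk) is detected when the
    estimate diverges and is returned flagged with non-finite values.
    """
    groups = np.asarray(groups, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if groups.sum() == 0 or groups.sum() == groups.size:
        raise ValueError("both groups must be non-empty")
    n_events = int(events.sum())
    if n_events < 1:
        raise ValueError("need at least one event")
    m1, a, b = _efron_terms(groups, times, events)

    beta = 0.0
    for _ in range(100):
        e = math.exp(beta)
        denom = a + b * e
        u = b * e / denom
        grad = m1 - u.sum()
        hess = -(u * (1.0 - u)).sum()
        if hess >= -1e-300:
            beta = math.copysign(beta_bound + 1, grad)
            break
        step = grad / -hess
        beta += np.clip(step, -2.0, 2.0)
        if abs(beta) > beta_bound:
            break
        if abs(step) < 1e-12:
            break
    if abs(beta) > beta_bound:
        return CohortEffect(
            cohort_id=cohort_id, organ=organ,
            log_hr=math.copysign(math.inf, beta), se=math.inf,
            n_subjects=groups.size, n_events=n_events, separation=True,
        )
    e = math.exp(beta)
    u = b * e / (a + b * e)
    info = (u * (1.0 - u)).sum()
    se = 1.0 / math.sqrt(info)
    return CohortEffect(
        cohort_id=cohort_id, organ=organ, log_hr=float(beta), se=float(se),
        n_subjects=groups.size, n_events=n_events,
    )


@dataclass
class KMLogrankResult:
    curves: Dict[str, pd.DataFrame]  # per group: columns time, survival
    chi2: float
    p: float


def km_logrank(
    groups: Sequence[int],
    times: Sequence[float],
    events: Sequence[int],
) -> KMLogrankResult:
    """Kaplan-Meier product-limit curves per group and the 1-df log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    groups = np.asarray(groups, dtype=int)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if groups.sum() == 0 or groups.sum() == groups.size:
        raise ValueError("both groups must be non-empty")
    curves = {}
    for g, name in ((0, "low"), (1, "high")):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=name)
        df = kmf.survival_function_.reset_index()
        df.columns = ["time", "survival"]
        curves[name] = df
    if events.sum() == 0:
        warnings.warn("no events: log-rank test degenerate, p = 1")
        return KMLogrankResult(curves=curves, chi2=0.0, p=1.0)
    res = logrank_test(times[groups == 1], times[groups == 0],
                       events[groups == 1], events[groups == 0])
    return KMLogrankResult(curves=curves, chi2=float(res.test_statistic), p=float(res.p_value))


def pool_effects(effects: Sequence[CohortEffect], model: str = "random") -> PooledEffect:
    """Inverse-variance (fixed) or DerSimonian-Laird (random) pooling.

    Q is Cochran's heterogeneity statistic under the fixed-effect weights;
    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) and
    I^2 = max(0, (Q - df)/Q) * 100.  CI and p are Wald on the log-HR scale.
    Non-finite per-cohort effects (separation) are excluded.
    """
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    usable = [e for e in effects if e.finite]
    if not usable:
        raise ValueError("no finite cohort effects to pool")
    y = np.array([e.log_hr for e in usable])
    w = np.array([1.0 / e.se**2 for e in usable])
    k = len(usable)
    sw = w.sum()
    y_fixed = float((w * y).sum() / sw)
    q = float((w * (y - y_fixed) ** 2).sum())
    df = k - 1
    if df > 0 and q > 0:
        tau2 = max(0.0, (q - df) / (sw - (w**2).sum() / sw))
        i2 = max(0.0, (q - df) / q) * 100.0
    else:
        tau2 = 0.0
        i2 = 0.0
    if model == "fixed":
        pooled, se = y_fixed, 1.0 / math.sqrt(sw)
    else:
        wr = 1.0 / (np.array([e.se**2 for e in usable]) + tau2)
        pooled = float((wr * y).sum() / wr.sum())
        se = 1.0 / math.sqrt(wr.sum())
    p = 2.0 * norm.sf(abs(pooled) / se)
    return PooledEffect(
        model=model,
        log_hr=pooled,
        se=float(se),
        ci_low=pooled - _Z975 * se,
        ci_high=pooled + _Z975 * se,
        p=float(p),
        q=q,
        tau2=float(tau2),
        i2=float(i2),
        k=k,
        n_subjects=sum(e.n_subjects for e in usable),
    )


@dataclass
class MetaResult:
    integrated: pd.DataFrame      # per gene: hr, ci, p, i2, n_patients, ...
    per_organ: pd.DataFrame       # per gene x organ x model
    per_cohort: pd.DataFrame      # raw per-cohort effects
    skipped: pd.DataFrame         # gene x cohort skip report with reason


def _cohort_effect_for_gene(cohort: Cohort, gene: str) -> CohortEffect:
    df = cohort.data
    labels = median_split(df[gene].to_numpy())
    return cox_hr(
        labels,
        df["time_months"].to_numpy(),
        df["event"].to_numpy(),
        cohort_id=cohort.cohort_id,
        organ=cohort.organ,
    )


def integrate_enzymes(
    cohorts: Sequence[Cohort],
    genes: Sequence[str],
    min_followup_months: Optional[float] = 84.0,
) -> MetaResult:
    """Per-gene median-split Cox HRs pooled per organ (fixed and random) and
    integrated across all cohorts (random effects).

    Cohorts with a maximum follow-up below ``min_followup_months`` (default 7
    years) are excluded up front.  Cohorts where a gene is missing, the split
    is degenerate or the Cox fit separates are excluded from that gene's
    pooling and listed in the skip report.
    """
    if min_followup_months is not None:
        cohorts = [c for c in cohorts if c.max_followup_months > min_followup_months]
    if not cohorts:
        raise ValueError("no cohorts satisfy the follow-up duration filter")
    integrated_rows, organ_rows, cohort_rows, skipped = [], [], [], []
    for gene in genes:
        effects: List[CohortEffect] = []
        for cohort in cohorts:
            if gene not in cohort.data.columns:
                skipped.append({"gene": gene, "cohort_id": cohort.cohort_id, "reason": "gene missing"})
                continue
            try:
                eff = _cohort_effect_for_gene(cohort, gene)
            except ValueError as exc:
                skipped.append({"gene": gene, "cohort_id": cohort.cohort_id, "reason": str(exc)})
                continue
            if eff.separation:
                skipped.append({"gene": gene, "cohort_id": cohort.cohort_id, "reason": "separation"})
                continue
            effects.append(eff)
            cohort_rows.append(
                {
                    "gene": gene, "cohort_id": eff.cohort_id, "organ": eff.organ,
                    "log_hr": eff.log_hr, "se": eff.se,
                    "n_subjects": eff.n_subjects, "n_events": eff.n_events,
                }
            )
        if not effects:
            continue
        for organ in sorted({e.organ for e in effects}):
            sub = [e for e in effects if e.organ == organ]
            for model in ("fixed", "random"):
                pe = pool_effects(sub, model)
                organ_rows.append(
                    {
                        "gene": gene, "organ": organ, "model": model,
                        "hr": pe.hr, "ci_low": pe.hr_ci[0], "ci_high": pe.hr_ci[1],
                        "p": pe.p, "i2": pe.i2, "tau2": pe.tau2,
                        "k_cohorts": pe.k, "n_patients": pe.n_subjects,
                    }
                )
        pe = pool_effects(effects, "random")
        integrated_rows.append(
            {
                "gene": gene,
                "hr": pe.hr, "ci_low": pe.hr_ci[0], "ci_high": pe.hr_ci[1],
                "p": pe.p, "i2": pe.i2, "tau2": pe.tau2,
                "k_cohorts": pe.k, "n_patients": pe.n_subjects,
            }
        )
    integrated = pd.DataFrame(integrated_rows)
    if not integrated.empty:
        integrated = integrated.sort_values("hr", ascending=False).reset_index(drop=True)
    return MetaResult(
        integrated=integrated,
        per_organ=pd.DataFrame(organ_rows),
        per_cohort=pd.DataFrame(cohort_rows),
        skipped=pd.DataFrame(skipped, columns=["gene", "cohort_id", "reason"]),
    )


def read_cohorts(manifest_path: str) -> List[Cohort]:
    """Load cohorts from a manifest CSV (cohort_id, organ, filename); each
    cohort file has columns subject_id, time_months, event, then genes."""
    import os

    manifest = pd.read_csv(manifest_path)
    required = {"cohort_id", "organ", "filename"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    base = os.path.dirname(os.path.abspath(manifest_path))
    cohorts = []
    for row in manifest.itertuples():
        path = row.filename
        if not os.path.isabs(path):
            path = os.path.join(base, path)
        if not os.path.exists(path):
            raise FileNotFoundError(f"cohort file missing for {row.cohort_id}: {path}")
        df = pd.read_csv(path)
        cohorts.append(Cohort(cohort_id=str(row.cohort_id), organ=str(row.organ), data=df))
    return cohorts
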