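"""Kaplan-Meier, log-rank, best-cutoff search and Cox PH prognostics.

Tree-derived heterogeneity descriptors are joined with the per-patient
time-to-event outcome and fed to Cox proportional-hazards models
(``h(t|x) = h0(t) exp(beta'x)``, Efron tie handling) in univariate and
multivariate fashion; performance is summarised by Harrell's concordance
index. Descriptor dichotomisation uses a best-cutoff scan minimising the
log-rank p over observed values; because that minimum is anti-conservative
by construction, a permutation-adjusted p accompanies the raw one.

The two-group log-rank statistic is computed by a vectorised numpy routine
(verified against lifelines) so that the permutation adjustment scales to
hundreds of permutations; Kaplan-Meier and Cox fits delegate to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_concordance
from scipy import stats

logger = logging.getLogger("lesionforest")


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def kaplan_meier(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence | None = None,
) -> dict[object, pd.DataFrame]:
    """Product-limit survival and Nelson-Aalen-style cumulative hazard curves.

    Returns, per group (single group ``"all"`` when ``groups`` is None), a
    step-function table with columns ``survival`` and ``cumhaz`` indexed by
    time. A fully censored group is estimated normally but flagged in the
    log.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(["all"] * len(times)) if groups is None else np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise ValueError(f"group {g!r} has no subjects")
        if not events[mask].any():
            logger.warning("group %r has no events; survival curve is flat", g)
        km = KaplanMeierFitter()
        km.fit(times[mask], events[mask])
        surv = km.survival_function_.iloc[:, 0]
        with np.errstate(divide="ignore"):
            cumhaz = -np.log(surv.clip(lower=np.finfo(float).tiny))
        out[g] = pd.DataFrame({"survival": surv, "cumhaz": cumhaz})
    return out


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def _logrank_chi2_many(
    times: np.ndarray, events: np.ndarray, masks: np.ndarray
) -> np.ndarray:
    """Two-group log-rank chi-squared for many group assignments at once.

    ``masks`` is (n, m) boolean, column j flagging membership of group 1 in
    assignment j. Uses the standard hypergeometric variance with tied event
    times aggregated per distinct time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim == 1:
        masks = masks[:, None]
    order = np.argsort(times, kind="stable")
    t, e, M = times[order], events[order], masks[order]
    n = len(t)
    starts = np.r_[0, np.nonzero(np.diff(t))[0] + 1]
    at_risk = (n - starts).astype(float)  # total at risk per distinct time
    d = np.add.reduceat(e.astype(float), starts)  # total events
    # group-1 at-risk and events per distinct time, per assignment
    revcum = np.cumsum(M[::-1].astype(float), axis=0)[::-1]
    n1 = revcum[starts]  # (B, m)
    d1 = np.add.reduceat(e[:, None] * M, starts, axis=0)
    valid = d > 0
    ar, dd = at_risk[valid, None], d[valid, None]
    n1v, d1v = n1[valid], d1[valid]
    expected = dd * n1v / ar
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            ar > 1,
            dd * (n1v / ar) * (1 - n1v / ar) * (ar - dd) / (ar - 1),
            0.0,
        )
    score = (d1v - expected).sum(axis=0)
    variance = var.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(variance > 0, score**2 / variance, 0.0)
    return chi2


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    df: int


def log_rank(
    times: Sequence[float], events: Sequence[bool], groups: Sequence
) -> LogRankResult:
    """Log-rank test between 2+ groups (chi-squared, k-1 df).

    The two-group case is the in-package vectorised statistic; three or more
    groups delegate to lifelines' multivariate log-rank test.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("log-rank needs at least two groups")
    for g in levels:
        if not (groups == g).any():
            raise ValueError(f"group {g!r} has no subjects")
    if len(levels) == 2:
        chi2 = float(_logrank_chi2_many(times, events, groups == levels[1])[0])
        return LogRankResult(chi2, float(stats.chi2.sf(chi2, 1)), 1)
    res = multivariate_logrank_test(times, groups, events)
    return LogRankResult(
        float(res.test_statistic), float(res.p_value), len(levels) - 1
    )


# ---------------------------------------------------------------------------
# Best cutoff
# ---------------------------------------------------------------------------

@dataclass
class CutoffScan:
    cutoff: float
    p_value: float
    statistic: float
    table: pd.DataFrame
    adjusted_p: float | None = None
    n_permutations: int = 0


def best_cutoff(
    values: Sequence[float],
    times: Sequence[float],
    events: Sequence[bool],
    candidates: Sequence[float] | None = None,
    n_permutations: int = 0,
    seed: int = 0,
) -> CutoffScan:
    """Best dichotomising cutoff of an integer descriptor by log-rank p.

    Candidates default to the observed values; each cutoff ``c`` splits
    patients at ``value > c`` and cutoffs yielding an empty arm are skipped.
    The reported minimum p is unadjusted (anti-conservative); when
    ``n_permutations > 0`` a permutation-adjusted p for the minimum is added
    (share of permuted minima at or below the observed one, add-one rule).
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    uniq = np.unique(values)
    if len(uniq) < 2:
        raise ValueError("need at least two distinct descriptor values")
    if candidates is None:
        candidates = uniq
    candidates = [c for c in np.asarray(candidates, dtype=float) if uniq.min() <= c < uniq.max()]
    if not candidates:
        raise ValueError("no cutoff candidate leaves both arms non-empty")

    masks = np.column_stack([values > c for c in candidates])
    chi2 = _logrank_chi2_many(times, events, masks)
    pvals = stats.chi2.sf(chi2, 1)
    table = pd.DataFrame(
        {
            "cutoff": candidates,
            "n_high": masks.sum(axis=0),
            "n_low": (~masks).sum(axis=0),
            "statistic": chi2,
            "p_value": pvals,
        }
    )
    best = int(np.argmin(pvals))
    scan = CutoffScan(
        cutoff=float(candidates[best]),
        p_value=float(pvals[best]),
        statistic=float(chi2[best]),
        table=table,
    )
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        perm_min = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.permutation(values)
            pmasks = np.column_stack([perm > c for c in candidates])
            pchi = _logrank_chi2_many(times, events, pmasks)
            perm_min[b] = stats.chi2.sf(pchi, 1).min()
        scan.adjusted_p = float(
            (1 + (perm_min <= scan.p_value).sum()) / (n_permutations + 1)
        )
        scan.n_permutations = n_permutations
    return scan


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted Cox PH model: ``h(t|x) = h0(t) exp(beta'x)``."""

    covariates: list[str]
    coefficients: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    concordance: float
    log_likelihood: float
    score_p_value: float
    model: CoxPHFitter = field(repr=False)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)


def _fit_cox(
    frame: pd.DataFrame,
    covariates: list[str],
    duration_col: str,
    event_col: str,
) -> CoxFit:
    cols = covariates + [duration_col, event_col]
    data = frame[cols].dropna()
    dropped = len(frame) - len(data)
    if dropped:
        logger.info("Cox fit: dropped %d row(s) with missing covariates", dropped)
    if not data[event_col].astype(bool).any():
        raise ValueError("no events in the survival frame")
    corr = data[covariates].corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    if (corr.values >= 1.0 - 1e-12).any():
        raise ValueError("perfectly collinear covariate pair in the design")
    cph = CoxPHFitter()
    cph.fit(data, duration_col=duration_col, event_col=event_col)  # Efron ties
    summary = cph.summary
    return CoxFit(
        covariates=covariates,
        coefficients=summary["coef"],
        standard_errors=summary["se(coef)"],
        p_values=summary["p"],
        concordance=float(cph.concordance_index_),
        log_likelihood=float(cph.log_likelihood_),
        score_p_value=float(cph.log_likelihood_ratio_test().p_value),
        model=cph,
    )


def cox_univariate(
    frame: pd.DataFrame,
    covariate: str,
    duration_col: str = "followup_time",
    event_col: str = "event",
) -> CoxFit:
    """Univariate Cox PH fit (partial likelihood, Efron ties)."""
    return _fit_cox(frame, [covariate], duration_col, event_col)


def cox_multivariate(
    frame: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "followup_time",
    event_col: str = "event",
) -> CoxFit:
    """Multivariate Cox PH fit over the given covariate list."""
    return _fit_cox(frame, list(covariates), duration_col, event_col)


def univariate_report(
    frame: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "followup_time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Per-covariate univariate screen: beta, HR, SE, p and concordance."""
    rows = []
    for cov in covariates:
        try:
            fit = cox_univariate(frame, cov, duration_col, event_col)
            rows.append(
                {
                    "covariate": cov,
                    "coef": float(fit.coefficients.iloc[0]),
                    "hazard_ratio": float(fit.hazard_ratios.iloc[0]),
                    "se": float(fit.standard_errors.iloc[0]),
                    "p_value": float(fit.p_values.iloc[0]),
                    "concordance": fit.concordance,
                }
            )
        except Exception as exc:  # convergence failures surface here
            logger.warning("univariate Cox failed for %r: %s", cov, exc)
            rows.append({"covariate": cov, "coef": np.nan, "hazard_ratio": np.nan,
                         "se": np.nan, "p_value": np.nan, "concordance": np.nan})
    return pd.DataFrame(rows).set_index("covariate")


def concordance_index(
    times: Sequence[float],
    risk_scores: Sequence[float],
    events: Sequence[bool],
) -> float:
    """Harrell's C over comparable pairs; higher risk should fail earlier."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    risk = np.asarray(risk_scores, dtype=float)
    if not events.any():
        raise ValueError("concordance undefined without any event")
    return float(_lifelines_concordance(times, -risk, events))


def fit_concordance(fit: CoxFit, frame: pd.DataFrame,
                    duration_col: str = "followup_time",
                    event_col: str = "event") -> float:
    """Harrell's C of a fitted Cox model on a (possibly new) frame."""
    data = frame[fit.covariates + [duration_col, event_col]].dropna()
    risk = fit.model.predict_partial_hazard(data[fit.covariates]).to_numpy()
    return concordance_index(
        data[duration_col].to_numpy(), risk, data[event_col].to_numpy(dtype=bool)
    )
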