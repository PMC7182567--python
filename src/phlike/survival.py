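"""Survival and competing-risks machinery for outcome comparisons.

Implements the estimators used to compare outcomes between the Ph-like and
non-Ph-like groups:

* Kaplan–Meier product-limit estimate with Greenwood variance and log-log
  (or linear) 95% confidence intervals — used for OS and DFS;
* the two-sample log-rank test;
* the Aalen–Johansen cumulative incidence function (CIF) for relapse with
  death-without-relapse as a competing risk, with the delta-method
  variance estimator;
* Gray's two-sample test on the subdistribution hazard of relapse;
* univariable Cox proportional hazards for a binary covariate (Newton
  iterations, Efron or Breslow tie handling).

Cause codes: 0 = censored, 1 = relapse (cause of interest), 2 = death
without relapse (competing).  Times are in years.

Gray's test statistic is the score of Gray (1988): at each relapse time
each group's risk set is inflated by its earlier competing-cause failures,
``R_j(t) = Y_j(t) (1 - F1_j(t-)) / S_j(t-)``, and the score accumulates
observed-minus-expected relapse counts against ``R_j/ΣR``.  The score
variance is estimated from seeded permutations of the group labels
(exactly valid under label exchangeability), and the chi-square p-value
uses that variance; an empirical permutation p-value is also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "SurvivalRecord",
    "StepFunctionEstimate",
    "GroupComparison",
    "CoxResult",
    "km_estimator",
    "logrank_test",
    "aalen_johansen_cif",
    "gray_test",
    "cox_univariable",
    "CAUSE_CENSORED",
    "CAUSE_RELAPSE",
    "CAUSE_DEATH",
]

CAUSE_CENSORED = 0
CAUSE_RELAPSE = 1
CAUSE_DEATH = 2

DEFAULT_HORIZONS = (3.0, 4.0, 5.0, 8.0)


@dataclass(frozen=True)
class SurvivalRecord:
    time: float
    cause: int
    group: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError("time must be finite and >= 0")
        if self.cause not in (0, 1, 2):
            raise ValueError("cause must be 0 (censored), 1 (relapse) or 2 (death)")


@dataclass
class StepFunctionEstimate:
    """A right-continuous step-function estimate with pointwise 95% CIs."""

    times: np.ndarray
    estimate: np.ndarray
    variance: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    kind: str  # "survival" | "cif"
    at_horizons: dict[float, float] = field(default_factory=dict)

    def value_at(self, t: float) -> float:
        """Estimate at time t (start value before the first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        start = 1.0 if self.kind == "survival" else 0.0
        return start if idx < 0 else float(self.estimate[idx])


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    df: int
    p_value: float
    method: str
    group_estimates: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CoxResult:
    log_hr: float
    se: float
    p_value: float
    n_events: int
    ties: str
    monotone_likelihood: bool = False

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.log_hr))

    def ci95(self) -> tuple[float, float]:
        if self.monotone_likelihood:
            return (0.0, np.inf)
        h = 1.959963984540054 * self.se
        return (float(np.exp(self.log_hr - h)), float(np.exp(self.log_hr + h)))


def _as_arrays(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    c = np.array([r.cause for r in records], dtype=int)
    g = np.array([r.group for r in records], dtype=object)
    order = np.argsort(t, kind="stable")
    return t[order], c[order], g[order]


def _event_table(t: np.ndarray, event: np.ndarray):
    """Distinct times with at-risk and event counts (input sorted by time)."""
    times = np.unique(t)
    n_at = np.array([(t >= u).sum() for u in times], dtype=float)
    d = np.array([event[t == u].sum() for u in times], dtype=float)
    return times, n_at, d


# ---------------------------------------------------------------------------
# Kaplan–Meier


def km_estimator(
    records: list[SurvivalRecord],
    horizons: tuple[float, ...] = DEFAULT_HORIZONS,
    ci: str = "loglog",
) -> StepFunctionEstimate:
    """Product-limit survival estimate, all-cause events (cause != 0).

    Greenwood's formula gives the pointwise variance; 95% CIs use the
    log(-log) transform by default (``ci="linear"`` for plain Wald).
    """
    if not records:
        raise ValueError("no records")
    t, c, _ = _as_arrays(records)
    event = (c != 0).astype(float)
    times, n_at, d = _event_table(t, event)
    s = np.cumprod(1.0 - d / n_at)
    # Greenwood: Var = S(t)^2 * sum d / (n (n - d))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(n_at > d, d / (n_at * (n_at - d)), 0.0)
    gw = np.cumsum(gw_terms)
    var = s**2 * gw
    lo, hi = _survival_ci(s, var, ci)
    est = StepFunctionEstimate(times, s, var, lo, hi, kind="survival")
    est.at_horizons.update({h: est.value_at(h) for h in horizons})
    return est


def _survival_ci(s: np.ndarray, var: np.ndarray, ci: str):
    z = 1.959963984540054
    se = np.sqrt(var)
    if ci == "linear":
        return np.clip(s - z * se, 0, 1), np.clip(s + z * se, 0, 1)
    if ci != "loglog":
        raise ValueError(f"unknown ci transform {ci!r}")
    lo = np.empty_like(s)
    hi = np.empty_like(s)
    interior = (s > 0) & (s < 1)
    lo[~interior] = s[~interior]
    hi[~interior] = s[~interior]
    si = s[interior]
    # se of log(-log S) by the delta method
    se_ll = se[interior] / np.abs(si * np.log(si))
    theta = np.log(-np.log(si))
    lo[interior] = np.exp(-np.exp(theta + z * se_ll))
    hi[interior] = np.exp(-np.exp(theta - z * se_ll))
    return lo, hi


# ---------------------------------------------------------------------------
# log-rank


def logrank_test(records: list[SurvivalRecord]) -> GroupComparison:
    """Two-sample log-rank test on all-cause events."""
    t, c, g = _as_arrays(records)
    groups = sorted(set(g))
    if len(groups) != 2:
        raise ValueError("exactly 2 groups required")
    event = (c != 0).astype(float)
    if event.sum() == 0:
        warnings.warn("no events in either group; log-rank p = 1")
        return GroupComparison(0.0, 1, 1.0, "logrank")
    in0 = g == groups[0]
    times = np.unique(t[event == 1])
    obs = exp = var = 0.0
    for u in times:
        at = t >= u
        n = at.sum()
        n0 = (at & in0).sum()
        d = event[t == u].sum()
        d0 = event[(t == u) & in0].sum()
        obs += d0
        exp += d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    stat = 0.0 if var == 0 else (obs - exp) ** 2 / var
    p = float(_sps.chi2.sf(stat, 1)) if var > 0 else 1.0
    return GroupComparison(float(stat), 1, p, "logrank")


# ---------------------------------------------------------------------------
# Aalen–Johansen CIF


def aalen_johansen_cif(
    records: list[SurvivalRecord],
    cause: int = CAUSE_RELAPSE,
    horizons: tuple[float, ...] = DEFAULT_HORIZONS,
) -> StepFunctionEstimate:
    """Cumulative incidence of the given cause under competing risks.

    ``CIF(t) = sum_{t_i <= t} S(t_i-) d_cause_i / n_i`` with ``S`` the
    all-cause Kaplan–Meier.  Pointwise variance is the delta-method
    estimator; CIs use a log(-log(1-F)) transform clipped to [0, 1].
    """
    if not records:
        raise ValueError("no records")
    t, c, _ = _as_arrays(records)
    all_event = (c != 0).astype(float)
    times, n_at, d_all = _event_table(t, all_event)
    d_cause = np.array([(c[t == u] == cause).sum() for u in times], dtype=float)
    s = np.cumprod(1.0 - d_all / n_at)
    s_prev = np.concatenate([[1.0], s[:-1]])
    jumps = s_prev * d_cause / n_at
    cif = np.cumsum(jumps)
    var = _cif_variance(times, n_at, d_all, d_cause, s_prev, cif)
    lo, hi = _cif_ci(cif, var)
    est = StepFunctionEstimate(times, cif, var, lo, hi, kind="cif")
    est.at_horizons.update({h: est.value_at(h) for h in horizons})
    return est


def _cif_variance(times, n_at, d_all, d_cause, s_prev, cif) -> np.ndarray:
    """Delta-method CIF variance (Aalen-type, three-term form)."""
    m = len(times)
    var = np.zeros(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.where(n_at > d_all, d_all / (n_at * (n_at - d_all)), 0.0)
    t2 = s_prev**2 * (d_cause / n_at**2) * ((n_at - d_cause) / n_at)
    t3 = s_prev * d_cause / n_at**2
    for k in range(m):
        diff = cif[k] - cif[: k + 1]
        var[k] = (
            float((diff**2 * gw[: k + 1]).sum())
            + float(t2[: k + 1].sum())
            - 2.0 * float((diff * t3[: k + 1]).sum())
        )
    return np.maximum(var, 0.0)


def _cif_ci(cif, var):
    z = 1.959963984540054
    se = np.sqrt(var)
    lo = np.empty_like(cif)
    hi = np.empty_like(cif)
    interior = (cif > 0) & (cif < 1) & (se > 0)
    lo[~interior] = cif[~interior]
    hi[~interior] = cif[~interior]
    f = cif[interior]
    se_ll = se[interior] / np.abs((1 - f) * np.log(1 - f))
    theta = np.log(-np.log(1 - f))
    lo[interior] = 1 - np.exp(-np.exp(theta - z * se_ll))
    hi[interior] = 1 - np.exp(-np.exp(theta + z * se_ll))
    return lo, hi


# ---------------------------------------------------------------------------
# Gray's test


def _gray_scores(t: np.ndarray, c: np.ndarray, member: np.ndarray, cause: int) -> np.ndarray:
    """Gray score for group 1 for each membership row (B x n), vectorized.

    ``t`` ascending; ``member`` is a B x n 0/1 matrix (1 = group of
    interest).  Returns the B score values.
    """
    other = 2 if cause == 1 else 1
    times, inv = np.unique(t, return_inverse=True)
    T = len(times)
    B, n = member.shape

    def per_time(mask_subjects: np.ndarray) -> np.ndarray:
        # B x T counts of masked subjects at each distinct time
        out = np.zeros((B, T))
        cols = inv[mask_subjects]
        if cols.size:
            np.add.at(out.T, cols, member[:, mask_subjects].T)
        return out

    w_any = per_time(np.ones(n, dtype=bool))  # membership counts per time
    d1 = per_time(c == cause)
    d2 = per_time(c == other)
    # at-risk: reverse cumulative sum of per-time membership counts
    y1 = np.cumsum(w_any[:, ::-1], axis=1)[:, ::-1]
    tot_any = np.bincount(inv, minlength=T).astype(float)
    tot_d1 = np.bincount(inv[c == cause], minlength=T).astype(float)
    tot_d2 = np.bincount(inv[c == other], minlength=T).astype(float)
    y0 = np.cumsum(tot_any[::-1])[::-1][None, :] - y1
    d1_0 = tot_d1[None, :] - d1
    d2_0 = tot_d2[None, :] - d2

    def modified_risk(y, dd1, dd2):
        safe_y = np.where(y > 0, y, 1.0)
        factor = np.where(y > 0, 1.0 - (dd1 + dd2) / safe_y, 1.0)
        s = np.cumprod(factor, axis=1)
        s_prev = np.concatenate([np.ones((B, 1)), s[:, :-1]], axis=1)
        f1 = np.cumsum(np.where(y > 0, s_prev * dd1 / safe_y, 0.0), axis=1)
        f1_prev = np.concatenate([np.zeros((B, 1)), f1[:, :-1]], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where((y > 0) & (s_prev > 0), y * (1.0 - f1_prev) / s_prev, 0.0)
        return r

    r1 = modified_risk(y1, d1, d2)
    r0 = modified_risk(y0, d1_0, d2_0)
    rtot = r1 + r0
    d1_tot = tot_d1[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = np.where(rtot > 0, d1_tot * r1 / rtot, 0.0)
    contrib = np.where(rtot > 0, d1 - expected, 0.0)
    return contrib.sum(axis=1)


def gray_test(
    records: list[SurvivalRecord],
    cause: int = CAUSE_RELAPSE,
    n_perm: int = 1000,
    seed: int = 0,
    p_mode: str = "chi2",
) -> GroupComparison:
    """Gray's two-sample test comparing cumulative incidence of ``cause``.

    The statistic is the squared Gray score divided by its variance under
    ``n_perm`` seeded permutations of the group labels; the p-value comes
    from chi-square with 1 df (``p_mode="permutation"`` for the empirical
    permutation p-value instead).
    """
    t, c, g = _as_arrays(records)
    groups = sorted(set(g))
    if len(groups) != 2:
        raise ValueError("exactly 2 groups required")
    if (c == cause).sum() == 0:
        warnings.warn("no events of the cause of interest; Gray p = 1")
        return GroupComparison(0.0, 1, 1.0, "gray")
    member_obs = (g == groups[1]).astype(np.float64)
    rng = np.random.default_rng(seed)
    perms = np.tile(member_obs, (n_perm + 1, 1))
    for b in range(1, n_perm + 1):
        perms[b] = rng.permutation(member_obs)
    scores = _gray_scores(t, c, perms, cause)
    z_obs = scores[0]
    z_perm = scores[1:]
    var = float(np.var(z_perm, ddof=1))
    if var == 0:
        warnings.warn("degenerate permutation variance; Gray p = 1")
        return GroupComparison(0.0, 1, 1.0, "gray")
    stat = z_obs**2 / var
    if p_mode == "chi2":
        p = float(_sps.chi2.sf(stat, 1))
    elif p_mode == "permutation":
        p = float((1 + (np.abs(z_perm) >= abs(z_obs)).sum()) / (n_perm + 1))
    else:
        raise ValueError(f"unknown p_mode {p_mode!r}")
    ests = {
        grp: aalen_johansen_cif([r for r in records if r.group == grp], cause=cause)
        for grp in groups
    }
    return GroupComparison(
        float(stat),
        1,
        p,
        "gray",
        group_estimates={grp: e.at_horizons for grp, e in ests.items()},
    )


# ---------------------------------------------------------------------------
# univariable Cox


def cox_univariable(
    records: list[SurvivalRecord],
    covariate: np.ndarray | list[float],
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Univariable Cox proportional-hazards fit (all-cause events).

    Newton–Raphson maximization of the partial likelihood for a single
    (typically binary) covariate, Efron (default) or Breslow tie handling.
    A group with no events yields a monotone likelihood, which is flagged
    and returned with an unbounded CI.
    """
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(records):
        raise ValueError("covariate length must match records")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling {ties!r}")
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.cause != 0 for r in records], dtype=bool)
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    n_events = int(e.sum())
    if n_events == 0:
        raise ValueError("no events")
    # monotone likelihood check for a binary covariate: all events on one side
    monotone = len(np.unique(x[e])) == 1 and len(np.unique(x)) == 2

    event_times = np.unique(t[e])
    beta = 0.0
    for _ in range(max_iter):
        u = 0.0  # score
        i2 = 0.0  # information
        for tt in event_times:
            at = t >= tt
            dead = (t == tt) & e
            d = int(dead.sum())
            xr = x[at]
            w = np.exp(beta * xr)
            s0, s1, s2 = w.sum(), (w * xr).sum(), (w * xr**2).sum()
            xd = x[dead]
            wd = np.exp(beta * xd)
            d0, d1_, d2_ = wd.sum(), (wd * xd).sum(), (wd * xd**2).sum()
            u += xd.sum()
            if ties == "breslow" or d == 1:
                u -= d * s1 / s0
                i2 += d * (s2 / s0 - (s1 / s0) ** 2)
            else:  # Efron
                for j in range(d):
                    f = j / d
                    q0 = s0 - f * d0
                    q1 = s1 - f * d1_
                    q2 = s2 - f * d2_
                    u -= q1 / q0
                    i2 += q2 / q0 - (q1 / q0) ** 2
        if i2 <= 0:
            break
        step = u / i2
        beta += step
        if abs(step) < tol:
            break
        beta = float(np.clip(beta, -50, 50))
    se = float(np.sqrt(1.0 / i2)) if i2 > 0 else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2 * _sps.norm.sf(abs(z)))
    if monotone:
        warnings.warn("monotone partial likelihood (no events in one group); CI unbounded")
    return CoxResult(float(beta), se, p, n_events, ties, monotone_likelihood=monotone)
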