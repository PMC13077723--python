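"""Disproportionality statistics for spontaneous-report 2x2 tables.

Four estimators of reporting disproportion are provided, each with its
conventional uncertainty bound and signal criterion:

* ROR, the reporting odds ratio ``ad/bc`` with a log-scale Wald 95% CI;
  signal when a >= 3, ROR >= 2 and the CI lower bound exceeds 1.
* PRR, the proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with a
  log-Wald CI and the Yates continuity-corrected chi-square; signal when
  a >= 3, PRR >= 2 and chi-square >= 4.
* BCPNN information component: the posterior expectation E(IC) of the
  log2 observed-to-expected reporting ratio under the Bayesian
  confidence propagation neural network model, with variance V(IC) and
  lower bound IC - 2*sqrt(V(IC)); signal when a >= 3 and IC-2SD > 0.
* MGPS/EBGM: empirical-Bayes geometric mean of the relative reporting
  ratio under a two-component gamma-Poisson mixture prior shared across
  all tables of the corpus, with its posterior 5th percentile EBGM05;
  signal when a >= 3 and EBGM05 > 2 (conventional cut, overridable).

Zero cells make ROR/PRR/chi-square undefined; those return NaN rather
than applying a silent Haldane correction (an explicit ``haldane=True``
adds 0.5 to every cell first).  The BCPNN priors regularize zeros, so the
information component is defined for every nonnegative table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .contingency import ContingencyTable
from .errors import ConfigurationError, FitError

_Z95 = 1.959963984540054  # standard normal 97.5% quantile
_UNDEF = float("nan")


def _cells(table: ContingencyTable, haldane: bool) -> tuple[float, float, float, float]:
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a), float(b), float(c), float(d)


def ror(table: ContingencyTable, haldane: bool = False) -> tuple[float, float, float]:
    """Reporting odds ratio with Wald 95% CI: exp(ln ROR +/- 1.96*se).

    se = sqrt(1/a + 1/b + 1/c + 1/d).  Any zero cell -> (nan, nan, nan).
    """
    a, b, c, d = _cells(table, haldane)
    if min(a, b, c, d) == 0:
        return _UNDEF, _UNDEF, _UNDEF
    estimate = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_est = math.log(estimate)
    return estimate, math.exp(log_est - _Z95 * se), math.exp(log_est + _Z95 * se)


def prr(table: ContingencyTable, haldane: bool = False) -> tuple[float, float, float]:
    """Proportional reporting ratio with log-Wald 95% CI.

    PRR = a(c+d) / c(a+b); se = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)).
    Undefined (nan) when a, c, a+b or c+d is zero.
    """
    a, b, c, d = _cells(table, haldane)
    if a == 0 or c == 0 or a + b == 0 or c + d == 0:
        return _UNDEF, _UNDEF, _UNDEF
    estimate = (a * (c + d)) / (c * (a + b))
    se_sq = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(se_sq, 0.0))
    log_est = math.log(estimate)
    return estimate, math.exp(log_est - _Z95 * se), math.exp(log_est + _Z95 * se)


def chisq_yates(table: ContingencyTable) -> float:
    """Yates continuity-corrected chi-square on the 2x2 table.

    ((|ad - bc| - n/2)^2 * n) / ((a+b)(a+c)(c+d)(b+d)), with the
    correction term floored at zero; nan if any margin is zero.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    n = a + b + c + d
    denom = (a + b) * (a + c) * (c + d) * (b + d)
    if denom == 0:
        return _UNDEF
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    return num * num * n / denom


@dataclass(frozen=True)
class BcpnnPriors:
    """Hyperparameters of the BCPNN beta/Dirichlet priors.

    The defaults (alpha1 = beta1 = 1, alpha = beta = 2, gamma11 = 1)
    center the prior information component at zero for an empty table.
    gamma is derived from the data, not a free parameter.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha, self.beta, self.gamma11) <= 0:
            raise ConfigurationError("BCPNN priors must be strictly positive")


def bcpnn(table: ContingencyTable, priors: BcpnnPriors = BcpnnPriors(),
          ) -> tuple[float, float, float]:
    """BCPNN information component: (E(IC), V(IC), IC - 2SD).

    With C = n, Cx = a+b, Cy = a+c, Cxy = a and the coupling prior
    gamma = gamma11 * (C+alpha)(C+beta) / ((Cx+alpha1)(Cy+beta1)):

      E(IC) = log2[ (Cxy+gamma11)(C+alpha)(C+beta)
                    / ((C+gamma)(Cx+alpha1)(Cy+beta1)) ]
      V(IC) = ln(2)^-2 * [ (C-Cxy+gamma-gamma11) / ((Cxy+gamma11)(1+C+gamma))
                         + (C-Cx+alpha-alpha1)   / ((Cx+alpha1)(1+C+alpha))
                         + (C-Cy+beta-beta1)     / ((Cy+beta1)(1+C+beta)) ]

    Defined for every nonnegative table; the priors regularize zeros.
    """
    p = priors
    c_total = float(table.n)
    cx = float(table.a + table.b)
    cy = float(table.a + table.c)
    cxy = float(table.a)
    gamma = p.gamma11 * (c_total + p.alpha) * (c_total + p.beta) / (
        (cx + p.alpha1) * (cy + p.beta1))
    ic = math.log2((cxy + p.gamma11) * (c_total + p.alpha) * (c_total + p.beta)
                   / ((c_total + gamma) * (cx + p.alpha1) * (cy + p.beta1)))
    v_ic = (1.0 / math.log(2) ** 2) * (
        (c_total - cxy + gamma - p.gamma11) / ((cxy + p.gamma11) * (1 + c_total + gamma))
        + (c_total - cx + p.alpha - p.alpha1) / ((cx + p.alpha1) * (1 + c_total + p.alpha))
        + (c_total - cy + p.beta - p.beta1) / ((cy + p.beta1) * (1 + c_total + p.beta)))
    return ic, v_ic, ic - 2.0 * math.sqrt(v_ic)


# ---------------------------------------------------------------------------
# MGPS / EBGM: two-component gamma-Poisson shrinkage
# ---------------------------------------------------------------------------

#: Conventional starting point (alpha1, beta1, alpha2, beta2, P) for the
#: mixture-prior maximum-likelihood fit.
MGPS_DEFAULT_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class MgpsOptions:
    """Fixed prior theta = (a1, b1, a2, b2, P), or fit by maximum
    marginal likelihood from ``start`` when ``prior`` is None."""

    prior: tuple[float, float, float, float, float] | None = None
    start: tuple[float, float, float, float, float] = MGPS_DEFAULT_START


@dataclass
class MgpsResult:
    theta: tuple[float, float, float, float, float]
    fitted: bool
    loglik: float
    ebgm: np.ndarray
    ebgm05: np.ndarray


def _nbinom_logpmf(a, alpha, beta, e):
    """log marginal P(a) when a ~ Poisson(lam*e), lam ~ Gamma(alpha, rate beta)."""
    p = beta / (beta + e)
    return stats.nbinom.logpmf(a, alpha, p)


def _mixture_logmarginal(a, e, theta):
    a1, b1, a2, b2, w = theta
    lp1 = _nbinom_logpmf(a, a1, b1, e) + math.log(w)
    lp2 = _nbinom_logpmf(a, a2, b2, e) + math.log(1.0 - w)
    return np.logaddexp(lp1, lp2), lp1, lp2


def expected_counts(tables: Sequence[ContingencyTable]) -> np.ndarray:
    """E_i = (a+b)(a+c)/n, the expected count under independence."""
    return np.array([(t.a + t.b) * (t.a + t.c) / t.n if t.n else _UNDEF
                     for t in tables])


def fit_mgps_prior(a: np.ndarray, e: np.ndarray,
                   start=MGPS_DEFAULT_START) -> tuple[tuple, float]:
    """Maximize the product of negative-binomial mixture marginals.

    Deterministic quasi-Newton (L-BFGS-B) on log/logit-transformed
    parameters from the stated start.  Returns (theta_hat, loglik).
    """
    if not (a > 0).any():
        raise FitError("all observed counts are zero; supply a fixed prior")

    def unpack(x):
        return (math.exp(x[0]), math.exp(x[1]), math.exp(x[2]), math.exp(x[3]),
                1.0 / (1.0 + math.exp(-x[4])))

    def nll(x):
        theta = unpack(x)
        with np.errstate(all="ignore"):
            lm, _, _ = _mixture_logmarginal(a, e, theta)
            val = -float(lm.sum())
        return val if math.isfinite(val) else 1e300

    x0 = np.array([math.log(start[0]), math.log(start[1]), math.log(start[2]),
                   math.log(start[3]), math.log(start[4] / (1 - start[4]))])
    res = optimize.minimize(nll, x0, method="L-BFGS-B",
                            bounds=[(-20.0, 20.0)] * 5,
                            options={"maxiter": 500, "ftol": 1e-12})
    return unpack(res.x), -float(res.fun)


def _posterior_mix(a_i: float, e_i: float, theta):
    """Posterior over lambda: weights and gamma(shape, rate) parameters."""
    a1, b1, a2, b2, _ = theta
    _, lp1, lp2 = _mixture_logmarginal(np.array([a_i]), np.array([e_i]), theta)
    q1 = float(np.exp(lp1 - np.logaddexp(lp1, lp2))[0])
    return ((q1, a1 + a_i, b1 + e_i), (1.0 - q1, a2 + a_i, b2 + e_i))


def _ebgm_pair(a_i: float, e_i: float, theta) -> tuple[float, float]:
    comps = _posterior_mix(a_i, e_i, theta)
    mean_log2 = sum(q * (special.digamma(shape) - math.log(rate))
                    for q, shape, rate in comps) / math.log(2)
    ebgm = 2.0 ** mean_log2

    def cdf(x):
        return sum(q * stats.gamma.cdf(x, shape, scale=1.0 / rate)
                   for q, shape, rate in comps)

    lo = min(stats.gamma.ppf(0.05, shape, scale=1.0 / rate)
             for _, shape, rate in comps)
    hi = max(stats.gamma.ppf(0.05, shape, scale=1.0 / rate)
             for _, shape, rate in comps)
    lo, hi = 0.5 * lo, 2.0 * hi
    while cdf(lo) > 0.05:
        lo *= 0.5
    while cdf(hi) < 0.05:
        hi *= 2.0
    ebgm05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-10)
    return ebgm, ebgm05


def ebgm_mgps(tables: Sequence[ContingencyTable],
              options: MgpsOptions = MgpsOptions()) -> MgpsResult:
    """EBGM and EBGM05 for every table of one corpus.

    Expected counts E_i = (a+b)(a+c)/n are computed per table; the prior
    on the relative reporting ratio lambda is the two-component gamma
    mixture P*Gamma(a1, b1) + (1-P)*Gamma(a2, b2) (shape/rate), shared
    across the corpus and either fixed or fitted by maximum marginal
    likelihood.  Per table, EBGM = 2**E[log2 lambda | a] and EBGM05 is
    the 5th percentile of the posterior mixture (root of the mixture CDF,
    tolerance 1e-10).  Tables with E_i = 0 get NaN.
    """
    if len(tables) < 2:
        raise ConfigurationError("MGPS shrinkage requires a corpus of >= 2 tables")
    a = np.array([float(t.a) for t in tables])
    e = expected_counts(tables)
    usable = np.isfinite(e) & (e > 0)
    if options.prior is not None:
        theta = tuple(float(x) for x in options.prior)
        if min(theta[:4]) <= 0 or not 0 < theta[4] <= 1:
            raise ConfigurationError("MGPS prior components must be positive, P in (0, 1]")
        if theta[4] == 1.0:  # single component: avoid log(0) weight
            theta = (theta[0], theta[1], theta[0], theta[1], 0.5)
        lm, _, _ = _mixture_logmarginal(a[usable], e[usable], theta)
        loglik = float(lm.sum())
        fitted = False
    else:
        theta, loglik = fit_mgps_prior(a[usable], e[usable], options.start)
        fitted = True
    ebgm = np.full(len(tables), _UNDEF)
    ebgm05 = np.full(len(tables), _UNDEF)
    for i in np.nonzero(usable)[0]:
        ebgm[i], ebgm05[i] = _ebgm_pair(a[i], e[i], theta)
    return MgpsResult(theta=theta, fitted=fitted, loglik=loglik,
                      ebgm=ebgm, ebgm05=ebgm05)


# ---------------------------------------------------------------------------
# Result assembly, signal criteria, ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalCriteria:
    """Thresholds for the per-algorithm signal flags.

    ROR and PRR cuts are inclusive (>=); the CI lower bound, IC-2SD and
    EBGM05 cuts are strict (>).  ``min_a`` gates every algorithm.
    """

    min_a: int = 3
    ror_min: float = 2.0
    ror_ci_low_exceeds: float = 1.0
    prr_min: float = 2.0
    chisq_min: float = 4.0
    ic025_exceeds: float = 0.0
    ebgm05_exceeds: float = 2.0


@dataclass
class SignalResult:
    """Per-(drug, event) statistics and signal flags."""

    event_label: str
    a: int
    ror: float = _UNDEF
    ror_ci_low: float = _UNDEF
    ror_ci_high: float = _UNDEF
    prr: float = _UNDEF
    prr_ci_low: float = _UNDEF
    prr_ci_high: float = _UNDEF
    chisq: float = _UNDEF
    ic: float = _UNDEF
    v_ic: float = _UNDEF
    ic_minus_2sd: float = _UNDEF
    ebgm: float = _UNDEF
    ebgm05: float = _UNDEF
    flags: dict = field(default_factory=dict)


def _ge(x: float, cut: float) -> bool:
    return bool(np.isfinite(x) and x >= cut)


def _gt(x: float, cut: float) -> bool:
    return bool(np.isfinite(x) and x > cut)


def evaluate_signals(results: Sequence[SignalResult],
                     criteria: SignalCriteria = SignalCriteria(),
                     ) -> list[SignalResult]:
    """Attach per-algorithm and combined signal flags.

    An undefined statistic never signals.  ``all_of``/``any_of`` are the
    conjunction/disjunction of the four per-algorithm flags.
    """
    out = []
    for r in results:
        gate = r.a >= criteria.min_a
        flags = {
            "ror_signal": gate and _ge(r.ror, criteria.ror_min)
            and _gt(r.ror_ci_low, criteria.ror_ci_low_exceeds),
            "prr_signal": gate and _ge(r.prr, criteria.prr_min)
            and _ge(r.chisq, criteria.chisq_min),
            "bcpnn_signal": gate and _gt(r.ic_minus_2sd, criteria.ic025_exceeds),
            "ebgm_signal": gate and _gt(r.ebgm05, criteria.ebgm05_exceeds),
        }
        flags["all_of"] = all(flags.values())
        flags["any_of"] = any(v for k, v in flags.items() if k != "all_of")
        out.append(replace(r, flags=flags))
    return out


def rank_results(results: Sequence[SignalResult], key: str = "ebgm",
                 top_n: int | None = None) -> list[SignalResult]:
    """Descending by ``key``; ties by (a descending, label ascending).

    NaN statistics sort last.  Stable and deterministic for any input
    order.
    """
    if not results:
        raise ConfigurationError("rank_results requires a non-empty result list")
    if key not in SignalResult.__dataclass_fields__ or key in ("event_label", "flags"):
        raise ConfigurationError(f"unknown ranking key {key!r}")

    def sort_key(r: SignalResult):
        v = getattr(r, key)
        defined = np.isfinite(v) if isinstance(v, float) else True
        return (0 if defined else 1, -(v if defined else 0.0), -r.a, r.event_label)

    ranked = sorted(results, key=sort_key)
    return ranked[:top_n] if top_n is not None else ranked


def compute_signals(tables: Sequence[tuple[str, ContingencyTable]],
                    priors: BcpnnPriors = BcpnnPriors(),
                    mgps: MgpsOptions = MgpsOptions(),
                    criteria: SignalCriteria = SignalCriteria(),
                    haldane: bool = False) -> list[SignalResult]:
    """Full statistics + flags for a labelled corpus of 2x2 tables."""
    results = []
    for label, t in tables:
        ror_e, ror_lo, ror_hi = ror(t, haldane)
        prr_e, prr_lo, prr_hi = prr(t, haldane)
        ic, v_ic, ic025 = bcpnn(t, priors)
        results.append(SignalResult(
            event_label=label, a=t.a,
            ror=ror_e, ror_ci_low=ror_lo, ror_ci_high=ror_hi,
            prr=prr_e, prr_ci_low=prr_lo, prr_ci_high=prr_hi,
            chisq=chisq_yates(t), ic=ic, v_ic=v_ic, ic_minus_2sd=ic025))
    if len(tables) >= 2:
        mg = ebgm_mgps([t for _, t in tables], mgps)
        for r, g, g05 in zip(results, mg.ebgm, mg.ebgm05):
            r.ebgm, r.ebgm05 = float(g), float(g05)
    return evaluate_signals(results, criteria)


RESULT_COLUMNS = ["event", "case_reports", "ror", "ror_ci_low", "ror_ci_high",
                  "prr", "prr_ci_low", "prr_ci_high", "chisq", "ic", "ic025",
                  "ebgm", "ebgm05", "ror_signal", "prr_signal", "bcpnn_signal",
                  "ebgm_signal", "all_of", "any_of"]


def results_to_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Export frame with one row per event, flags as booleans."""
    rows = []
    for r in results:
        rows.append({
            "event": r.event_label, "case_reports": r.a,
            "ror": r.ror, "ror_ci_low": r.ror_ci_low, "ror_ci_high": r.ror_ci_high,
            "prr": r.prr, "prr_ci_low": r.prr_ci_low, "prr_ci_high": r.prr_ci_high,
            "chisq": r.chisq, "ic": r.ic, "ic025": r.ic_minus_2sd,
            "ebgm": r.ebgm, "ebgm05": r.ebgm05,
            **{k: r.flags.get(k, False) for k in
               ("ror_signal", "prr_signal", "bcpnn_signal", "ebgm_signal",
                "all_of", "any_of")},
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
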