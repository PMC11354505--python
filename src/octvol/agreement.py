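"""Bland-Altman agreement statistics and power for agreement designs.

Conventions (all at the literal 1.96 multiplier, not a t-quantile):

* difference = value_a - value_b, in the order the comparison is named
  ("A-B" means A minus B);
* bias = mean(diffs); s = sample SD of diffs (n-1 denominator);
* bias CI = bias +/- 1.96 * s / sqrt(n);
* coefficient of repeatability CR = 1.96 * s;
* limits of agreement LOA = bias +/- CR;
* each LOA's CI = LOA +/- 1.96 * SE_LOA with SE_LOA = sqrt(3 s^2 / n).

``loa_se_mode="table1"`` substitutes SE_LOA = 3 s / sqrt(n) (a factor
sqrt(3) wider), provided as a compatibility option for published tables
whose LOA CIs follow that convention.

Power for an agreement study asks: with differences drawn from
Normal(bias, sd^2) and n pairs, what is the probability that *both* LOA
confidence intervals fall strictly inside the clinical agreement band
(-delta, +delta)?  ``agreement_power`` evaluates this either by direct
numerical integration over the sampling distributions of the mean and SD
("approximate") or by Monte-Carlo simulation of the full estimator
pipeline ("monte_carlo", the oracle).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .annotation_io import PairedMeasurements
from .errors import InsufficientDataError

logger = logging.getLogger("octvol")

__all__ = [
    "AgreementResult",
    "PowerSpec",
    "PowerResult",
    "BAPlotData",
    "bland_altman",
    "agreement_from_summary",
    "agreement_power",
    "ba_plot_data",
]

DEFAULT_CLINICAL_DELTA_MM3 = 0.01
DEFAULT_MC_SEED = 2024


def _z(confidence: float) -> float:
    # The published convention is the literal 1.96, not Phi^-1(0.975).
    if confidence == 0.95:
        return 1.96
    return float(stats.norm.ppf(0.5 + confidence / 2.0))


def _se_loa(sd: float, n: int, mode: str) -> float:
    if mode == "bland":
        return math.sqrt(3.0 * sd * sd / n)
    if mode == "table1":
        return 3.0 * sd / math.sqrt(n)
    raise ValueError(f"loa_se_mode must be 'bland' or 'table1', got {mode!r}")


@dataclass
class AgreementResult:
    """Bias, repeatability and limits of agreement for one paired comparison."""

    n: int
    bias: float
    sd: float
    se_bias: float
    bias_ci: tuple[float, float]
    cr: float
    loa_lower: float
    loa_upper: float
    se_loa: float
    loa_ci_lower: tuple[float, float]
    loa_ci_upper: tuple[float, float]
    loa_se_mode: str = "bland"
    comparison: str = ""
    means: np.ndarray = field(default_factory=lambda: np.empty(0))
    diffs: np.ndarray = field(default_factory=lambda: np.empty(0))

    def rounded(self, ndigits: int = 4) -> dict[str, object]:
        """Report-style view with every statistic rounded to ``ndigits`` dp."""
        r = lambda v: round(v, ndigits)
        return {
            "comparison": self.comparison,
            "n": self.n,
            "bias": r(self.bias),
            "bias_ci": (r(self.bias_ci[0]), r(self.bias_ci[1])),
            "loa_lower": r(self.loa_lower),
            "loa_ci_lower": (r(self.loa_ci_lower[0]), r(self.loa_ci_lower[1])),
            "loa_upper": r(self.loa_upper),
            "loa_ci_upper": (r(self.loa_ci_upper[0]), r(self.loa_ci_upper[1])),
            "cr": r(self.cr),
        }


def _assemble(
    n: int,
    bias: float,
    sd: float,
    loa_se_mode: str,
    comparison: str,
    means: np.ndarray,
    diffs: np.ndarray,
) -> AgreementResult:
    se_bias = sd / math.sqrt(n)
    cr = 1.96 * sd
    se_loa = _se_loa(sd, n, loa_se_mode)
    loa_lower = bias - cr
    loa_upper = bias + cr
    return AgreementResult(
        n=n,
        bias=bias,
        sd=sd,
        se_bias=se_bias,
        bias_ci=(bias - 1.96 * se_bias, bias + 1.96 * se_bias),
        cr=cr,
        loa_lower=loa_lower,
        loa_upper=loa_upper,
        se_loa=se_loa,
        loa_ci_lower=(loa_lower - 1.96 * se_loa, loa_lower + 1.96 * se_loa),
        loa_ci_upper=(loa_upper - 1.96 * se_loa, loa_upper + 1.96 * se_loa),
        loa_se_mode=loa_se_mode,
        comparison=comparison,
        means=means,
        diffs=diffs,
    )


def bland_altman(pairs: PairedMeasurements, loa_se_mode: str = "bland") -> AgreementResult:
    """Full Bland-Altman analysis of one paired comparison (a - b)."""
    n = pairs.n
    if n < 3:
        raise InsufficientDataError(f"Bland-Altman analysis needs n >= 3 pairs, got {n}")
    a, b = pairs.values_a, pairs.values_b
    diffs = a - b
    means = (a + b) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        logger.warning(
            "zero variance of differences (n=%d); limits of agreement collapse to the bias", n
        )
    return _assemble(
        n,
        bias,
        sd,
        loa_se_mode,
        f"{pairs.method_a_label}-{pairs.method_b_label}",
        means,
        diffs,
    )


def agreement_from_summary(
    bias: float,
    cr: float,
    n: int,
    loa_se_mode: str = "bland",
    comparison: str = "",
) -> AgreementResult:
    """Reconstruct an :class:`AgreementResult` from published summary statistics.

    Takes the reported bias, coefficient of repeatability and sample size;
    the SD of differences is recovered as ``cr / 1.96``.  Used to check a
    published table's limits of agreement and CIs for internal consistency.
    """
    if n < 3:
        raise InsufficientDataError(f"n >= 3 required, got {n}")
    if cr < 0:
        raise ValueError(f"cr must be >= 0, got {cr}")
    return _assemble(n, bias, cr / 1.96, loa_se_mode, comparison, np.empty(0), np.empty(0))


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for an agreement-study power calculation."""

    bias: float
    sd: float
    n: int
    delta: float = DEFAULT_CLINICAL_DELTA_MM3
    loa_confidence: float = 0.95
    ci_confidence: float = 0.95
    loa_se_mode: str = "bland"

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if not self.sd > 0:
            raise ValueError(f"sd must be > 0, got {self.sd}")
        if self.n < 3:
            raise ValueError(f"n must be >= 3, got {self.n}")


@dataclass
class PowerResult:
    power: float
    method: str
    spec: PowerSpec
    mc_se: float | None = None
    sims: int | None = None
    seed: int | None = None


def _acceptance_halfwidth_coeff(spec: PowerSpec) -> float:
    """Coefficient c such that the study succeeds iff |mean| + c * s < delta."""
    z_loa = _z(spec.loa_confidence)
    z_ci = _z(spec.ci_confidence)
    if spec.loa_se_mode == "bland":
        return z_loa + z_ci * math.sqrt(3.0 / spec.n)
    if spec.loa_se_mode == "table1":
        return z_loa + z_ci * 3.0 / math.sqrt(spec.n)
    raise ValueError(f"loa_se_mode must be 'bland' or 'table1', got {spec.loa_se_mode!r}")


def _power_exact(spec: PowerSpec) -> float:
    # P(|xbar| + c*s < delta) with xbar ~ N(mu, sigma^2/n) independent of
    # s = sigma * sqrt(U/(n-1)), U ~ chi2(n-1).  Integrate the Gaussian
    # probability of the mean over the chi-square density of the SD.
    mu, sigma, n = spec.bias, spec.sd, spec.n
    delta = spec.delta
    c = _acceptance_halfwidth_coeff(spec)
    k = n - 1
    u_max = k * (delta / (c * sigma)) ** 2
    # Cap at the chi-square's effective support so huge delta/sd ratios do
    # not dilute the quadrature over an astronomically wide, empty range.
    u_hi = min(u_max, float(stats.chi2.isf(1e-14, k)))
    root_n = math.sqrt(n)

    def integrand(u: float) -> float:
        s = sigma * math.sqrt(u / k)
        m = delta - c * s  # |xbar| must fall below this margin
        p_mean = stats.norm.cdf((m - mu) * root_n / sigma) - stats.norm.cdf(
            (-m - mu) * root_n / sigma
        )
        return p_mean * stats.chi2.pdf(u, k)

    value, _ = integrate.quad(integrand, 0.0, u_hi, limit=200)
    if u_max > u_hi:
        # Everything beyond u_hi is accepted with probability ~ P(mean band),
        # but carries chi-square mass <= 1e-14; fold it in as an upper bound.
        value += float(stats.chi2.sf(u_hi, k))
    return min(max(value, 0.0), 1.0)


def _power_monte_carlo(spec: PowerSpec, sims: int, seed: int) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    z_loa = _z(spec.loa_confidence)
    z_ci = _z(spec.ci_confidence)
    n = spec.n
    successes = 0
    # Chunked so a 1e5-sim run at large n stays well under memory limits.
    chunk = max(1, min(sims, int(2e7) // n))
    remaining = sims
    while remaining > 0:
        m = min(chunk, remaining)
        d = rng.normal(spec.bias, spec.sd, size=(m, n))
        xbar = d.mean(axis=1)
        s = d.std(axis=1, ddof=1)
        if spec.loa_se_mode == "bland":
            se = np.sqrt(3.0 * s * s / n)
        else:
            se = 3.0 * s / math.sqrt(n)
        upper_ok = xbar + z_loa * s + z_ci * se < spec.delta
        lower_ok = xbar - z_loa * s - z_ci * se > -spec.delta
        successes += int(np.count_nonzero(upper_ok & lower_ok))
        remaining -= m
    p = successes / sims
    return p, math.sqrt(max(p * (1.0 - p), 1.0 / sims) / sims)


def agreement_power(
    spec: PowerSpec,
    method: str = "approximate",
    sims: int = 100_000,
    seed: int = DEFAULT_MC_SEED,
) -> PowerResult:
    """Probability that both LOA confidence intervals fall inside (-delta, delta).

    ``method="approximate"`` integrates the exact sampling distributions of
    the mean and SD of the differences (deterministic).  ``method=
    "monte_carlo"`` simulates the full Bland-Altman estimator pipeline and
    serves as the oracle the approximation is checked against.
    """
    if method == "approximate":
        return PowerResult(power=_power_exact(spec), method=method, spec=spec)
    if method == "monte_carlo":
        if sims < 1000:
            raise ValueError(f"monte_carlo requires sims >= 1000, got {sims}")
        p, se = _power_monte_carlo(spec, sims, seed)
        return PowerResult(power=p, method=method, spec=spec, mc_se=se, sims=sims, seed=seed)
    raise ValueError(f"method must be 'approximate' or 'monte_carlo', got {method!r}")


# ---------------------------------------------------------------------------
# Plot data
# ---------------------------------------------------------------------------


@dataclass
class BAPlotData:
    """Numbers behind a Bland-Altman plot: one (mean, diff) row per pair plus
    the horizontal reference lines, taken bit-exactly from the result."""

    points: pd.DataFrame
    lines: dict[str, float]


def ba_plot_data(result: AgreementResult) -> BAPlotData:
    points = pd.DataFrame({"mean": result.means, "diff": result.diffs})
    lines = {
        "bias": result.bias,
        "bias_ci_low": result.bias_ci[0],
        "bias_ci_high": result.bias_ci[1],
        "loa_lower": result.loa_lower,
        "loa_lower_ci_low": result.loa_ci_lower[0],
        "loa_lower_ci_high": result.loa_ci_lower[1],
        "loa_upper": result.loa_upper,
        "loa_upper_ci_low": result.loa_ci_upper[0],
        "loa_upper_ci_high": result.loa_ci_upper[1],
    }
    return BAPlotData(points=points, lines=lines)
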