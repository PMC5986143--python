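"""Statistical procedures for count and morphometric data.

Implements the zero-truncated Poisson (ZTP) null model for per-bouton counts
(e.g. microtubules per bouton) with a G-test against binned observed counts,
two-sample t-tests computable from printed summary statistics (mean, sd, n),
the uncorrected 2x2 chi-square test, and Pearson correlation.

The ZTP is the Poisson distribution conditioned on k >= 1:

    P(k) = lambda^k / ((e^lambda - 1) k!),   k = 1, 2, ...

with mean m = lambda / (1 - e^-lambda). The rate lambda is recovered from an
observed mean by root finding (moment estimator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import special
from scipy import stats as sps

__all__ = [
    "ZTPModel",
    "GTestResult",
    "SummaryTwoSample",
    "StatResult",
    "ztp_pmf",
    "ztp_mean",
    "ztp_lambda_from_mean",
    "ztp_sample",
    "bin_counts",
    "bin_probabilities",
    "DEFAULT_BINS",
    "g_test",
    "ztp_gof",
    "t_test_from_summary",
    "chi2_2x2",
    "pearson",
]

# count bins used for the per-bouton goodness-of-fit: singletons 1..5, then
# 6-8 pooled, then the open tail
DEFAULT_BINS = ((1, 1), (2, 2), (3, 3), (4, 4), (5, 5), (6, 8), (9, None))


@dataclass
class ZTPModel:
    """Zero-truncated Poisson with rate ``lambda_`` (> 0); mean > 1."""

    lambda_: float

    def __post_init__(self):
        if not self.lambda_ > 0:
            raise ValueError("lambda_ must be positive")

    @property
    def mean(self) -> float:
        return ztp_mean(self.lambda_)

    def pmf(self, k) -> np.ndarray:
        return ztp_pmf(k, self.lambda_)


@dataclass
class GTestResult:
    g: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray


@dataclass
class SummaryTwoSample:
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    df: float
    p_value: float
    pooled: bool = True


@dataclass
class StatResult:
    test: str
    statistic: float
    df: float
    p_value: float
    inputs: dict = field(default_factory=dict)


def ztp_pmf(k, lambda_: float):
    """P(k) = lambda^k / ((e^lambda - 1) k!), evaluated in log space."""
    if not lambda_ > 0:
        raise ValueError("lambda_ must be positive")
    k_arr = np.asarray(k)
    if np.any(k_arr < 1) or np.any(k_arr != np.floor(k_arr)):
        raise ValueError("k must be integer >= 1")
    # log(e^lambda - 1) = lambda + log(1 - e^-lambda), stable for any lambda
    log_norm = lambda_ + math.log1p(-math.exp(-lambda_))
    logp = k_arr * math.log(lambda_) - special.gammaln(k_arr + 1) - log_norm
    out = np.exp(logp)
    return float(out) if np.isscalar(k) else out


def ztp_mean(lambda_: float) -> float:
    return lambda_ / (1.0 - math.exp(-lambda_))


def ztp_lambda_from_mean(m: float, tol: float = 1e-12) -> float:
    """Invert m = lambda / (1 - e^-lambda) by Brent root finding.

    Defined for m > 1 (the ZTP mean approaches 1 as lambda -> 0).
    """
    if not m > 1:
        raise ValueError("zero-truncated Poisson mean must exceed 1")
    # ztp_mean(x) < x + 1 so f(m) > 0; f -> 1 - m < 0 as x -> 0
    f = lambda x: ztp_mean(x) - m
    lo = 1e-12
    hi = m
    if f(hi) <= 0:  # pragma: no cover - f(m) > 0 analytically
        hi = m + 1
    return float(optimize.brentq(f, lo, hi, xtol=tol, rtol=8.9e-16))


def ztp_sample(lambda_: float, size: int, rng) -> np.ndarray:
    """Draw ZTP counts by rejection of Poisson zeros."""
    out = np.empty(size, dtype=np.int64)
    filled = 0
    while filled < size:
        draw = rng.poisson(lambda_, size=max(size - filled, 16))
        draw = draw[draw > 0]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def bin_counts(histogram, bins=DEFAULT_BINS) -> np.ndarray:
    """Pool a histogram over k >= 1 into the analysis bins.

    ``histogram`` maps k -> count (dict) or is a sequence of counts where
    position i corresponds to k = i + 1.
    """
    if isinstance(histogram, dict):
        items = {int(k): int(v) for k, v in histogram.items()}
    else:
        items = {i + 1: int(v) for i, v in enumerate(histogram)}
    if any(k < 1 for k in items) or any(v < 0 for v in items.values()):
        raise ValueError("histogram must have integer k >= 1 and counts >= 0")
    out = np.zeros(len(bins), dtype=np.int64)
    for k, v in items.items():
        for i, (lo, hi) in enumerate(bins):
            if k >= lo and (hi is None or k <= hi):
                out[i] += v
                break
        else:
            raise ValueError(f"count k={k} falls outside every bin")
    return out


def bin_probabilities(lambda_: float, bins=DEFAULT_BINS) -> np.ndarray:
    """ZTP probability mass pooled into the same bins (open tail = 1 - CDF)."""
    probs = np.zeros(len(bins))
    for i, (lo, hi) in enumerate(bins):
        if hi is None:
            ks = np.arange(1, lo)
            probs[i] = 1.0 - float(np.sum(ztp_pmf(ks, lambda_))) if lo > 1 else 1.0
        else:
            ks = np.arange(lo, hi + 1)
            probs[i] = float(np.sum(ztp_pmf(ks, lambda_)))
    return probs


def g_test(observed, expected) -> GTestResult:
    """Log-likelihood-ratio goodness of fit: G = 2 sum f_i ln(f_i / fhat_i).

    ``expected`` is rescaled to the observed total; bins with observed = 0
    contribute nothing (0 ln 0 := 0); an expected 0 with observed > 0 is an
    error. Compared against chi-square with (number of bins - 1) df.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed/expected must be equal-length 1D, length >= 2")
    if np.any(obs < 0) or np.any(exp < 0):
        raise ValueError("negative frequencies")
    if np.any((exp == 0) & (obs > 0)):
        raise ValueError("expected frequency 0 where observed > 0")
    exp = exp * (obs.sum() / exp.sum())
    nz = obs > 0
    g = 2.0 * float(np.sum(obs[nz] * np.log(obs[nz] / exp[nz])))
    df = obs.size - 1
    p = float(sps.chi2.sf(g, df))
    return GTestResult(g=g, df=df, p_value=p, observed=obs, expected=exp)


def ztp_gof(histogram, bins=DEFAULT_BINS) -> GTestResult:
    """Fit a ZTP to a count histogram by the moment estimator and G-test it.

    The rate is estimated from the observed mean; expected bin frequencies are
    the binned ZTP masses scaled to the sample size.
    """
    if isinstance(histogram, dict):
        ks = np.array(sorted(histogram))
        ns = np.array([histogram[k] for k in ks], dtype=float)
    else:
        ks = np.arange(1, len(histogram) + 1)
        ns = np.asarray(histogram, dtype=float)
    n = ns.sum()
    if n <= 0:
        raise ValueError("empty histogram")
    mean = float((ks * ns).sum() / n)
    lam = ztp_lambda_from_mean(mean)
    obs = bin_counts(dict(zip((int(k) for k in ks), (int(v) for v in ns))), bins)
    exp = bin_probabilities(lam, bins) * n
    return g_test(obs, exp)


def t_test_from_summary(mean1, sd1, n1, mean2, sd2, n2,
                        welch: bool = False) -> SummaryTwoSample:
    """Two-sided two-sample t-test from summary statistics.

    Pooled (Student) variance by default; Welch with ``welch=True``. Both
    samples need n >= 2 and sd >= 0. Two identical degenerate samples give
    t = 0, p = 1 by convention.
    """
    for n in (n1, n2):
        if n < 2:
            raise ValueError("each sample needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return SummaryTwoSample(mean1, sd1, n1, mean2, sd2, n2,
                                    t=0.0, df=n1 + n2 - 2, p_value=1.0,
                                    pooled=not welch)
        raise ValueError("zero variance with unequal means: t undefined")
    if welch:
        se2 = sd1 ** 2 / n1 + sd2 ** 2 / n2
        t = (mean1 - mean2) / math.sqrt(se2)
        df = se2 ** 2 / ((sd1 ** 2 / n1) ** 2 / (n1 - 1)
                         + (sd2 ** 2 / n2) ** 2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
        t = (mean1 - mean2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return SummaryTwoSample(mean1, sd1, n1, mean2, sd2, n2,
                            t=float(t), df=float(df), p_value=p, pooled=not welch)


def chi2_2x2(a: int, b: int, c: int, d: int) -> StatResult:
    """Uncorrected chi-square for a 2x2 table [[a, b], [c, d]], df = 1."""
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("cell counts must be non-negative integers")
    n = a + b + c + d
    if n < 1:
        raise ValueError("empty table")
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined with a zero marginal")
    chi2 = n * (a * d - b * c) ** 2 / math.prod(margins)
    p = float(sps.chi2.sf(chi2, 1))
    return StatResult(test="chi2_2x2", statistic=float(chi2), df=1.0, p_value=p,
                      inputs={"a": a, "b": b, "c": c, "d": d})


def pearson(x, y) -> StatResult:
    """Pearson correlation with the two-sided t-transform p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1D with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has no defined correlation")
    r, p = sps.pearsonr(x, y)
    return StatResult(test="pearson", statistic=float(r), df=float(x.size - 2),
                      p_value=float(p), inputs={"n": int(x.size)})
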