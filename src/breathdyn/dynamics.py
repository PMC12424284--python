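"""The eight breathing-dynamics metrics and feature-table transforms.

Each metric is computed separately on the breath-indexed rate and amplitude
series, giving a 16-element dynamics vector per subject-condition:

* central tendency: mean
* variability: standard deviation (n-1), coefficient of variation
* timescales: ACW-50 (first lag where the autocorrelation falls below 0.5)
  and the power-law exponent beta of the power spectral density, fitted by
  OLS in log-log coordinates (reported positive, so larger beta means more
  slow-frequency power)
* complexity: normalized Lempel-Ziv phrase count of the mean-binarized
  series, and multiscale entropy (mean sample entropy over coarse-grained
  scales)
* entropy: sample entropy (m=2, r=0.2*SD by default)

The per-breath series are treated as unit-sampled sequences (breath index,
not clock time), so ACW lags are in breaths and PSD frequencies in cycles
per breath.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import FEATURE_COLUMNS, FeatureTable
from .preprocess import BreathSeries, quality_summary

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameter containers

@dataclass
class SampEnParams:
    """Sample-entropy parameters: embedding dimension m, tolerance fraction
    r_factor (r = r_factor * SD of the series), embedding delay in samples."""

    m: int = 2
    r_factor: float = 0.2
    delay: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if not 0 < self.r_factor < 1:
            raise ValueError("r_factor must be in (0, 1)")
        if self.delay < 1:
            raise ValueError("delay must be >= 1")


@dataclass
class MSEParams:
    """Multiscale-entropy parameters.

    ``scales=None`` means 1..min(10, len(x)//10). The tolerance r is fixed
    from the ORIGINAL series' SD across all scales (Costa's convention)
    unless ``r_per_scale`` is set.
    """

    base: SampEnParams = field(default_factory=SampEnParams)
    scales: tuple[int, ...] | None = None
    summary: str = "mean"
    r_per_scale: bool = False

    def resolve_scales(self, n: int) -> tuple[int, ...]:
        if self.scales is not None:
            if any(s < 1 for s in self.scales):
                raise ValueError("every scale must be >= 1")
            return tuple(self.scales)
        return tuple(range(1, min(10, n // 10) + 1))


# ---------------------------------------------------------------------------
# result containers

@dataclass
class AcfProfile:
    lags: np.ndarray
    acf: np.ndarray
    acw50: int
    capped: bool = False


@dataclass
class PSDEstimate:
    freqs: np.ndarray
    power: np.ndarray
    beta: float
    raw_slope: float
    fit_range: tuple[float, float]


@dataclass
class LZCResult:
    pattern_count: int
    n: int
    normalized: float


@dataclass
class MSEProfile:
    scales: tuple[int, ...]
    sampen: np.ndarray
    summary: float


# ---------------------------------------------------------------------------
# elementary statistics

def series_mean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    return float(np.mean(x))


def series_sd(x: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    return float(np.std(x, ddof=1))


def series_cv(x: np.ndarray) -> float:
    """Coefficient of variation sd/mean (dimensionless)."""
    m = series_mean(x)
    if m == 0:
        raise ValueError("cv undefined for zero-mean series")
    return series_sd(x) / m


# ---------------------------------------------------------------------------
# timescales

def autocorr_window(x: np.ndarray, max_lag: int | None = None) -> AcfProfile:
    """Biased autocorrelation function and the ACW-50 timescale.

    The estimator normalizes the lag-k autocovariance (n denominator) by
    the lag-0 autocovariance. ACW-50 is the first integer lag where the
    ACF drops below 0.5; if it never does within n/2 lags the window is
    capped there and flagged.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 values for an ACF")
    xc = x - x.mean()
    var = float(np.dot(xc, xc))
    if var == 0:
        raise ValueError("zero-variance series")
    L = max_lag if max_lag is not None else n // 2
    # FFT-based autocovariance, biased (n denominator cancels in the ratio)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f))[: L + 1]
    acf = acov / acov[0]
    below = np.flatnonzero(acf[1:] < 0.5)
    if below.size:
        acw50, capped = int(below[0] + 1), False
    else:
        acw50, capped = L, True
    return AcfProfile(lags=np.arange(L + 1), acf=acf, acw50=acw50, capped=capped)


def psd_slope(x: np.ndarray) -> PSDEstimate:
    """Power-law exponent of the periodogram via log-log OLS.

    The mean-removed series is treated as unit-sampled; the periodogram
    over 0 < f <= 0.5 cycles/breath is regressed (log10 power on log10
    frequency) and beta = -slope, so beta > 0 means low-frequency
    dominance.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 32:
        raise ValueError("need at least 32 values for a PSD slope")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance series")
    f, p = sps.periodogram(x - x.mean(), fs=1.0)
    keep = (f > 0) & (p > 0)
    lf, lp = np.log10(f[keep]), np.log10(p[keep])
    slope, _ = np.polyfit(lf, lp, 1)
    return PSDEstimate(
        freqs=f[keep], power=p[keep], beta=float(-slope), raw_slope=float(slope),
        fit_range=(float(f[keep].min()), float(f[keep].max())),
    )


# ---------------------------------------------------------------------------
# complexity / entropy

def _lz76_count(bits: bytes) -> int:
    """Novel-phrase count of an exhaustive LZ76 parse.

    Scanning left to right, each phrase is the shortest substring starting
    at the current position that has not occurred earlier (substring search
    over the prefix ending one character before the phrase's last one). A
    trailing remainder that is still reproducible from the history closes
    the parse without opening a new phrase, so a constant string has
    complexity 1.
    """
    n = len(bits)
    i, c = 0, 0
    while i < n:
        k = 1
        while i + k <= n and bits[i : i + k] in bits[: i + k - 1]:
            k += 1
        if i + k > n:
            break  # reproducible tail, no new phrase
        c += 1
        i += k
    return c


def lempel_ziv_complexity(x: np.ndarray) -> LZCResult:
    """Normalized Lempel-Ziv complexity of the mean-binarized series.

    Values at or above the mean map to 1, below to 0; the LZ76 phrase
    count c is normalized by c * log2(n) / n so iid coin flips approach 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 16:
        raise ValueError("need at least 16 values")
    bits = bytes((x >= x.mean()).astype(np.uint8))
    c = _lz76_count(bits)
    return LZCResult(pattern_count=c, n=n, normalized=c * np.log2(n) / n)


def _embed(x: np.ndarray, m: int, delay: int) -> np.ndarray:
    """Delay-embedding matrix with one row per template."""
    n = x.size
    rows = n - (m - 1) * delay
    if rows < 1:
        raise ValueError("series too short for embedding")
    idx = np.arange(rows)[:, None] + delay * np.arange(m)[None, :]
    return x[idx]


def _sampen_abs(x: np.ndarray, m: int, r: float, delay: int) -> float:
    """Sample entropy with an absolute tolerance r.

    B counts ordered template pairs (self-matches excluded) of length m
    whose Chebyshev distance is <= r, A the same for length m+1; both
    counts run over the templates for which the (m+1)-extension exists,
    the classic n-m template set when delay is 1. Returns NaN when no
    m-level or no (m+1)-level match exists.
    """
    x = np.asarray(x, dtype=float)
    em1 = _embed(x, m + 1, delay)           # (T, m+1)
    T = em1.shape[0]
    if T < 2:
        raise ValueError("series too short for sample entropy")
    a = 0
    b = 0
    chunk = max(16, 4_000_000 // T)
    for start in range(0, T, chunk):
        block = em1[start : start + chunk]
        match = np.abs(block[:, 0, None] - em1[:, 0][None, :]) <= r
        for k in range(1, m):
            match &= np.abs(block[:, k, None] - em1[:, k][None, :]) <= r
        b += int(match.sum())
        match &= np.abs(block[:, m, None] - em1[:, m][None, :]) <= r
        a += int(match.sum())
    # remove self-matches (diagonal)
    a -= T
    b -= T
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))


def sample_entropy(x: np.ndarray, params: SampEnParams | None = None) -> float:
    """Sample entropy with tolerance r = r_factor * SD(x)."""
    params = params or SampEnParams()
    x = np.asarray(x, dtype=float)
    if x.size < 4 * (params.m + 1):
        raise ValueError("series too short for sample entropy")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("zero-SD series")
    return _sampen_abs(x, params.m, params.r_factor * sd, params.delay)


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Means of non-overlapping blocks of size tau (remainder dropped)."""
    x = np.asarray(x, dtype=float)
    n = (x.size // tau) * tau
    if n == 0:
        raise ValueError(f"series too short for scale {tau}")
    return x[:n].reshape(-1, tau).mean(axis=1)


def multiscale_entropy(x: np.ndarray, params: MSEParams | None = None) -> MSEProfile:
    """Multiscale entropy: sample entropy of coarse-grained series.

    With the default convention the tolerance is fixed from the original
    series' SD for every scale, so the per-scale profile reflects how
    coarse-graining removes (or preserves) fast irregularity. The summary
    is the mean of the finite per-scale values.
    """
    params = params or MSEParams()
    x = np.asarray(x, dtype=float)
    scales = params.resolve_scales(x.size)
    if x.size < 10 * max(scales):
        raise ValueError(
            f"series of length {x.size} too short for scales up to {max(scales)}"
        )
    base = params.base
    sd0 = np.std(x, ddof=1)
    if sd0 == 0:
        raise ValueError("zero-SD series")
    values = []
    for tau in scales:
        cg = coarse_grain(x, tau)
        if cg.size < base.m + 2:
            values.append(float("nan"))
            continue
        if params.r_per_scale:
            sd = np.std(cg, ddof=1)
            r = base.r_factor * sd if sd > 0 else np.inf
        else:
            r = base.r_factor * sd0
        values.append(_sampen_abs(cg, base.m, r, base.delay))
    values = np.asarray(values)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("sample entropy undefined at every scale")
    if params.summary == "mean":
        summary = float(finite.mean())
    elif params.summary == "auc":
        summary = float(np.trapezoid(finite))
    else:
        raise ValueError(f"unknown MSE summary {params.summary!r}")
    return MSEProfile(scales=scales, sampen=values, summary=summary)


# ---------------------------------------------------------------------------
# the 16-feature vector

def compute_dynamics(
    series: BreathSeries,
    sampen_params: SampEnParams | None = None,
    mse_params: MSEParams | None = None,
    min_breaths: int = 20,
) -> dict[str, float]:
    """All eight metrics on the rate and amplitude series.

    Returns a dict keyed by the canonical feature names
    (``mean_rate`` ... ``mse_amp``). Metric errors are re-raised with the
    feature name attached.
    """
    q = quality_summary(series, min_breaths=min_breaths)
    if not q.ok:
        raise ValueError(f"series failed quality checks: {q.flags}")
    out: dict[str, float] = {}
    for label, x in (("rate", series.rate), ("amp", series.amplitude)):
        metrics = {
            "mean": lambda v: series_mean(v),
            "sd": lambda v: series_sd(v),
            "cv": lambda v: series_cv(v),
            "acw50": lambda v: float(autocorr_window(v).acw50),
            "psd_slope": lambda v: psd_slope(v).beta,
            "lzc": lambda v: lempel_ziv_complexity(v).normalized,
            "sampen": lambda v: sample_entropy(v, sampen_params),
            "mse": lambda v: multiscale_entropy(v, mse_params).summary,
        }
        for name, fn in metrics.items():
            try:
                out[f"{name}_{label}"] = fn(x)
            except ValueError as err:
                raise ValueError(f"{name}_{label}: {err}") from err
    return out


# ---------------------------------------------------------------------------
# feature-table transforms

def log_transform_features(table: FeatureTable) -> FeatureTable:
    """Natural log of every strictly positive feature column.

    Columns containing any non-positive value (possible for psd_slope or
    for flagged entropy values) are passed through unchanged and recorded
    in ``untransformed``.
    """
    if table.transform_state != "raw":
        raise ValueError(f"expected a raw table, got {table.transform_state}")
    df = table.df.copy()
    skipped = []
    for col in FEATURE_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        if np.all(vals[np.isfinite(vals)] > 0):
            df[col] = np.log(vals)
        else:
            skipped.append(col)
    if skipped:
        warnings.warn(f"columns left untransformed (non-positive values): {skipped}")
    return FeatureTable(df, "logged", tuple(skipped))


def harmonize_sites(table: FeatureTable, min_per_site: int = 3) -> FeatureTable:
    """Location/scale site harmonization of a logged feature table.

    Each site's values are standardized by the site mean/SD and rescaled
    to the pooled mean/SD per feature (a simplified ComBat without
    empirical-Bayes shrinkage). Afterwards every site's feature means
    equal the grand mean. A single-site table is returned unchanged.
    """
    if table.transform_state != "logged":
        raise ValueError(f"expected a logged table, got {table.transform_state}")
    df = table.df.copy()
    sites = df["site"].unique()
    counts = df["site"].value_counts()
    small = counts[counts < min_per_site]
    if len(sites) > 1 and len(small):
        raise ValueError(f"sites with fewer than {min_per_site} rows: {dict(small)}")
    if len(sites) > 1:
        for col in FEATURE_COLUMNS:
            pooled_mean = df[col].mean()
            pooled_sd = df[col].std(ddof=1)
            for site in sites:
                mask = df["site"] == site
                m = df.loc[mask, col].mean()
                s = df.loc[mask, col].std(ddof=1)
                if s == 0:
                    raise ValueError(f"zero within-site SD for {col} at site {site}")
                df.loc[mask, col] = (df.loc[mask, col] - m) / s * pooled_sd + pooled_mean
    return FeatureTable(df, "harmonized", table.untransformed)
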