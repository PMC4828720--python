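"""Downstream statistics for per-tumor quantification tables.

Covers the analyses run on tumor observations: Gaussian kernel density
estimation of proliferative indices by size class, quadratic regression of
proliferative index against log10 tumor volume, two-sided variance F-tests
between size classes, Pearson correlation, and the size classification
itself (large means log10 volume > 5.0; the small/medium cutoff defaults
to 4.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "DEFAULT_SIZE_CUTOFFS",
    "TumorObservation",
    "size_class",
    "GaussianKDE",
    "gaussian_kde",
    "QuadraticFit",
    "quadratic_fit",
    "FTestResult",
    "variance_f_test",
    "pearson_r",
    "quantification_report",
]

#: (small|medium, medium|large) cutoffs on log10 tumor volume (μm³).
DEFAULT_SIZE_CUTOFFS: tuple[float, float] = (4.5, 5.0)


@dataclass
class TumorObservation:
    """One tumor's derived quantities for the statistical layer."""

    tumor_id: int
    log10_volume: float
    proliferative_index: float
    gliosis_index: float
    size_class: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.log10_volume):
            raise ValueError("log10_volume must be finite")
        for name in ("proliferative_index", "gliosis_index"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.size_class:
            self.size_class = size_class(self.log10_volume)


def size_class(
    log10_volume: float, cutoffs: tuple[float, float] = DEFAULT_SIZE_CUTOFFS
) -> str:
    """Classify a tumor by log10 volume; boundaries belong to the lower
    class (large strictly requires log10 V > cutoffs[1])."""
    lo, hi = cutoffs
    if not lo < hi:
        raise ValueError(f"cutoffs must be strictly increasing, got {cutoffs}")
    if log10_volume > hi:
        return "large"
    if log10_volume <= lo:
        return "small"
    return "medium"


class GaussianKDE:
    """Gaussian kernel density estimate with an explicit bandwidth in data
    units.

    The density is the equal-weight mixture of Normal(vᵢ, h²) kernels; with
    ``bandwidth='scott'`` (default) h = σ̂ · n^(−1/5). A single observation
    requires an explicit bandwidth.
    """

    def __init__(self, values, bandwidth="scott"):
        values = np.asarray(values, dtype=float).ravel()
        if values.size == 0:
            raise ValueError("KDE requires at least one value")
        if isinstance(bandwidth, str):
            if bandwidth != "scott":
                raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
            if values.size < 2:
                raise ValueError("auto bandwidth requires at least 2 values")
            sd = values.std(ddof=1)
            if sd == 0:
                raise ValueError("auto bandwidth undefined for constant data")
            h = sd * values.size ** (-1 / 5)
        else:
            h = float(bandwidth)
            if h <= 0:
                raise ValueError("bandwidth must be positive")
        self.values = values
        self.bandwidth = h

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.values) / self.bandwidth
        dens = np.exp(-0.5 * z**2).sum(-1)
        dens /= self.values.size * self.bandwidth * np.sqrt(2 * np.pi)
        return dens

    def grid(self, n: int = 2048, pad_sigmas: float = 5.0) -> np.ndarray:
        lo = self.values.min() - pad_sigmas * self.bandwidth
        hi = self.values.max() + pad_sigmas * self.bandwidth
        return np.linspace(lo, hi, n)

    @property
    def mode(self) -> float:
        """Argmax of the density over a wide evaluation grid."""
        g = self.grid()
        return float(g[np.argmax(self(g))])


def gaussian_kde(values, bandwidth="scott") -> GaussianKDE:
    """Build a :class:`GaussianKDE` (callable density with ``.mode``)."""
    return GaussianKDE(values, bandwidth)


@dataclass
class QuadraticFit:
    """Least-squares fit y = a·x² + b·x + c."""

    a: float
    b: float
    c: float
    p_value: float  # two-sided t-test on the quadratic coefficient
    vertex: float | None  # x* = -b / (2a); None when a == 0


def quadratic_fit(x, y) -> QuadraticFit:
    """Quadratic least squares with a t-test on the curvature term.

    With an exactly interpolating fit the residual variance is zero and the
    p-value is undefined; it is reported as ``nan``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("quadratic fit needs n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("x values must not all be equal")
    X = np.column_stack([x**2, x, np.ones(n)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design (collinear x², x, 1)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    df = n - 3
    a, b, c = (float(v) for v in beta)
    scale = np.linalg.inv(X.T @ X)[0, 0]
    if df <= 0 or ssr <= 1e-12 * max(float(y @ y), 1.0):
        p = float("nan")
    else:
        se = np.sqrt(ssr / df * scale)
        t = a / se
        p = float(2 * sps.t.sf(abs(t), df))
    vertex = None if a == 0 else -b / (2 * a)
    return QuadraticFit(a, b, c, p, vertex)


@dataclass
class FTestResult:
    """Variance-ratio test between two groups."""

    statistic: float
    p_value: float
    df: tuple[int, int]


def variance_f_test(a, b) -> FTestResult:
    """Two-sided F-test of equal variances: F = s²(a)/s²(b), p = 2·min(tail,
    1−tail) with (n_a−1, n_b−1) degrees of freedom."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    vb = b.var(ddof=1)
    if vb == 0:
        raise ValueError("zero variance in denominator group")
    f = float(a.var(ddof=1) / vb)
    dfn, dfd = a.size - 1, b.size - 1
    cdf = sps.f.cdf(f, dfn, dfd)
    p = float(min(1.0, 2 * min(cdf, 1 - cdf)))
    return FTestResult(f, p, (dfn, dfd))


def quantification_report(
    df, cutoffs: tuple[float, float] = DEFAULT_SIZE_CUTOFFS
) -> dict[str, float | str]:
    """Summary statistics over a per-tumor quantification table.

    Expects columns ``log10_volume``, ``proliferative_index`` and
    ``gliosis_index``. Reports the per-size-class KDE mode of the
    proliferative index, the quadratic regression of proliferative index on
    log10 volume, the variance F-test of large vs small+medium proliferation,
    and the Pearson correlation of proliferative index with the square root
    of the gliosis index per class. Quantities whose group is too small are
    omitted.
    """
    out: dict[str, float | str] = {}
    classes = np.array([size_class(v, cutoffs) for v in df["log10_volume"]])
    out["n_tumors"] = int(len(df))
    prolif = np.asarray(df["proliferative_index"], dtype=float)
    gli = np.asarray(df["gliosis_index"], dtype=float)
    logv = np.asarray(df["log10_volume"], dtype=float)

    for cls in ("small", "medium", "large"):
        sel = classes == cls
        out[f"n_{cls}"] = int(sel.sum())
        vals = prolif[sel]
        if vals.size >= 2 and np.ptp(vals) > 0:
            out[f"kde_mode_proliferation_{cls}"] = gaussian_kde(vals).mode

    if len(df) >= 4 and np.ptp(logv) > 0:
        fit = quadratic_fit(logv, prolif)
        out.update(
            quadratic_a=fit.a,
            quadratic_b=fit.b,
            quadratic_c=fit.c,
            quadratic_p=fit.p_value,
            quadratic_vertex=float("nan") if fit.vertex is None else fit.vertex,
        )

    large = prolif[classes == "large"]
    rest = prolif[classes != "large"]
    if large.size >= 2 and rest.size >= 2 and rest.var(ddof=1) > 0:
        ft = variance_f_test(large, rest)
        out["f_statistic_large_vs_rest"] = ft.statistic
        out["f_p_large_vs_rest"] = ft.p_value

    # The gliosis–proliferation relation is assessed on the square root of
    # the gliosis index (variance-stabilising for small fractions).
    for cls in ("small", "medium", "large"):
        sel = classes == cls
        x, y = np.sqrt(gli[sel]), prolif[sel]
        if x.size >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
            out[f"pearson_sqrt_gliosis_vs_proliferation_{cls}"] = pearson_r(x, y)
    return out


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs n >= 3 with equal lengths")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no defined correlation")
    return float(sps.pearsonr(x, y).statistic)
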