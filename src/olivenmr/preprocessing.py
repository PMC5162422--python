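"""Spectral bucketing and pretreatment.

Turns frequency-domain 1D proton NMR spectra into the matrix that feeds the
multivariate analysis: fixed-width rectangular buckets over 10.00-0.50 ppm
with the residual-chloroform window (7.6-6.9 ppm) excluded, total-sum
normalization of each sample row, mean-centering with Pareto scaling of each
bucket column, and a Hotelling T-squared outlier screen in PCA score space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Spectrum",
    "BucketScheme",
    "BucketTable",
    "OutlierReport",
    "make_bucket_grid",
    "integrate_buckets",
    "build_bucket_table",
    "normalize_total_sum",
    "pareto_scale",
    "detect_outliers",
    "DEFAULT_SCHEME",
]

_EPS = 1e-9


@dataclass(frozen=True)
class Spectrum:
    """One frequency-domain 1D spectrum on a descending ppm grid."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", inten)
        if ppm.ndim != 1 or inten.ndim != 1 or ppm.size != inten.size:
            raise ValueError("Spectrum: ppm and intensity must be 1-D of equal length")
        if ppm.size >= 2 and not np.all(np.diff(ppm) < 0):
            raise ValueError("Spectrum: ppm axis must be strictly decreasing")
        if not np.all(np.isfinite(inten)):
            raise ValueError("Spectrum: intensities must be finite")


@dataclass(frozen=True)
class BucketScheme:
    """Rectangular bucketing scheme on the chemical-shift axis.

    The grid is anchored at ``region_high`` and steps down by ``width``; a
    trailing bucket truncated at ``region_low`` is kept; buckets fully
    contained in an exclusion interval are dropped.
    """

    region_high: float = 10.00
    region_low: float = 0.50
    width: float = 0.04
    exclusions: tuple[tuple[float, float], ...] = ((7.6, 6.9),)

    def __post_init__(self) -> None:
        if self.region_high <= self.region_low:
            raise ValueError("BucketScheme: region_high must exceed region_low")
        if self.width <= 0:
            raise ValueError("BucketScheme: width must be positive")
        for hi, lo in self.exclusions:
            if hi <= lo:
                raise ValueError("BucketScheme: exclusion (high, low) must have high > low")
            if hi > self.region_high + _EPS or lo < self.region_low - _EPS:
                raise ValueError("BucketScheme: exclusion must lie inside the bucketed region")


DEFAULT_SCHEME = BucketScheme()


@dataclass
class BucketTable:
    """Samples x buckets intensity matrix plus per-sample metadata.

    ``centers`` are the bucket central chemical shifts in descending order;
    bucket labels are their 2-decimal text renderings. ``state`` tracks the
    pretreatment stage (raw -> normalized -> scaled).
    """

    values: np.ndarray
    centers: np.ndarray
    metadata: pd.DataFrame
    state: str = "raw"
    normalization_target: float | None = None
    scaling_params: dict[str, np.ndarray] | None = None
    scheme: BucketScheme | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("BucketTable: values must be 2-D")
        if self.centers.size != self.values.shape[1]:
            raise ValueError("BucketTable: label count must equal column count")
        if self.centers.size >= 2 and not np.all(np.diff(self.centers) < 0):
            raise ValueError("BucketTable: bucket labels must be strictly decreasing")
        if len(self.metadata) != self.values.shape[0]:
            raise ValueError("BucketTable: metadata rows must match sample rows")

    @property
    def labels(self) -> list[str]:
        return [f"{c:.2f}" for c in self.centers]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_buckets(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        meta = self.metadata.reset_index(drop=True)
        buckets = pd.DataFrame(self.values, columns=self.labels)
        return pd.concat([meta, buckets], axis=1)

    def subset(self, mask: np.ndarray) -> "BucketTable":
        mask = np.asarray(mask)
        return replace(
            self,
            values=self.values[mask],
            metadata=self.metadata.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask].reset_index(drop=True),
        )


@dataclass(frozen=True)
class OutlierReport:
    """Result of a single-pass Hotelling T-squared screen on PCA scores."""

    flagged_ids: list[str]
    statistic: np.ndarray
    threshold: float
    n_components_used: int
    alpha: float


def make_bucket_grid(scheme: BucketScheme) -> list[tuple[float, float, float]]:
    """Return the bucket grid as (high, low, center) triples.

    Anchored at ``region_high``, stepping down by ``width``; the trailing
    partial bucket is truncated at ``region_low`` and kept; buckets fully
    contained in an exclusion interval are dropped. Centers are midpoints of
    the (possibly truncated) bucket.
    """
    span = scheme.region_high - scheme.region_low
    if scheme.width >= span:
        raise ValueError("make_bucket_grid: width must be smaller than the region span")
    n = int(np.ceil(span / scheme.width - _EPS))
    grid: list[tuple[float, float, float]] = []
    for i in range(n):
        hi = scheme.region_high - i * scheme.width
        lo = max(scheme.region_high - (i + 1) * scheme.width, scheme.region_low)
        contained = any(
            hi <= ex_hi + _EPS and lo >= ex_lo - _EPS for ex_hi, ex_lo in scheme.exclusions
        )
        if contained:
            continue
        grid.append((hi, lo, 0.5 * (hi + lo)))
    return grid


def integrate_buckets(spectrum: Spectrum, scheme: BucketScheme) -> np.ndarray:
    """Integrate a spectrum over each bucket by the trapezoidal rule.

    Bucket edges falling between grid points are handled by linear
    interpolation of the intensity, so a constant spectrum integrates to
    exactly ``constant * width`` per full bucket.
    """
    if spectrum.ppm.size < 2:
        raise ValueError("integrate_buckets: spectrum needs at least 2 points")
    hi_cov, lo_cov = spectrum.ppm[0], spectrum.ppm[-1]
    if hi_cov < scheme.region_high - _EPS or lo_cov > scheme.region_low + _EPS:
        raise ValueError(
            "integrate_buckets: spectrum covers "
            f"[{lo_cov:.4f}, {hi_cov:.4f}] ppm but the scheme requires "
            f"[{scheme.region_low:.4f}, {scheme.region_high:.4f}] ppm"
        )
    # ascending axis for interpolation / integration
    x = spectrum.ppm[::-1]
    y = spectrum.intensity[::-1]
    grid = make_bucket_grid(scheme)
    out = np.empty(len(grid))
    for k, (hi, lo, _) in enumerate(grid):
        i0 = np.searchsorted(x, lo, side="right")
        i1 = np.searchsorted(x, hi, side="left")
        xs = np.concatenate(([lo], x[i0:i1], [hi]))
        ys = np.concatenate(
            ([np.interp(lo, x, y)], y[i0:i1], [np.interp(hi, x, y)])
        )
        out[k] = np.trapezoid(ys, xs)
    return out


def build_bucket_table(
    spectra: Sequence[Spectrum],
    metadata: pd.DataFrame,
    scheme: BucketScheme = DEFAULT_SCHEME,
) -> BucketTable:
    """Bucket a collection of spectra into a raw BucketTable."""
    if len(spectra) != len(metadata):
        raise ValueError("build_bucket_table: one metadata row per spectrum required")
    values = np.vstack([integrate_buckets(s, scheme) for s in spectra])
    centers = np.array([c for _, _, c in make_bucket_grid(scheme)])
    return BucketTable(
        values=values,
        centers=centers,
        metadata=metadata.reset_index(drop=True),
        state="raw",
        scheme=scheme,
    )


def normalize_total_sum(table: BucketTable, target: float = 100.0) -> BucketTable:
    """Scale each sample row to a fixed total (total-sum normalization)."""
    sums = table.values.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        sid = table.metadata.iloc[bad[0]].get("sample_id", str(bad[0]))
        raise ValueError(f"normalize_total_sum: nonpositive row sum for sample {sid!r}")
    values = table.values * (target / sums)[:, None]
    return replace(table, values=values, state="normalized", normalization_target=target)


def pareto_scale(table: BucketTable) -> BucketTable:
    """Mean-center each bucket and divide by the square root of its SD.

    Standard deviation uses denominator n-1. Zero-variance buckets map to
    all-zero columns with a warning. The per-bucket means and SDs are stored
    in ``scaling_params`` so folds or new samples can reuse them.
    """
    if table.state == "scaled":
        raise ValueError("pareto_scale: table is already scaled")
    if table.n_samples < 2:
        raise ValueError("pareto_scale: at least 2 samples required")
    means = table.values.mean(axis=0)
    sds = table.values.std(axis=0, ddof=1)
    zero = sds <= 0
    if zero.any():
        warnings.warn(
            f"pareto_scale: {int(zero.sum())} zero-variance bucket(s) set to zero",
            stacklevel=2,
        )
    divisor = np.where(zero, 1.0, np.sqrt(sds))
    values = (table.values - means) / divisor
    values[:, zero] = 0.0
    return replace(
        table,
        values=values,
        state="scaled",
        scaling_params={"mean": means, "sd": sds},
    )


def apply_pareto(values: np.ndarray, params: dict[str, np.ndarray]) -> np.ndarray:
    """Apply previously estimated Pareto parameters to new rows."""
    sds = params["sd"]
    zero = sds <= 0
    divisor = np.where(zero, 1.0, np.sqrt(sds))
    out = (np.asarray(values, dtype=float) - params["mean"]) / divisor
    out[:, zero] = 0.0
    return out


def hotelling_t2_limit(n: int, k: int, alpha: float) -> float:
    """Upper control limit of Hotelling T2 for k PCA scores from n samples."""
    f_crit = stats.f.ppf(1.0 - alpha, k, n - k)
    return k * (n * n - 1) / (n * (n - k)) * f_crit


def detect_outliers(
    table: BucketTable, alpha: float = 0.05, n_components: int = 2
) -> OutlierReport:
    """Single-pass Hotelling T2 outlier screen on the first PCA scores.

    The statistic for each sample is the sum of its squared scores divided by
    the per-component score variance; samples above the F-distribution-based
    (1 - alpha) limit are flagged. No iterative refitting is performed.
    """
    n = table.n_samples
    if n_components >= n:
        raise ValueError("detect_outliers: n_components must be below the sample count")
    X = table.values - table.values.mean(axis=0)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        raise ValueError("detect_outliers: n_components exceeds the matrix rank")
    scores = X @ vt[:n_components].T
    var = scores.var(axis=0, ddof=1)
    t2 = np.sum(scores**2 / var, axis=1)
    limit = hotelling_t2_limit(n, n_components, alpha)
    flagged = np.flatnonzero(t2 > limit)
    ids = (
        [str(table.metadata.iloc[i]["sample_id"]) for i in flagged]
        if "sample_id" in table.metadata.columns
        else [str(i) for i in flagged]
    )
    return OutlierReport(
        flagged_ids=ids,
        statistic=t2,
        threshold=float(limit),
        n_components_used=n_components,
        alpha=alpha,
    )
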