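"""Plant-level paired distance analysis.

Each tree yields one oil per harvest; pairwise Mahalanobis distances between
the two harvest-year cohorts (in retained PCA score space) are split into a
plant-plant set (each tree's year-1 oil against its own year-2 oil) and a
plant-cultivar set (each year-1 oil against every year-2 oil of the same
cultivar). The first distribution traces what a single tree experienced
between the years; the second represents the cultivar's overall
between-harvest variability. Distribution summaries and Gaussian kernel
density curves are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

__all__ = [
    "PairedDesign",
    "DistanceSets",
    "DistributionSummary",
    "KernelDensityCurve",
    "build_pairing",
    "pairwise_mahalanobis",
    "split_sets",
    "paired_distance_sets",
    "summarize",
    "kernel_density",
    "silverman_bandwidth",
]


@dataclass
class PairedDesign:
    """Plants matched across the two harvests, plus the excluded leftovers."""

    pairs: list[tuple[str, str, str]]  # (plant_id, sample_id_year1, sample_id_year2)
    unmatched: list[str]


def build_pairing(metadata: pd.DataFrame) -> PairedDesign:
    """Match each plant's two harvest records; list the rest as unmatched.

    Samples with no counterpart in the other harvest are excluded from the
    paired analysis but reported. A plant appearing twice within one harvest
    is an error.
    """
    required = {"sample_id", "plant_id", "harvest"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"build_pairing: metadata lacks column(s) {sorted(missing)}")
    harvests = sorted(metadata["harvest"].astype(str).unique())
    if len(harvests) != 2:
        raise ValueError(f"build_pairing: exactly 2 harvests required, got {harvests}")
    by_harvest: dict[str, dict[str, str]] = {}
    for h in harvests:
        sub = metadata[metadata["harvest"].astype(str) == h]
        dup = sub["plant_id"][sub["plant_id"].duplicated()]
        if not dup.empty:
            raise ValueError(
                f"build_pairing: plant {dup.iloc[0]!r} has two samples in harvest {h}"
            )
        by_harvest[h] = dict(zip(sub["plant_id"].astype(str), sub["sample_id"].astype(str)))
    h1, h2 = harvests
    common = sorted(set(by_harvest[h1]) & set(by_harvest[h2]))
    pairs = [(p, by_harvest[h1][p], by_harvest[h2][p]) for p in common]
    unmatched = sorted(
        [sid for h in harvests for p, sid in by_harvest[h].items() if p not in common]
    )
    if not pairs:
        warnings.warn("build_pairing: no plant present in both harvests", stacklevel=2)
    return PairedDesign(pairs=pairs, unmatched=unmatched)


def pairwise_mahalanobis(
    scores_year1: np.ndarray,
    scores_year2: np.ndarray,
    covariance: np.ndarray,
) -> np.ndarray:
    """All-pairs Mahalanobis distances between two score sets.

    Entry (i, j) = sqrt((x_i - y_j)^T C^-1 (x_i - y_j)). Computed by
    whitening both sets with the Cholesky factor of C; a small ridge is
    attempted once if C is singular.
    """
    X = np.atleast_2d(np.asarray(scores_year1, dtype=float))
    Y = np.atleast_2d(np.asarray(scores_year2, dtype=float))
    C = np.asarray(covariance, dtype=float)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * float(np.mean(np.diag(C)))
        try:
            L = np.linalg.cholesky(C + ridge * np.eye(C.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "pairwise_mahalanobis: covariance singular even after ridging"
            ) from exc
    U = solve_triangular(L, X.T, lower=True).T
    V = solve_triangular(L, Y.T, lower=True).T
    d2 = (
        np.sum(U**2, axis=1)[:, None]
        + np.sum(V**2, axis=1)[None, :]
        - 2.0 * U @ V.T
    )
    return np.sqrt(np.clip(d2, 0.0, None))


@dataclass
class DistanceSets:
    """Plant-plant and plant-cultivar Mahalanobis distance collections."""

    plant_plant: np.ndarray
    plant_cultivar: np.ndarray
    cultivar: str
    k_used: int
    covariance_meta: str


def split_sets(
    matrix: np.ndarray,
    pairing: PairedDesign,
    cultivar: str,
    *,
    k_used: int = 0,
    covariance_meta: str = "",
    exclude_own_pair: bool = False,
) -> DistanceSets:
    """Split an all-pairs distance matrix into the two study sets.

    ``matrix`` rows are the cultivar's year-1 samples and columns its year-2
    samples, both in ``pairing.pairs`` order. plant_plant is the diagonal
    (each tree against itself next year); plant_cultivar is every entry —
    including, by default, the tree's own matched pair.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(pairing.pairs)
    if n == 0:
        raise ValueError(f"split_sets: no matched pairs for cultivar {cultivar!r}")
    if matrix.shape != (n, n):
        raise ValueError(
            f"split_sets: matrix shape {matrix.shape} does not match the "
            f"{n} matched pairs"
        )
    plant_plant = np.diag(matrix).copy()
    if exclude_own_pair:
        mask = ~np.eye(n, dtype=bool)
        plant_cultivar = matrix[mask]
    else:
        plant_cultivar = matrix.ravel().copy()
    return DistanceSets(
        plant_plant=plant_plant,
        plant_cultivar=plant_cultivar,
        cultivar=cultivar,
        k_used=k_used,
        covariance_meta=covariance_meta,
    )


def paired_distance_sets(
    scores: np.ndarray,
    metadata: pd.DataFrame,
    cultivar: str,
    *,
    exclude_own_pair: bool = False,
) -> DistanceSets:
    """End-to-end paired analysis for one cultivar in a given score space.

    The covariance used for whitening is the pooled covariance of the
    cultivar's combined two-year samples in the retained component space
    (recorded in ``covariance_meta``).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    meta = metadata.reset_index(drop=True)
    mask = meta["cultivar"].astype(str) == str(cultivar)
    if not mask.any():
        raise ValueError(f"paired_distance_sets: cultivar {cultivar!r} not present")
    sub_meta = meta[mask].reset_index(drop=True)
    sub_scores = scores[np.asarray(mask)]
    pairing = build_pairing(sub_meta)
    index = {sid: i for i, sid in enumerate(sub_meta["sample_id"].astype(str))}
    idx1 = [index[s1] for _, s1, _ in pairing.pairs]
    idx2 = [index[s2] for _, _, s2 in pairing.pairs]
    paired_rows = sub_scores[idx1 + idx2]
    cov = np.cov(paired_rows, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    matrix = pairwise_mahalanobis(sub_scores[idx1], sub_scores[idx2], cov)
    return split_sets(
        matrix,
        pairing,
        cultivar,
        k_used=scores.shape[1],
        covariance_meta=(
            f"pooled covariance of the {len(idx1) * 2} matched two-year samples "
            f"of {cultivar} in {scores.shape[1]} retained components"
        ),
        exclude_own_pair=exclude_own_pair,
    )


@dataclass
class DistributionSummary:
    """Five-number-style summary of a distance set (SD with n-1; missing for
    singleton sets)."""

    minimum: float
    median: float
    mean: float
    standard_deviation: float | None
    maximum: float
    n: int


def summarize(values: np.ndarray) -> DistributionSummary:
    """Summary statistics of a nonempty distance vector."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("summarize: empty distance set")
    return DistributionSummary(
        minimum=float(values.min()),
        median=float(np.median(values)),
        mean=float(values.mean()),
        standard_deviation=float(values.std(ddof=1)) if values.size > 1 else None,
        maximum=float(values.max()),
        n=int(values.size),
    )


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * values.size ** (-1 / 5)


@dataclass
class KernelDensityCurve:
    """Gaussian-kernel density estimate on a fixed grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


def kernel_density(
    values: np.ndarray, bandwidth: float | None = None, n_grid: int = 512
) -> KernelDensityCurve:
    """Gaussian KDE on a 512-point grid spanning [min - 3h, max + 3h].

    Default bandwidth by Silverman's rule; a zero-variance set requires an
    explicit bandwidth.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("kernel_density: at least 2 values required")
    h = bandwidth if bandwidth is not None else silverman_bandwidth(values)
    if not h > 0:
        raise ValueError(
            "kernel_density: zero-variance set; pass an explicit bandwidth"
        )
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, n_grid)
    z = (grid[:, None] - values[None, :]) / h
    density = np.exp(-0.5 * z**2).sum(axis=1) / (values.size * h * np.sqrt(2 * np.pi))
    return KernelDensityCurve(grid=grid, density=density, bandwidth=float(h))
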