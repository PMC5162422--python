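"""Cluster separation and compactness in PCA score space.

Within/between-class scatter matrices, the J2 determinant-ratio criterion
J2 = |S_w + S_b| / |S_w|, and group-to-group Mahalanobis distances under
either a fixed number of retained components or a cumulative-variance rule.
High J2 means tight, well-separated clusters; J2 = 1 when all class means
coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chemometrics import PCAModel, select_ncomp_by_cumvar

__all__ = [
    "ScatterDecomposition",
    "QualityReport",
    "scatter_matrices",
    "j2_criterion",
    "group_mahalanobis",
    "quality_report",
    "year_contrast",
]

_COND_LIMIT = 1e12


@dataclass
class ScatterDecomposition:
    """Unnormalized within-class (S_w) and between-class (S_b) scatter."""

    S_w: np.ndarray
    S_b: np.ndarray
    class_means: dict[str, np.ndarray]
    grand_mean: np.ndarray
    class_sizes: dict[str, int]


def scatter_matrices(scores: np.ndarray, labels: Sequence[str]) -> ScatterDecomposition:
    """Within- and between-class scatter of score vectors.

    S_w = sum over classes of sum over members of (x - m_c)(x - m_c)^T;
    S_b = sum over classes of n_c (m_c - m)(m_c - m)^T. Both are raw sums
    (not divided by counts): J2 is invariant to any common normalization.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray([str(x) for x in labels])
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("scatter_matrices: at least 2 classes required")
    k = X.shape[1]
    grand = X.mean(axis=0)
    S_w = np.zeros((k, k))
    S_b = np.zeros((k, k))
    means: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    for c in classes:
        Xi = X[labels == c]
        if Xi.shape[0] < 2:
            raise ValueError(f"scatter_matrices: singleton class {c!r}")
        m = Xi.mean(axis=0)
        dev = Xi - m
        S_w += dev.T @ dev
        d = m - grand
        S_b += Xi.shape[0] * np.outer(d, d)
        means[c], sizes[c] = m, Xi.shape[0]
    return ScatterDecomposition(
        S_w=S_w, S_b=S_b, class_means=means, grand_mean=grand, class_sizes=sizes
    )


def j2_criterion(decomp: ScatterDecomposition, ridge: float | None = None) -> float:
    """J2 = |S_w + S_b| / |S_w|, computed via log-determinants."""
    S_w = decomp.S_w
    if ridge is not None:
        S_w = S_w + ridge * np.eye(S_w.shape[0])
    cond = np.linalg.cond(S_w)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise ValueError(
            "j2_criterion: within-class scatter is (near-)singular; "
            "retain fewer PCs or pass a ridge"
        )
    sign_t, logdet_t = np.linalg.slogdet(S_w + decomp.S_b)
    sign_w, logdet_w = np.linalg.slogdet(S_w)
    if sign_t <= 0 or sign_w <= 0:
        raise ValueError("j2_criterion: scatter determinants must be positive")
    return float(np.exp(logdet_t - logdet_w))


def group_mahalanobis(
    scores: np.ndarray,
    labels: Sequence[str],
    class_a: str,
    class_b: str,
    pooling: str = "pooled_within",
    covariance: np.ndarray | None = None,
) -> float:
    """Mahalanobis distance between two class means in score space.

    d = sqrt((m_a - m_b)^T C^-1 (m_a - m_b)) with C the pooled within-class
    covariance of the two classes (divisor n_a + n_b - 2), unless an explicit
    ``covariance`` is supplied. Scale-invariant by construction. A ridge of
    1e-8 x mean diagonal is applied once if C is singular.
    """
    if pooling != "pooled_within":
        raise ValueError(f"group_mahalanobis: unknown pooling {pooling!r}")
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray([str(x) for x in labels])
    Xa, Xb = X[labels == str(class_a)], X[labels == str(class_b)]
    if Xa.shape[0] < 2 or Xb.shape[0] < 2:
        raise ValueError("group_mahalanobis: both classes need at least 2 members")
    ma, mb = Xa.mean(axis=0), Xb.mean(axis=0)
    if covariance is None:
        da, db = Xa - ma, Xb - mb
        covariance = (da.T @ da + db.T @ db) / (Xa.shape[0] + Xb.shape[0] - 2)
    diff = ma - mb
    return float(np.sqrt(diff @ _robust_solve(covariance, diff)))


def _robust_solve(C: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Solve C x = v; retry once with a small ridge, then raise."""
    C = np.asarray(C, dtype=float)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * float(np.mean(np.diag(C)))
        try:
            L = np.linalg.cholesky(C + ridge * np.eye(C.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance matrix is singular even after ridging") from exc
    z = np.linalg.solve(L, v)
    return np.linalg.solve(L.T, z)


@dataclass
class QualityReport:
    """J2 and group Mahalanobis distances per component-selection rule."""

    rows: list[dict]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def quality_report(
    pca: PCAModel,
    labels: Sequence[str],
    configurations: Sequence[dict],
) -> QualityReport:
    """Evaluate cluster quality under several component-selection rules.

    Each configuration is {"rule": "fixed_k" | "cumvar", "value": v}. Scores
    are truncated to the selected k; the report contains the partition-level
    J2, the per-pair J2 (computed on each two-class subset) and the per-pair
    group Mahalanobis distance, each tagged with the variance actually
    covered by the retained components.
    """
    labels = np.asarray([str(x) for x in labels])
    classes = sorted(set(labels))
    rows: list[dict] = []
    for config in configurations:
        rule, value = config["rule"], config["value"]
        if rule == "fixed_k":
            k = int(value)
            if k > pca.n_components:
                raise ValueError(
                    f"quality_report: k={k} exceeds the {pca.n_components} "
                    "available components"
                )
        elif rule == "cumvar":
            k = select_ncomp_by_cumvar(pca, float(value))
        else:
            raise ValueError(f"quality_report: unknown rule {rule!r}")
        S = pca.scores[:, :k]
        covered = float(pca.cumulative_R2X[k - 1])
        decomp = scatter_matrices(S, labels)
        rows.append(
            {
                "rule": rule,
                "value": value,
                "k": k,
                "covered_variance": covered,
                "pair": "ALL",
                "j2": j2_criterion(decomp),
                "mahalanobis": np.nan,
            }
        )
        for i, a in enumerate(classes):
            for b in classes[i + 1 :]:
                mask = (labels == a) | (labels == b)
                sub = scatter_matrices(S[mask], labels[mask])
                rows.append(
                    {
                        "rule": rule,
                        "value": value,
                        "k": k,
                        "covered_variance": covered,
                        "pair": f"{a}|{b}",
                        "j2": j2_criterion(sub),
                        "mahalanobis": group_mahalanobis(S, labels, a, b),
                    }
                )
    return QualityReport(rows=rows)


def year_contrast(
    scores: np.ndarray,
    class_labels: Sequence[str],
    year_labels: Sequence[str],
) -> pd.DataFrame:
    """Between-harvest separation of each class in a shared score space.

    For every class, its samples are split by harvest year and the two-group
    Mahalanobis distance and J2 are computed on that subset. Low values mean
    the class kept a stable profile across the two harvests.
    """
    class_labels = np.asarray([str(x) for x in class_labels])
    year_labels = np.asarray([str(x) for x in year_labels])
    years = sorted(set(year_labels))
    if len(years) != 2:
        raise ValueError("year_contrast: exactly two harvest years required")
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    rows = []
    for c in sorted(set(class_labels)):
        mask = class_labels == c
        decomp = scatter_matrices(X[mask], year_labels[mask])
        rows.append(
            {
                "class": c,
                "n": int(mask.sum()),
                "mahalanobis": group_mahalanobis(
                    X[mask], year_labels[mask], years[0], years[1]
                ),
                "j2": j2_criterion(decomp),
            }
        )
    return pd.DataFrame(rows)
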