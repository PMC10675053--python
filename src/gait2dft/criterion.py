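"""Discrimination-criterion scoring of DF-score clouds.

Separation of the three condition clusters in the discriminant plane is
summarised by a single dimensionless ratio::

    criterion = (Dist_1 × Dist_2 × Dist_3) / (Scatter_1 × Scatter_2 × Scatter_3)

where the Dist terms are the pairwise Euclidean distances between the
three cluster centroids (fast–normal, fast–slow, normal–slow) and each
Scatter is the standard deviation of the cluster's point-to-centroid
distances.  Large centroid spacing combined with tight clusters drives
the ratio up; a criterion above 500 corresponds to visually
non-overlapping clusters and counts as a successful discrimination.

The ratio is invariant under rotation, translation and uniform scaling
of the DF plane: numerator and denominator each scale with the cube of
a similarity factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DataError, DegenerateClusterError

#: Success threshold: clusters with a criterion above this do not overlap.
DEFAULT_THRESHOLD = 500.0

#: Canonical condition ordering used for the named distance fields.
_CANONICAL = ("fast", "normal", "slow")

SCATTER_CONVENTIONS = ("sd-of-distances", "radial-rms")


@dataclass(frozen=True)
class ClusterSummary:
    """Centroid and radial scatter of one condition's DF scores."""

    label: str
    centroid: np.ndarray
    scatter: float
    n: int


@dataclass(frozen=True)
class CriterionResult:
    """Pairwise centroid distances, per-cluster scatters, and the verdict.

    ``distances`` maps unordered label pairs to centroid distances and
    ``scatters`` maps labels to radial scatters.  For the standard
    fast/normal/slow session the named properties expose the three
    distances in their conventional order.
    """

    distances: dict[frozenset, float]
    scatters: dict[str, float]
    criterion: float
    success: bool
    threshold: float = DEFAULT_THRESHOLD

    def _dist(self, a: str, b: str) -> float:
        return self.distances[frozenset((a, b))]

    @property
    def dist_fast_normal(self) -> float:
        return self._dist("fast", "normal")

    @property
    def dist_fast_slow(self) -> float:
        return self._dist("fast", "slow")

    @property
    def dist_normal_slow(self) -> float:
        return self._dist("normal", "slow")

    def as_record(self) -> dict:
        """Flat dict for report CSVs."""
        rec = {}
        for pair, d in sorted(self.distances.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(pair)
            rec[f"dist_{a}_{b}"] = d
        for label, s in sorted(self.scatters.items()):
            rec[f"scatter_{label}"] = s
        rec["criterion"] = self.criterion
        rec["threshold"] = self.threshold
        rec["success"] = self.success
        return rec


def summarize_cluster(
    points: np.ndarray,
    label: str,
    convention: str = "sd-of-distances",
    ddof: int = 0,
) -> ClusterSummary:
    """Centroid and radial scatter of one cluster.

    ``convention`` selects the scatter definition: ``"sd-of-distances"``
    (standard deviation of the point-to-centroid distance set, the
    default) or ``"radial-rms"`` (root-mean-square radial deviation).
    ``ddof=0`` gives the population standard deviation.
    """
    if convention not in SCATTER_CONVENTIONS:
        raise DataError(f"unknown scatter convention {convention!r}")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 2:
        raise DataError(f"cluster {label!r} needs at least 2 points for a defined scatter")
    centroid = points.mean(axis=0)
    dists = np.linalg.norm(points - centroid, axis=1)
    if convention == "radial-rms":
        scatter = float(np.sqrt(np.mean(dists**2)))
    else:
        scatter = float(dists.std(ddof=ddof))
    return ClusterSummary(label=label, centroid=centroid, scatter=scatter, n=points.shape[0])


def classify_success(criterion: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Strict comparison: success means criterion strictly greater than the threshold."""
    if not math.isfinite(criterion) or criterion < 0:
        raise ValueError(f"criterion must be a finite nonnegative number, got {criterion}")
    return criterion > threshold


def criterion_score(
    cloud,
    threshold: float = DEFAULT_THRESHOLD,
    convention: str = "sd-of-distances",
    ddof: int = 0,
    expected_labels: tuple[str, ...] | None = None,
) -> CriterionResult:
    """Score a three-cluster DF cloud with the discrimination criterion.

    ``cloud`` is any object with ``points`` (n × 2) and ``labels``
    attributes.  Exactly three labels must be present, each with at
    least two points; a zero scatter raises
    :class:`DegenerateClusterError` rather than silently returning an
    infinite (always-passing) criterion.
    """
    points = np.asarray(cloud.points, dtype=float)
    labels = np.asarray(cloud.labels, dtype=object)
    present = sorted(set(labels.tolist()))
    if expected_labels is not None:
        missing = [c for c in expected_labels if c not in present]
        if missing:
            raise DataError(f"missing condition(s) {missing} in the DF cloud")
    if len(present) != 3:
        raise DataError(f"criterion needs exactly 3 conditions, found {len(present)}: {present}")

    summaries = {
        c: summarize_cluster(points[labels == c], c, convention=convention, ddof=ddof)
        for c in present
    }
    for c, s in summaries.items():
        if s.scatter == 0.0:
            raise DegenerateClusterError(
                f"cluster {c!r} has zero scatter; the criterion ratio is undefined"
            )

    if set(present) == set(_CANONICAL):
        ordered_pairs = [("fast", "normal"), ("fast", "slow"), ("normal", "slow")]
    else:
        ordered_pairs = [
            (present[i], present[j]) for i in range(3) for j in range(i + 1, 3)
        ]
    distances = {
        frozenset(p): float(np.linalg.norm(summaries[p[0]].centroid - summaries[p[1]].centroid))
        for p in ordered_pairs
    }
    num = float(np.prod([distances[frozenset(p)] for p in ordered_pairs]))
    den = float(np.prod([summaries[c].scatter for c in present]))
    crit = num / den
    return CriterionResult(
        distances=distances,
        scatters={c: summaries[c].scatter for c in present},
        criterion=crit,
        success=classify_success(crit, threshold),
        threshold=threshold,
    )
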