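"""Dimensionality reduction and discriminant projection of 2DFT features.

The high-density training database (300 rows × ~160 features in a
default session) is first reduced by principal component analysis,
keeping the smallest leading set of components that explains at least
80% of the pooled total variance.  Which and how many components
survive therefore varies from session to session — the retention rule
is a variance fraction, not a fixed count.

Fisher discriminant function analysis (DFA) then projects the retained
PC scores onto exactly two discriminant axes, the directions maximising
between-class scatter relative to within-class scatter for the three
walking conditions.  Solving the discriminant inside the retained-PC
subspace keeps the within-class scatter well conditioned even though
the raw feature dimension exceeds the row count; a small ridge
(1e-8 × mean diagonal) guards the remaining degenerate cases.

Both projections follow a fixed sign convention (largest-magnitude
loading positive) so repeated runs are byte-comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import scipy.linalg
from sklearn.decomposition import PCA

from .errors import DataError, DegenerateDataError, ShapeError
from .features import FeatureMatrix

_RIDGE = 1e-8


def _orient(vectors: np.ndarray) -> np.ndarray:
    """Flip each row so its largest-magnitude entry is positive."""
    out = vectors.copy()
    for i, v in enumerate(out):
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            out[i] = -v
    return out


@dataclass(frozen=True)
class VarianceBasis:
    """Retained principal components of the pooled training database."""

    mean_vector: np.ndarray
    components: np.ndarray  # (retained_count, n_features), orthonormal rows
    explained_fractions: np.ndarray  # all components, non-increasing
    retained_count: int
    variance_target: float

    @property
    def retained_fraction(self) -> float:
        return float(self.explained_fractions[: self.retained_count].sum())

    def to_hdf5(self, group) -> None:
        group.create_dataset("mean_vector", data=self.mean_vector)
        group.create_dataset("components", data=self.components)
        group.create_dataset("explained_fractions", data=self.explained_fractions)
        group.attrs["retained_count"] = self.retained_count
        group.attrs["variance_target"] = self.variance_target

    @classmethod
    def from_hdf5(cls, group) -> "VarianceBasis":
        return cls(
            mean_vector=group["mean_vector"][...],
            components=group["components"][...],
            explained_fractions=group["explained_fractions"][...],
            retained_count=int(group.attrs["retained_count"]),
            variance_target=float(group.attrs["variance_target"]),
        )


@dataclass(frozen=True)
class DiscriminantModel:
    """Two-axis Fisher discriminant projection over retained-PC space."""

    class_labels: tuple[str, ...]
    projection: np.ndarray  # (2, retained_count)
    class_centroids_pc: np.ndarray  # (n_classes, retained_count)
    eigenvalues: np.ndarray  # discriminability per retained axis

    def to_hdf5(self, group) -> None:
        group.create_dataset("projection", data=self.projection)
        group.create_dataset("class_centroids_pc", data=self.class_centroids_pc)
        group.create_dataset("eigenvalues", data=self.eigenvalues)
        group.attrs["class_labels"] = [str(s) for s in self.class_labels]

    @classmethod
    def from_hdf5(cls, group) -> "DiscriminantModel":
        labels = tuple(
            s.decode() if isinstance(s, bytes) else str(s)
            for s in group.attrs["class_labels"]
        )
        return cls(
            class_labels=labels,
            projection=group["projection"][...],
            class_centroids_pc=group["class_centroids_pc"][...],
            eigenvalues=group["eigenvalues"][...],
        )


@dataclass(frozen=True)
class DfScoreCloud:
    """2-D discriminant scores, one point per training row."""

    points: np.ndarray  # (n, 2)
    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ShapeError("DF scores must be n × 2")
        if self.labels.size != self.points.shape[0]:
            raise ShapeError("one label per DF point required")

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"df1": self.points[:, 0], "df2": self.points[:, 1], "condition": self.labels}
        ).to_csv(path, index=False)


def _as_rows(features: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.rows
    return np.asarray(features, dtype=float)


def fit_variance_basis(
    features: FeatureMatrix | np.ndarray, variance_target: float = 0.80
) -> VarianceBasis:
    """Fit PCA on the pooled rows and keep the minimal 80%-variance set.

    ``retained_count`` is the smallest k with cumulative explained
    variance fraction >= ``variance_target``.
    """
    X = _as_rows(features)
    if not (0.0 < variance_target <= 1.0):
        raise DataError("variance_target must lie in (0, 1]")
    if X.shape[0] < 2:
        raise DataError("PCA needs at least 2 rows")
    if np.allclose(X.var(axis=0), 0.0):
        raise DegenerateDataError("training database has zero total variance")

    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(X)
    frac = pca.explained_variance_ratio_
    cum = np.cumsum(frac)
    reached = np.nonzero(cum >= variance_target - 1e-12)[0]
    retained = int(reached[0]) + 1 if reached.size else frac.size
    return VarianceBasis(
        mean_vector=pca.mean_,
        components=_orient(pca.components_[:retained]),
        explained_fractions=frac,
        retained_count=retained,
        variance_target=variance_target,
    )


def project_scores(features: FeatureMatrix | np.ndarray, basis: VarianceBasis) -> np.ndarray:
    """Center rows by the basis mean and project on the retained components."""
    X = _as_rows(features)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != basis.mean_vector.size:
        raise ShapeError(
            f"feature length {X.shape[1]} does not match basis ({basis.mean_vector.size})"
        )
    return (X - basis.mean_vector) @ basis.components.T


def fit_discriminant(
    scores: np.ndarray, labels: np.ndarray | list, n_classes: int = 3
) -> DiscriminantModel:
    """Fisher LDA on PC scores: solve Sb v = λ Sw v, keep the top 2 axes.

    Requires exactly ``n_classes`` classes with at least 2 rows each.
    Three classes span a between-class scatter of rank ≤ 2, so two axes
    capture all linear discriminability.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels.tolist()))
    if len(classes) != n_classes:
        raise DataError(f"expected {n_classes} classes, found {len(classes)}: {classes}")
    d = scores.shape[1]
    grand_mean = scores.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    centroids = []
    for c in classes:
        Xc = scores[labels == c]
        if Xc.shape[0] < 2:
            raise DataError(f"class {c!r} has {Xc.shape[0]} row(s); need at least 2")
        mc = Xc.mean(axis=0)
        centroids.append(mc)
        Xc0 = Xc - mc
        Sw += Xc0.T @ Xc0
        dm = (mc - grand_mean)[:, None]
        Sb += Xc.shape[0] * (dm @ dm.T)

    ridge = _RIDGE * np.trace(Sw) / d if np.trace(Sw) > 0 else _RIDGE
    try:
        eigvals, eigvecs = scipy.linalg.eigh(Sb, Sw)
    except scipy.linalg.LinAlgError:
        eigvals, eigvecs = scipy.linalg.eigh(Sb, Sw + ridge * np.eye(d))
    order = np.argsort(eigvals)[::-1][:2]
    W = _orient(eigvecs[:, order].T)  # (up to 2, d)
    if W.shape[0] < 2:
        # one-dimensional score space: the second discriminant axis is
        # degenerate; keep the 2-D contract with a zero axis
        W = np.vstack([W, np.zeros((2 - W.shape[0], d))])
        eigvals = np.concatenate([eigvals[order], np.zeros(2 - order.size)])
    else:
        eigvals = eigvals[order]
    return DiscriminantModel(
        class_labels=tuple(classes),
        projection=W,
        class_centroids_pc=np.stack(centroids),
        eigenvalues=eigvals,
    )


def transform_df_scores(
    scores: np.ndarray, model: DiscriminantModel, labels: np.ndarray | list
) -> DfScoreCloud:
    """Project PC scores onto the two discriminant axes."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[None, :]
    if scores.shape[1] != model.projection.shape[1]:
        raise ShapeError(
            f"score dimension {scores.shape[1]} does not match the model "
            f"({model.projection.shape[1]})"
        )
    return DfScoreCloud(points=scores @ model.projection.T, labels=np.asarray(labels, dtype=object))


def save_model(path, basis: VarianceBasis, model: DiscriminantModel) -> None:
    with h5py.File(path, "w") as f:
        basis.to_hdf5(f.create_group("variance_basis"))
        model.to_hdf5(f.create_group("discriminant"))


def load_model(path) -> tuple[VarianceBasis, DiscriminantModel]:
    with h5py.File(path, "r") as f:
        return (
            VarianceBasis.from_hdf5(f["variance_basis"]),
            DiscriminantModel.from_hdf5(f["discriminant"]),
        )
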