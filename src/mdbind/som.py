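"""Conformational microstates from self-organizing maps.

Frames are described by protein–ligand intermolecular distances
(:class:`FeatureMatrix`), a hexagonal non-periodic SOM (10×10 by default)
is trained online for 5000 cycles, each frame is assigned to its best
matching unit (BMU), and neurons are merged by complete-linkage
agglomerative clustering with the cluster count chosen by the silhouette
score over a scanned range (5–10 by default).  Cluster labels are capital
letters in order of discovery.

Training is the classical online Kohonen rule: per cycle one frame is
drawn uniformly at random (seeded), the BMU found by Euclidean distance,
and every neuron moved toward the frame by
lr·exp(−d²_lattice/(2·radius²)), with the learning rate decaying linearly
0.05 → 0.01 and the neighborhood radius ⌈max(grid)/2⌉ → 1 over the run.
The hexagonal lattice distance is Euclidean in the offset→Cartesian
embedding x = col + 0.5·(row mod 2), y = row·√3/2, which has unit
neighbor spacing.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist
from sklearn.metrics import silhouette_score

from .core import Trajectory, minimum_image

__all__ = [
    "FeatureMatrix",
    "SOMGrid",
    "ClusterModel",
    "DegenerateClusteringError",
    "extract_features",
    "train_som",
    "assign_frames",
    "cluster_neurons",
    "population_map",
    "representative_frame",
]


class DegenerateClusteringError(RuntimeError):
    """The codebook is degenerate (all neurons coincide)."""


@dataclass
class FeatureMatrix:
    """Frames × protein–ligand distances (Å) with per-column labels."""

    values: np.ndarray
    labels: Sequence[str]
    frame_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix must not contain missing values")
        if np.any(self.values < 0):
            raise ValueError("distance features must be nonnegative")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("one label per feature column required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("feature labels must be unique")
        if self.frame_indices is None:
            self.frame_indices = np.arange(self.values.shape[0])
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class SOMGrid:
    """Hexagonal sheet of neurons with their codebook (feature units, Å)."""

    width: int
    height: int
    codebook: np.ndarray
    lattice_xy: np.ndarray
    feature_mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.width * self.height


@dataclass
class ClusterModel:
    """Neuron → cluster letters, the chosen k, and the silhouette scan."""

    neuron_labels: np.ndarray
    k: int
    silhouette_by_k: dict[int, float]
    linkage: str = "complete"
    metric: str = "euclidean"


def hexagonal_positions(width: int, height: int) -> np.ndarray:
    """Cartesian embedding of an offset hexagonal grid, unit neighbor spacing."""
    rows, cols = np.divmod(np.arange(width * height), width)
    x = cols + 0.5 * (rows % 2)
    y = rows * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x, y]).astype(float)


# ---------------------------------------------------------------------------


def extract_features(
    trajectory: Trajectory, pairs: Sequence[tuple[int, int]]
) -> FeatureMatrix:
    """Minimum-image distances per frame for each atom pair."""
    if not pairs:
        raise ValueError("need at least one atom pair")
    n = trajectory.topology.n_atoms
    for i, j in pairs:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"pair ({i},{j}) out of range")
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    values = np.empty((len(trajectory), len(pairs)))
    for k, frame in enumerate(trajectory):
        d = minimum_image(
            frame.coordinates[jj] - frame.coordinates[ii], frame.box
        )
        values[k] = np.linalg.norm(d, axis=1)
    labels = [f"{i}-{j}" for i, j in pairs]
    return FeatureMatrix(values=values, labels=labels)


def train_som(
    features: FeatureMatrix,
    width: int = 10,
    height: int = 10,
    cycles: int = 5000,
    seed: int = 1234,
    lr_start: float = 0.05,
    lr_end: float = 0.01,
    radius_start: float | None = None,
    radius_end: float = 1.0,
) -> SOMGrid:
    """Online SOM training on a hexagonal, non-periodic sheet.

    The codebook is initialized by sampling input frames (seeded), which
    keeps the initial weights on the data scale.  Zero-variance features
    are dropped with a warning.  Deterministic for a given seed.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if features.n_frames == 0 or features.n_features == 0:
        raise ValueError("empty feature matrix")
    x = features.values
    variances = x.var(axis=0)
    mask = variances > 0
    if not mask.any():
        # a single repeated frame still trains (all features constant)
        mask = np.ones(features.n_features, dtype=bool)
    elif not mask.all():
        dropped = [features.labels[i] for i in np.flatnonzero(~mask)]
        warnings.warn(f"dropping zero-variance features: {dropped}")
    x = x[:, mask]

    n_neurons = width * height
    if features.n_frames < n_neurons:
        warnings.warn(
            f"{features.n_frames} frames for {n_neurons} neurons; "
            "the map will be undersampled"
        )
    rng = np.random.default_rng(seed)
    init_idx = rng.choice(
        features.n_frames, size=n_neurons,
        replace=features.n_frames < n_neurons,
    )
    codebook = x[init_idx].astype(float).copy()
    positions = hexagonal_positions(width, height)
    lattice_d2 = cdist(positions, positions, "sqeuclidean")
    if radius_start is None:
        radius_start = float(np.ceil(max(width, height) / 2.0))

    denom = max(cycles - 1, 1)
    for t in range(cycles):
        frac = t / denom
        lr = lr_start + (lr_end - lr_start) * frac
        radius = radius_start + (radius_end - radius_start) * frac
        sample = x[rng.integers(features.n_frames)]
        bmu = int(np.argmin(((codebook - sample) ** 2).sum(axis=1)))
        influence = np.exp(-lattice_d2[bmu] / (2.0 * radius**2))
        codebook += lr * influence[:, None] * (sample - codebook)

    return SOMGrid(
        width=width, height=height, codebook=codebook,
        lattice_xy=positions, feature_mask=mask,
        metadata={
            "cycles": cycles, "seed": seed,
            "lr_schedule": (lr_start, lr_end),
            "radius_schedule": (radius_start, radius_end),
        },
    )


def assign_frames(som: SOMGrid, features: FeatureMatrix) -> np.ndarray:
    """Per-frame BMU index (nearest codebook vector; ties → lowest index)."""
    x = features.values[:, som.feature_mask]
    if x.shape[1] != som.codebook.shape[1]:
        raise ValueError("feature count does not match the codebook")
    d = cdist(x, som.codebook)
    return np.argmin(d, axis=1)


def cluster_neurons(
    som: SOMGrid,
    features: FeatureMatrix,
    assignments: np.ndarray | None = None,
    k_range: Sequence[int] = range(5, 11),
    level: str = "frames",
) -> ClusterModel:
    """Merge neurons by complete-linkage clustering; pick k by silhouette.

    The dendrogram is cut at each k in ``k_range``; every frame inherits
    its BMU's cluster and the mean silhouette is computed over frames in
    feature space (``level="neurons"`` scores the non-empty codebook
    vectors instead).  The k with the highest silhouette wins; its neuron
    labeling is relabeled A, B, … in order of first appearance by neuron
    index.
    """
    k_range = [int(k) for k in k_range]
    if min(k_range) < 2 or max(k_range) > som.n_neurons:
        raise ValueError("k_range must lie within [2, neuron count]")
    if assignments is None:
        assignments = assign_frames(som, features)
    # cluster only neurons that represent at least one frame; frame-empty
    # neurons are interpolation artifacts of the sheet and would otherwise
    # inflate the cluster count without changing any frame's label
    occupied_idx = np.unique(assignments)
    occ_codebook = som.codebook[occupied_idx]
    if len(occupied_idx) < 2 or pdist(occ_codebook).max() < 1e-12:
        raise DegenerateClusteringError(
            "occupied codebook vectors coincide; the dendrogram is degenerate"
        )
    z = linkage(occ_codebook, method="complete", metric="euclidean")
    x = features.values[:, som.feature_mask]
    occ_rank = {int(n): r for r, n in enumerate(occupied_idx)}
    frame_neuron_rank = np.array([occ_rank[int(n)] for n in assignments])

    scores: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in k_range:
        if k > len(occupied_idx):
            warnings.warn(f"k={k} exceeds the {len(occupied_idx)} occupied neurons; skipped")
            continue
        occ_labels = fcluster(z, t=k, criterion="maxclust")
        labelings[k] = occ_labels
        if level == "neurons":
            lab = occ_labels
            data = occ_codebook
        else:
            lab = occ_labels[frame_neuron_rank]
            data = x
        if len(np.unique(lab)) < 2:
            warnings.warn(f"k={k}: all frames fall in one cluster; skipped")
            continue
        scores[k] = float(silhouette_score(data, lab))
    if not scores:
        raise DegenerateClusteringError("no k in range yields >=2 populated clusters")

    best_k = max(scores, key=lambda k: (scores[k], -k))
    occ_best = labelings[best_k]
    # attach frame-empty neurons to the cluster of the nearest occupied neuron
    nearest = np.argmin(cdist(som.codebook, occ_codebook), axis=1)
    raw = occ_best[nearest]
    raw[occupied_idx] = occ_best
    letters = {}
    final = np.empty(som.n_neurons, dtype="<U2")
    for neuron in range(som.n_neurons):
        c = raw[neuron]
        if c not in letters:
            letters[c] = _letter(len(letters))
        final[neuron] = letters[c]
    return ClusterModel(
        neuron_labels=final, k=int(len(letters)), silhouette_by_k=scores
    )


def _letter(i: int) -> str:
    alphabet = string.ascii_uppercase
    if i < len(alphabet):
        return alphabet[i]
    return alphabet[i // len(alphabet) - 1] + alphabet[i % len(alphabet)]


def population_map(assignments: np.ndarray, som: SOMGrid) -> np.ndarray:
    """Per-neuron frame counts (sums to the frame count)."""
    assignments = np.asarray(assignments, dtype=int)
    if assignments.size and (
        assignments.min() < 0 or assignments.max() >= som.n_neurons
    ):
        raise ValueError("assignments reference unknown neurons")
    return np.bincount(assignments, minlength=som.n_neurons)


def representative_frame(
    cluster: str,
    model: ClusterModel,
    assignments: np.ndarray,
    features: FeatureMatrix,
    som: SOMGrid,
) -> int:
    """Frame closest to the codebook of the cluster's most populated neuron.

    Ties in population go to the lowest neuron index; ties in distance to
    the lowest frame index.
    """
    members = np.flatnonzero(model.neuron_labels == cluster)
    if members.size == 0:
        raise ValueError(f"unknown cluster label {cluster!r}")
    counts = population_map(assignments, som)
    if counts[members].max() == 0:
        raise ValueError(f"cluster {cluster!r} holds no frames")
    top_neuron = int(members[np.argmax(counts[members])])
    frames = np.flatnonzero(np.asarray(assignments) == top_neuron)
    x = features.values[:, som.feature_mask]
    d = np.linalg.norm(x[frames] - som.codebook[top_neuron], axis=1)
    return int(frames[np.argmin(d)])
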