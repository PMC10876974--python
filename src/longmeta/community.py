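"""Community-level structure: richness, dissimilarity, ordination, clustering.

Richness is compared across samples after downsampling every sample to the
smallest retained read count (reads in excluded clades — vertebrate host and
plant material by default — are removed first).  Between-sample structure
uses Bray–Curtis dissimilarity on the filtered compositional estimates,
classical-scaling ordination (PCoA), and a k-means scan over k = 2..6 scored
by mean silhouette.  "Cluster spaces" for follow-up samples are the 2-D
convex hulls of the baseline samples of each cluster in the first two
ordination axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import QhullError, ConvexHull, Delaunay
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .taxonomy import (
    NCBI_CHORDATA,
    NCBI_VIRIDIPLANTAE,
    ReadAssignment,
    TaxonomyTree,
)
from .validation import ValidationResult

__all__ = [
    "OrdinationResult",
    "ClusterResult",
    "downsampled_richness",
    "bray_curtis_matrix",
    "pcoa",
    "scan_kmeans",
    "cluster_membership",
]


def downsampled_richness(
    assignments_by_sample: Mapping[str, Sequence[ReadAssignment]],
    tree: TaxonomyTree,
    validation_by_sample: Mapping[str, Sequence[ValidationResult]],
    seed: int,
    *,
    exclude_clades: Sequence[int] | None = None,
    ranks: tuple[str, ...] = ("species", "genus"),
) -> pd.DataFrame:
    """Per-sample taxon richness at a common downsampled depth.

    Excluded-clade reads (default: Chordata and Viridiplantae, i.e. host and
    dietary plant DNA) are removed *before* the common depth is computed as
    the minimum retained read count over samples.  Each sample is then
    uniformly subsampled without replacement to that depth and distinct
    validated taxa are counted at each requested rank.
    """
    if len(assignments_by_sample) < 2:
        raise ValueError("need at least 2 samples for comparable richness")
    if exclude_clades is None:
        exclude_clades = (NCBI_CHORDATA, NCBI_VIRIDIPLANTAE)
    excluded: set[int] = set()
    for clade in exclude_clades:
        if clade in tree:
            excluded |= tree.descendants(clade)

    retained: dict[str, list[ReadAssignment]] = {}
    for sample, assignments in assignments_by_sample.items():
        kept = [
            a
            for a in assignments
            if a.classified and a.taxid not in excluded
        ]
        if not kept:
            raise ValueError(f"sample {sample}: zero retained reads")
        retained[sample] = kept
    depth = min(len(v) for v in retained.values())

    rng = np.random.default_rng(seed)
    rows = {}
    for sample in sorted(retained):
        reads = retained[sample]
        if len(reads) > depth:
            idx = rng.choice(len(reads), size=depth, replace=False)
            reads = [reads[i] for i in idx]
        validated_taxa = {
            r.taxid
            for r in validation_by_sample.get(sample, ())
            if r.validated
        }
        row = {"depth": depth}
        for rank in ranks:
            taxa = set()
            for a in reads:
                anc = tree.ancestor_at_rank(a.taxid, rank)
                if anc is not None and anc in validated_taxa:
                    taxa.add(anc)
            row[f"n_{rank}"] = len(taxa)
        rows[sample] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def bray_curtis_matrix(vectors: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity BC(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ).

    Input rows are per-sample abundance vectors; each is renormalized to sum
    1, so distances lie in [0, 1].  An all-zero row is an error.
    """
    mat = np.asarray(vectors, dtype=float)
    if (mat < 0).any():
        raise ValueError("abundance vectors must be non-negative")
    sums = mat.sum(axis=1)
    if (sums == 0).any():
        bad = list(np.asarray(vectors.index)[sums == 0])
        raise ValueError(f"all-zero abundance vector for samples: {bad}")
    mat = mat / sums[:, None]
    dist = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(dist, ids=[str(i) for i in vectors.index])


@dataclass(frozen=True)
class OrdinationResult:
    """Classical-scaling (PCoA) embedding.

    Only positive-eigenvalue axes are retained; ``proportion_explained`` is
    each axis' share of the positive inertia.  ``n_negative_eigenvalues``
    reports how many axes were dropped for non-Euclidean input.
    """

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # (n_samples, n_axes)
    eigenvalues: np.ndarray  # positive, decreasing
    proportion_explained: np.ndarray
    n_negative_eigenvalues: int

    def coordinates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates,
            index=list(self.sample_ids),
            columns=[f"PC{i + 1}" for i in range(self.coordinates.shape[1])],
        )


def pcoa(distances: DistanceMatrix, *, eps: float = 1e-10) -> OrdinationResult:
    """Principal-coordinates analysis by classical scaling.

    Double-center −½D², eigendecompose, scale eigenvectors by the square
    roots of their (positive) eigenvalues.  Negative-eigenvalue axes, which
    arise for non-Euclidean dissimilarities such as Bray–Curtis, are dropped
    and counted.
    """
    d = np.asarray(distances.data, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = max(abs(evals[0]), 1.0) if n else 1.0
    positive = evals > eps * scale
    n_negative = int((evals < -eps * scale).sum())
    evals_pos = evals[positive]
    coords = evecs[:, positive] * np.sqrt(evals_pos)
    if coords.shape[1] == 0:
        coords = np.zeros((n, 1))
        evals_pos = np.zeros(1)
        prop = np.zeros(1)
    else:
        prop = evals_pos / evals_pos.sum()
    return OrdinationResult(
        sample_ids=tuple(distances.ids),
        coordinates=coords,
        eigenvalues=evals_pos,
        proportion_explained=prop,
        n_negative_eigenvalues=n_negative,
    )


@dataclass(frozen=True)
class ClusterResult:
    """Outcome of the silhouette-scored k-means scan."""

    k: int
    labels: dict[str, int]
    silhouette_by_k: dict[int, float]
    seed: int
    restarts: int
    skipped_k: tuple[int, ...] = ()


def scan_kmeans(
    ordination: OrdinationResult,
    *,
    k_range: tuple[int, int] = (2, 6),
    seed: int = 0,
    restarts: int = 100,
    n_axes: int | None = None,
    sample_ids: Sequence[str] | None = None,
) -> ClusterResult:
    """k-means over the ordination axes, scanning k for the best silhouette.

    For each k the best of ``restarts`` seeded runs (by inertia) is kept and
    scored by mean silhouette width in the retained-axis Euclidean space;
    the chosen k maximizes silhouette, ties going to the smaller k.  Values
    of k exceeding the sample count are skipped.

    ``sample_ids`` restricts the scan (and the labels) to a subset, e.g.
    pre-treatment baseline samples within a joint ordination.
    """
    coords = ordination.coordinates
    ids = list(ordination.sample_ids)
    if sample_ids is not None:
        wanted = [str(s) for s in sample_ids]
        pos = {s: i for i, s in enumerate(ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise ValueError(f"samples absent from ordination: {missing}")
        coords = coords[[pos[s] for s in wanted]]
        ids = wanted
    if n_axes is not None:
        coords = coords[:, :n_axes]
    n = coords.shape[0]
    kmin, kmax = k_range
    if kmin < 2:
        raise ValueError("k must start at 2")

    silhouettes: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    skipped = []
    for k in range(kmin, kmax + 1):
        if k > n - 1:
            skipped.append(k)
            continue
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        labels = km.fit_predict(coords)
        if len(set(labels)) < 2:
            skipped.append(k)
            continue
        silhouettes[k] = float(silhouette_score(coords, labels))
        labels_by_k[k] = labels
    if not silhouettes:
        raise ValueError("no feasible k in the scan range")
    best_k = min(silhouettes, key=lambda k: (-silhouettes[k], k))
    return ClusterResult(
        k=best_k,
        labels={s: int(l) for s, l in zip(ids, labels_by_k[best_k])},
        silhouette_by_k=silhouettes,
        seed=seed,
        restarts=restarts,
        skipped_k=tuple(skipped),
    )


def _in_hull(points: np.ndarray, query: np.ndarray, tol: float = 1e-9) -> bool:
    """Point-in-convex-hull test robust to degenerate (collinear) clusters."""
    if len(points) >= 3:
        try:
            hull = Delaunay(points)
            return bool(hull.find_simplex(query) >= 0)
        except QhullError:
            pass  # degenerate: fall through to segment/point test
    # Distance from query to the segment (or point) spanned by the cluster.
    if len(points) == 1:
        return bool(np.linalg.norm(query - points[0]) <= tol)
    best = np.inf
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            a, b = points[i], points[j]
            ab = b - a
            denom = float(ab @ ab)
            t = 0.0 if denom == 0 else np.clip((query - a) @ ab / denom, 0, 1)
            best = min(best, float(np.linalg.norm(query - (a + t * ab))))
    return best <= tol


def cluster_membership(
    ordination: OrdinationResult,
    baseline_labels: Mapping[str, int],
    query_samples: Sequence[str],
    *,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Which baseline cluster space, if any, contains each query sample.

    A cluster space is the convex hull of that cluster's baseline samples in
    the first two ordination axes.  Returns a frame with one row per query
    sample: ``cluster`` (label or −1 for outside all hulls) and ``inside``.
    """
    coords = ordination.coordinates_frame().iloc[:, :2]
    missing = [s for s in query_samples if s not in coords.index]
    missing += [s for s in baseline_labels if s not in coords.index]
    if missing:
        raise ValueError(f"samples absent from ordination: {sorted(set(missing))}")
    hulls: dict[int, np.ndarray] = {}
    for cluster in sorted(set(baseline_labels.values())):
        members = [s for s, c in baseline_labels.items() if c == cluster]
        hulls[cluster] = coords.loc[members].to_numpy()
    rows = []
    for sample in query_samples:
        q = coords.loc[sample].to_numpy()
        hit = -1
        for cluster, pts in hulls.items():
            if _in_hull(pts, q, tol):
                hit = cluster
                break
        rows.append({"sample_id": sample, "cluster": hit, "inside": hit >= 0})
    return pd.DataFrame(rows).set_index("sample_id")
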