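"""Population structure: dosage encoding, PCA, Euclidean UPGMA, concordance.

The analysis chain mirrors the standard R workflow for SNP germplasm panels:
genotypes as 0/1/2 alt-allele dosages, column-centered PCA without unit
variance scaling, Euclidean distances on the dosage matrix, average-linkage
(UPGMA) agglomeration with heights equal to the linkage distances, and an
optimal label matching to compare the PCA- and tree-derived clusterings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .datamodel import MISSING, GenotypeMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class EncodedMatrix:
    """Numeric alt-dosage matrix with an imputation mask for missing cells."""

    accession_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray       # float, (accessions, markers)
    imputed: np.ndarray      # bool mask of originally-missing cells


@dataclass
class PCAResult:
    accession_ids: list[str]
    scores: np.ndarray               # (accessions, k)
    variance_explained: np.ndarray   # percent per component


@dataclass
class Dendrogram:
    """UPGMA merge tree: scipy linkage matrix over named leaves."""

    leaf_ids: list[str]
    linkage: np.ndarray    # (n-1, 4) scipy format; heights are linkage distances

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = len(self.leaf_ids)
        height = {i: 0.0 for i in range(n)}
        label = {i: self.leaf_ids[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = f"{label[a]}:{h - height[a]:g}"
            lb = f"{label[b]}:{h - height[b]:g}"
            label[n + k] = f"({la},{lb})"
            height[n + k] = h
        return label[n + len(self.linkage) - 1] + ";"


def encode_genotypes(
    matrix: GenotypeMatrix, imputation_policy: str = "marker_mean"
) -> EncodedMatrix:
    """Encode calls as alt-allele dosage 0/1/2.

    ``marker_mean`` imputes missing cells with the per-marker mean dosage;
    ``none`` leaves NaN (for pairwise-complete distance modes). Markers with
    no called genotype at all are dropped with a warning.
    """
    if imputation_policy not in ("marker_mean", "none"):
        raise ValidationError(f"unknown imputation policy {imputation_policy!r}")
    values = matrix.calls.astype(float)
    mask = matrix.calls == MISSING
    values[mask] = np.nan
    all_missing = mask.all(axis=0)
    if all_missing.any():
        dropped = [m for m, d in zip(matrix.marker_ids, all_missing) if d]
        warnings.warn(f"dropping {len(dropped)} all-missing marker(s): {dropped[:5]}")
        keep = ~all_missing
        values = values[:, keep]
        mask = mask[:, keep]
        marker_ids = [m for m, k in zip(matrix.marker_ids, keep) if k]
    else:
        marker_ids = list(matrix.marker_ids)
    if imputation_policy == "marker_mean" and mask.any():
        col_means = np.nanmean(values, axis=0)
        values = np.where(np.isnan(values), col_means[None, :], values)
    return EncodedMatrix(list(matrix.accession_ids), marker_ids, values, mask)


def pca(encoded: EncodedMatrix, n_components: int = 2) -> PCAResult:
    """Column-centered PCA (no unit-variance scaling), deterministic signs.

    Component sign is fixed by forcing each component's largest-magnitude
    loading positive. ``variance_explained`` is in percent of total variance.
    """
    X = encoded.values
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValidationError("PCA needs >= 2 accessions and >= 2 markers")
    if n_components > min(n, m):
        raise ValidationError(
            f"n_components={n_components} exceeds min(dim)={min(n, m)}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    # sign convention: largest-|loading| positive per component
    for k in range(n_components):
        j = np.argmax(np.abs(model.components_[k]))
        if model.components_[k, j] < 0:
            scores[:, k] *= -1
    return PCAResult(
        list(encoded.accession_ids),
        scores,
        100.0 * model.explained_variance_ratio_,
    )


def euclidean_distance_matrix(encoded: EncodedMatrix) -> np.ndarray:
    """Symmetric Euclidean distance matrix on imputed dosage rows."""
    if np.isnan(encoded.values).any():
        raise ValidationError(
            "distance matrix requires imputed values; encode with marker_mean"
        )
    return squareform(pdist(encoded.values, metric="euclidean"))


def upgma(distance_matrix: np.ndarray, leaf_ids: list[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    Cluster-pair distance is the unweighted mean over member pairs; merge
    heights are the linkage distances themselves (R hclust convention).
    """
    D = np.asarray(distance_matrix, dtype=float)
    if np.isnan(D).any():
        raise ValidationError("distance matrix contains NaN")
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValidationError("distance matrix must be square symmetric")
    n = D.shape[0]
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return Dendrogram(list(leaf_ids), Z)


def cut_clusters(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Cut the tree into exactly ``k`` clusters; labels follow first-seen leaf order."""
    n = len(dendrogram.leaf_ids)
    if not (1 <= k <= n):
        raise ValidationError(f"k={k} outside [1, {n}]")
    raw = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    attained = len(set(raw))
    if attained != k:
        raise ValidationError(
            f"tied merge heights make k={k} unattainable; nearest attainable k={attained}"
        )
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for leaf, c in zip(dendrogram.leaf_ids, raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        out[leaf] = relabel[c]
    return out


def pca_cluster_assignment(
    result: PCAResult, k: int = 4, seed: int | None = 0
) -> dict[str, int]:
    """Cluster accessions in PC-score space with seeded k-means.

    This reproduces the visual cluster assignment of a PC1/PC2 scatter as a
    computable object; it is an interpretation, not a named method of the
    original workflow.
    """
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(result.scores[:, : min(2, result.scores.shape[1])])
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for acc, c in zip(result.accession_ids, raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        out[acc] = relabel[c]
    return out


def compare_clusterings(
    assign_a: dict[str, int], assign_b: dict[str, int]
) -> tuple[list[str], dict[int, int]]:
    """Discordant accessions between two clusterings after optimal label matching.

    Labels are matched one-to-one by maximizing agreement over the
    contingency table (Hungarian assignment); returns (discordant accession
    list, mapping from A-labels to matched B-labels).
    """
    if set(assign_a) != set(assign_b):
        raise ValidationError("clusterings cover different accession sets")
    labels_a = sorted(set(assign_a.values()))
    labels_b = sorted(set(assign_b.values()))
    table = np.zeros((len(labels_a), len(labels_b)))
    ia = {l: i for i, l in enumerate(labels_a)}
    ib = {l: i for i, l in enumerate(labels_b)}
    for acc in assign_a:
        table[ia[assign_a[acc]], ib[assign_b[acc]]] += 1
    rows, cols = linear_sum_assignment(-table)
    matching = {labels_a[r]: labels_b[c] for r, c in zip(rows, cols)}
    discordant = [
        acc for acc in sorted(assign_a)
        if matching.get(assign_a[acc]) != assign_b[acc]
    ]
    return discordant, matching
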