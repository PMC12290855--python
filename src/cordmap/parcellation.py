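"""Connectivity-based parcellation of the spinal cord.

Each cord gray-matter voxel is described by its Fisher-z FC profile
with every sensorimotor-cortex voxel (feature matrix Z, n_sc x n_smc).
The functional similarity between two cord voxels is the Pearson
correlation of their profiles; average-linkage hierarchical clustering
of 1 - similarity, cut at K, yields functional levels that are compared
with an atlas of segmental levels via maximum-weight matching and Dice.
Stability across subjects is assessed by voxelwise profile correlations
and by aligning individual clusterings to the group solution.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .errors import ContractError
from .seedfc import fisher_z
from .types import BoldImage, LabelMap, as_mask

__all__ = [
    "FCFeatureMatrix",
    "SimilarityMatrix",
    "ClusterSolution",
    "MatchReport",
    "fc_feature_matrix",
    "similarity_from_features",
    "group_mean_similarity",
    "hierarchical_cluster",
    "dice",
    "match_labels_max_weight",
    "intersubject_profile_stability",
    "subject_group_alignment",
    "group_label_heatmaps",
    "cluster_fingerprints",
]


@dataclass
class FCFeatureMatrix:
    """Cord-voxel x cortical-voxel Fisher-z connectivity matrix."""

    Z: np.ndarray  # (n_cord, n_smc)
    cord_mask: np.ndarray
    smc_mask: np.ndarray
    subject: str = "group"
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.Z).all():
            raise ContractError("feature matrix must be finite")
        if self.Z.shape != (int(np.sum(self.cord_mask)), int(np.sum(self.smc_mask))):
            raise ContractError("Z shape inconsistent with mask sizes")


@dataclass
class SimilarityMatrix:
    """Symmetric cord-voxel similarity with unit diagonal."""

    S: np.ndarray
    provenance: str = "subject"
    degenerate_rows: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ContractError("similarity matrix must be square")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ContractError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(S), 1.0):
            raise ContractError("similarity diagonal must be 1")
        if S.max() > 1 + 1e-10 or S.min() < -1 - 1e-10:
            raise ContractError("similarity entries must lie in [-1, 1]")
        self.S = S

    @property
    def n(self) -> int:
        return self.S.shape[0]


def fc_feature_matrix(
    cord_img: BoldImage,
    smc_img: BoldImage,
    cord_mask: np.ndarray,
    smc_mask: np.ndarray,
    subject: str = "group",
) -> FCFeatureMatrix:
    """Fisher-z Pearson correlation of every cord voxel with every
    cortical voxel.  Constant voxels contribute 0 entries (flagged)."""
    if cord_img.n_volumes != smc_img.n_volumes:
        raise ContractError("cord and cortex series must share temporal length")
    cord_mask = as_mask(cord_mask, cord_img.grid)
    smc_mask = as_mask(smc_mask, smc_img.grid)
    X = cord_img.data[cord_mask]
    Y = smc_img.data[smc_mask]

    def standardize(M):
        Mc = M - M.mean(axis=1, keepdims=True)
        sd = np.sqrt((Mc**2).sum(axis=1))
        bad = sd == 0
        Mc = np.divide(Mc, sd[:, None], where=~bad[:, None], out=Mc)
        return Mc, bad

    Xs, bad_x = standardize(X)
    Ys, bad_y = standardize(Y)
    r = np.clip(Xs @ Ys.T, -1.0, 1.0)
    r[bad_x, :] = 0.0
    r[:, bad_y] = 0.0
    Z = fisher_z(r)
    return FCFeatureMatrix(Z, cord_mask, smc_mask, subject,
                           n_degenerate=int(bad_x.sum() + bad_y.sum()))


def similarity_from_features(
    Z: FCFeatureMatrix | np.ndarray, method: str = "pearson"
) -> SimilarityMatrix:
    """Cross-correlation of the feature matrix: S[i, k] is the Pearson
    correlation between the cortical FC profiles of cord voxels i and k.

    ``method='inner'`` uses the raw (normalized) inner product without
    row centering.  Zero-variance rows get similarity 0 and are flagged.
    The diagonal is forced to exactly 1.
    """
    M = Z.Z if isinstance(Z, FCFeatureMatrix) else np.asarray(Z, dtype=float)
    if M.shape[1] < 2:
        raise ContractError("need at least 2 cortical voxels")
    if method == "pearson":
        Mc = M - M.mean(axis=1, keepdims=True)
    elif method == "inner":
        Mc = M.copy()
    else:
        raise ContractError(f"unknown method {method!r}")
    sd = np.sqrt((Mc**2).sum(axis=1))
    bad = sd == 0
    Mc = np.divide(Mc, sd[:, None], where=~bad[:, None], out=Mc)
    S = np.clip(Mc @ Mc.T, -1.0, 1.0)
    S[bad, :] = 0.0
    S[:, bad] = 0.0
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0
    prov = Z.subject if isinstance(Z, FCFeatureMatrix) else "subject"
    return SimilarityMatrix(S, prov, np.flatnonzero(bad))


def group_mean_similarity(mats: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Elementwise mean across subjects (symmetry/diagonal preserved)."""
    if not mats:
        raise ContractError("need at least one similarity matrix")
    n = mats[0].n
    if any(m.n != n for m in mats):
        raise ContractError("similarity matrices differ in size")
    mean = np.mean([m.S for m in mats], axis=0)
    np.fill_diagonal(mean, 1.0)
    return SimilarityMatrix(mean, "group-mean")


@dataclass
class ClusterSolution:
    """Average-linkage clustering of cord voxels across a K range."""

    labels: dict[int, np.ndarray]  # K -> per-voxel labels 1..K
    linkage_matrix: np.ndarray
    k_values: tuple[int, ...]

    def label_map(self, K: int, mask: np.ndarray, affine: np.ndarray | None = None) -> LabelMap:
        data = np.zeros(mask.shape, dtype=np.int32)
        data[mask] = self.labels[K]
        return LabelMap(data, affine if affine is not None else np.eye(4))


def hierarchical_cluster(
    S: SimilarityMatrix, k_values: tuple[int, ...] | list[int]
) -> ClusterSolution:
    """Agglomerative average-linkage on the dissimilarity 1 - S.

    The dendrogram is cut at every requested K; labels are renumbered
    1..K in order of first appearance along the voxel index.
    """
    k_values = tuple(int(k) for k in k_values)
    n = S.n
    if any(k < 1 or k > n for k in k_values):
        raise ContractError(f"k_values must lie in [1, {n}]")
    D = 1.0 - S.S
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    Zl = linkage(squareform(D, checks=False), method="average")
    labels = {}
    for k in k_values:
        raw = fcluster(Zl, t=k, criterion="maxclust")
        # renumber deterministically by first appearance
        order = {}
        out = np.empty_like(raw)
        for i, v in enumerate(raw):
            if v not in order:
                order[v] = len(order) + 1
            out[i] = order[v]
        labels[k] = out
    return ClusterSolution(labels, Zl, k_values)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a&b| / (|a| + |b|); two empty masks give 0."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ContractError("masks must share a grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


@dataclass
class MatchReport:
    """Injective cluster <-> atlas assignment with per-pair Dice."""

    mapping: dict[int, int]  # cluster label -> atlas label
    pair_dice: dict[int, float]  # cluster label -> Dice of its pair
    mean_dice: float
    sd_dice: float
    total_weight: float


def _label_arrays(obj) -> np.ndarray:
    return obj.data if isinstance(obj, LabelMap) else np.asarray(obj)


def match_labels_max_weight(
    clusters: LabelMap | np.ndarray,
    atlas: LabelMap | np.ndarray,
    weight: str = "dice",
) -> MatchReport:
    """Maximum-weight bipartite matching of cluster to atlas labels.

    ``weight`` is 'dice' (default) or 'overlap' (shared voxel count).
    The assignment is injective both ways (Hungarian algorithm on the
    rectangular weight matrix); the report carries per-pair Dice and
    their mean +/- sd regardless of the weight used.
    """
    ca = _label_arrays(clusters)
    aa = _label_arrays(atlas)
    if ca.shape != aa.shape:
        raise ContractError("cluster and atlas maps must share a grid")
    if weight not in ("dice", "overlap"):
        raise ContractError(f"unknown weight {weight!r}")
    c_labels = np.unique(ca[ca != 0])
    a_labels = np.unique(aa[aa != 0])
    if len(c_labels) == 0 or len(a_labels) == 0:
        raise ContractError("both label maps must be nonempty")
    W = np.empty((len(c_labels), len(a_labels)))
    Dm = np.empty_like(W)
    for i, c in enumerate(c_labels):
        cm = ca == c
        for j, a in enumerate(a_labels):
            am = aa == a
            Dm[i, j] = dice(cm, am)
            W[i, j] = Dm[i, j] if weight == "dice" else int((cm & am).sum())
    rows, cols = linear_sum_assignment(-W)
    mapping = {int(c_labels[i]): int(a_labels[j]) for i, j in zip(rows, cols)}
    pair_dice = {int(c_labels[i]): float(Dm[i, j]) for i, j in zip(rows, cols)}
    dvals = np.array(list(pair_dice.values()))
    return MatchReport(mapping, pair_dice, float(dvals.mean()),
                       float(dvals.std(ddof=0)), float(W[rows, cols].sum()))


def intersubject_profile_stability(
    mats: list[SimilarityMatrix],
) -> tuple[np.ndarray, float]:
    """Per-voxel stability of similarity profiles across subject pairs.

    For each cord voxel i, the mean over subject pairs (a, b) of the
    Pearson correlation between row i of S_a and row i of S_b with the
    diagonal entry excluded.  Returns (per-voxel map, grand mean).
    """
    if len(mats) < 2:
        raise ContractError("need at least 2 subjects")
    n = mats[0].n
    if any(m.n != n for m in mats):
        raise ContractError("similarity matrices differ in size")
    off = ~np.eye(n, dtype=bool)
    rows = [m.S[off].reshape(n, n - 1) for m in mats]

    def center(R):
        Rc = R - R.mean(axis=1, keepdims=True)
        sd = np.sqrt((Rc**2).sum(axis=1))
        sd = np.where(sd == 0, 1.0, sd)
        return Rc / sd[:, None]

    rows = [center(R) for R in rows]
    total = np.zeros(n)
    n_pairs = 0
    for a in range(len(rows)):
        for b in range(a + 1, len(rows)):
            total += (rows[a] * rows[b]).sum(axis=1)
            n_pairs += 1
    stability = total / n_pairs
    return stability, float(stability.mean())


def subject_group_alignment(
    individual_labels: np.ndarray,
    group_labels: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, dict[int, int]]:
    """Align one subject's cluster labels to the group labels.

    The contingency matrix (individual x group) is normalized by group
    cluster size, then a maximum-weight injective assignment maps each
    individual label to at most one group label; unmatched individual
    labels become 0 ("unassigned").  Returns (aligned labels, normalized
    contingency, mapping individual -> group).
    """
    ind = np.asarray(individual_labels)
    grp = np.asarray(group_labels)
    if ind.shape != grp.shape:
        raise ContractError("label arrays must share a grid")
    i_labels = np.unique(ind[ind != 0])
    g_labels = np.unique(grp[grp != 0])
    C = np.zeros((len(i_labels), len(g_labels)))
    for a, il in enumerate(i_labels):
        for b, gl in enumerate(g_labels):
            C[a, b] = np.sum((ind == il) & (grp == gl))
    g_sizes = np.array([np.sum(grp == gl) for gl in g_labels], dtype=float)
    Cn = C / np.where(g_sizes == 0, 1.0, g_sizes)[None, :]
    rows, cols = linear_sum_assignment(-Cn)
    mapping = {int(i_labels[i]): int(g_labels[j]) for i, j in zip(rows, cols)}
    aligned = np.zeros_like(ind)
    for il, gl in mapping.items():
        aligned[ind == il] = gl
    return aligned, Cn, mapping


def group_label_heatmaps(
    aligned_subject_labels: list[np.ndarray], group_labels: np.ndarray
) -> dict[int, np.ndarray]:
    """Per group label, the voxelwise count of subjects whose aligned
    label covers the voxel."""
    g_labels = np.unique(group_labels[group_labels != 0])
    heat = {int(g): np.zeros(group_labels.shape, dtype=int) for g in g_labels}
    for aligned in aligned_subject_labels:
        for g in g_labels:
            heat[int(g)] += (aligned == g).astype(int)
    return heat


def cluster_fingerprints(
    cluster_labels: np.ndarray,
    feature_matrices: list[FCFeatureMatrix],
) -> np.ndarray:
    """Group-mean brain FC fingerprint of each cord cluster.

    Per subject and cluster: the mean over member cord voxels of their
    Fisher-z brain FC profiles (the rows of Z) — the mean of member FC
    maps, not the FC of the mean series.  Averaged across subjects;
    returns (K, n_smc).  Empty clusters are skipped with NaN rows.
    """
    if not feature_matrices:
        raise ContractError("need at least one subject feature matrix")
    labels = np.asarray(cluster_labels).ravel()
    n_cord = feature_matrices[0].Z.shape[0]
    if labels.shape[0] != n_cord:
        raise ContractError("cluster labels must cover the cord mask voxels")
    ks = np.unique(labels[labels != 0])
    out = np.full((len(ks), feature_matrices[0].Z.shape[1]), np.nan)
    import warnings as _warnings

    for i, k in enumerate(ks):
        members = labels == k
        if not members.any():  # pragma: no cover - ks built from labels
            _warnings.warn(f"cluster {k} is empty; fingerprint skipped")
            continue
        out[i] = np.mean([fm.Z[members].mean(axis=0) for fm in feature_matrices],
                         axis=0)
    return out
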