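"""Binding-pose analysis: superposition, PCA, X-means, site mapping.

After removing overall protein translation and rotation (least-squares
rigid-body superposition on a reference selection), pooled ligand Cartesian
coordinates are reduced by PCA; the first three principal components are
clustered by X-means (BIC-guided recursive 2-means splitting) into an
optimal number of binding poses, ranked by centroid distance to the
projected crystallographic pose (Pose 1 = closest).  Stable-complex mean
structures feed a per-residue interaction-frequency map f_int, from which
residues hot for every ligand (f_int > 0.1) are excluded as nonspecific
and the remainder ranked as ligand-specific binding sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans


# ---------------------------------------------------------------------------
# superposition


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: Optional[np.ndarray] = None):
    """Optimal rigid-body superposition (Kabsch) of mobile onto reference.

    The rotation/translation minimizing the RMSD over ``selection`` (all
    atoms when None) is found via SVD with a proper rotation enforced
    (det = +1) and applied to *all* mobile atoms (ligand included).

    Returns (transformed coordinates, selection RMSD).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    if len(sel) < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    m_sel, r_sel = mobile[sel], reference[sel]
    m_c, r_c = m_sel.mean(axis=0), r_sel.mean(axis=0)
    a, b = m_sel - m_c, r_sel - r_c
    if np.linalg.matrix_rank(a) < 2:
        raise ValueError("degenerate (collinear) selection")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transformed = (mobile - m_c) @ rot.T + r_c
    rmsd = float(np.sqrt(np.mean(np.sum((transformed[sel] - r_sel) ** 2, axis=1))))
    return transformed, rmsd


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PoseDataset:
    """Pooled, superposed ligand coordinate vectors (one 3n vector per frame)."""

    frames: np.ndarray                         # (T, 3*n_atoms)
    source_ids: Optional[np.ndarray] = None
    reference: Optional[np.ndarray] = None     # crystal pose, same layout

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 3:              # (T, n_atoms, 3) accepted
            self.frames = self.frames.reshape(len(self.frames), -1)
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float).reshape(-1)
            if self.reference.shape[0] != self.frames.shape[1]:
                raise ValueError("reference pose dimensionality mismatch")


@dataclass
class PoseClustering:
    """PCA + X-means result over a PoseDataset."""

    eigenvectors: np.ndarray        # (3n, n_pc)
    variance_fractions: np.ndarray  # (n_pc,)
    scores: np.ndarray              # (T, n_pc)
    labels: np.ndarray = None
    centroids: np.ndarray = None
    pose_ranks: np.ndarray = None   # rank r: cluster pose_ranks[r] is Pose r+1
    crystal_scores: Optional[np.ndarray] = None


def ligand_pca(dataset: PoseDataset, n_components: int = 3) -> PoseClustering:
    """PCA of pooled ligand coordinates about the mean frame.

    Eigen-decomposition of the frame covariance; scores are the centered
    frames projected on the top eigenvectors; variance fractions are
    λ_k / Σλ over *all* components.
    """
    x = dataset.frames
    if len(x) < 2:
        raise ValueError("PCA needs at least 2 frames")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (len(x) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = float(np.sum(evals))
    if total <= 0:
        raise ValueError("zero-variance dataset: variance fractions undefined")
    k = min(n_components, len(evals))
    out = PoseClustering(
        eigenvectors=evecs[:, :k],
        variance_fractions=evals[:k] / total,
        scores=xc @ evecs[:, :k],
    )
    if dataset.reference is not None:
        out.crystal_scores = (dataset.reference - mean) @ evecs[:, :k]
    return out


# ---------------------------------------------------------------------------
# X-means


def _bic(points: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Spherical-Gaussian BIC of a k-means model (Pelleg–Moore formulation)."""
    r, m = points.shape
    k = len(centroids)
    if r <= k:
        return -np.inf
    sq = np.sum((points - centroids[labels]) ** 2)
    sigma2 = sq / (m * (r - k))
    if sigma2 <= 0:
        sigma2 = 1e-300
    ll = 0.0
    for j in range(k):
        rn = int(np.sum(labels == j))
        if rn == 0:
            continue
        ll += (rn * np.log(rn) - rn * np.log(r)
               - rn * m / 2.0 * np.log(2.0 * np.pi * sigma2)
               - (rn - 1) * m / 2.0)
    n_params = k * (m + 1)
    return ll - n_params / 2.0 * np.log(r)


def _kmeans(points: np.ndarray, k: int, seed: int) -> KMeans:
    return KMeans(n_clusters=k, n_init=10, random_state=seed).fit(points)


def xmeans(points: np.ndarray, k_max: int = 20, seed: int = 0):
    """X-means clustering: BIC-guided recursive 2-means splitting.

    Starts from a single cluster and recursively attempts to split each
    centroid in two (k-means++ with 10 restarts per split), accepting a
    split when it improves the spherical-Gaussian BIC of that region, until
    no split is accepted or ``k_max`` clusters exist.  A final global
    k-means refines the accepted centroids.  Deterministic under a fixed
    seed.

    Returns (labels, centroids, k).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if len(points) < 2:
        return np.zeros(len(points), dtype=int), points.copy(), max(len(points), 1)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    centroids = [points.mean(axis=0)]
    improved = True
    while improved and len(centroids) < k_max:
        improved = False
        cent_arr = np.array(centroids)
        d = np.sum((points[:, None, :] - cent_arr[None, :, :]) ** 2, axis=2)
        labels = np.argmin(d, axis=1)
        new_centroids: list[np.ndarray] = []
        budget = k_max - len(centroids)     # splits allowed this round
        for j, c in enumerate(centroids):
            region = points[labels == j]
            if len(region) < 4 or budget == 0:
                new_centroids.append(c)
                continue
            parent_bic = _bic(region, np.zeros(len(region), dtype=int),
                              c[None, :])
            km = _kmeans(region, 2, seed)
            child_bic = _bic(region, km.labels_, km.cluster_centers_)
            if child_bic > parent_bic:
                new_centroids.extend(km.cluster_centers_)
                budget -= 1
                improved = True
            else:
                new_centroids.append(c)
        centroids = new_centroids
    k = len(centroids)
    km = KMeans(n_clusters=k, n_init=1, init=np.array(centroids),
                random_state=seed).fit(points)
    return km.labels_.astype(int), km.cluster_centers_, k


def rank_poses(labels: np.ndarray, centroids: np.ndarray,
               crystal_scores: np.ndarray) -> np.ndarray:
    """Order clusters by centroid distance to the projected crystal pose.

    Returns cluster indices in rank order (element 0 = Pose 1).  Distance
    ties are broken by cluster size, larger first.
    """
    labels = np.asarray(labels)
    centroids = np.asarray(centroids, dtype=float)
    crystal = np.asarray(crystal_scores, dtype=float)
    dist = np.sqrt(np.sum((centroids - crystal) ** 2, axis=1))
    sizes = np.array([np.sum(labels == j) for j in range(len(centroids))])
    order = sorted(range(len(centroids)), key=lambda j: (dist[j], -sizes[j]))
    return np.array(order, dtype=int)


# ---------------------------------------------------------------------------
# interaction-frequency mapping


@dataclass
class InteractionMap:
    """Per-residue interaction frequencies and the specific/nonspecific split."""

    f_int: dict                       # ligand -> {residue: frequency}
    nonspecific: list = field(default_factory=list)
    specific: dict = field(default_factory=dict)   # ligand -> [residues ranked]


def interaction_frequency(stable_windows: Sequence[dict],
                          residue_coords: Sequence[dict],
                          n_trajectories: int, cutoff: float = 0.5,
                          mode: str = "per_trajectory") -> dict:
    """Per-residue ligand interaction frequency f_int.

    For each stable window (with ``ligand_mean`` coordinates) and each
    residue (dict of residue -> (n_atoms, 3) mean heavy-atom coordinates,
    one dict per window), the residue counts as interacting when any of its
    atoms lies within ``cutoff`` of any mean-ligand atom.  Counts are
    normalized by ``n_trajectories`` (default: f_int may exceed 1 when a
    trajectory contributes several stable windows); ``mode="fraction"``
    instead normalizes by the number of stable windows.
    """
    if len(stable_windows) != len(residue_coords):
        raise ValueError("one residue-coordinate dict per stable window required")
    counts: dict = {}
    for window, residues in zip(stable_windows, residue_coords):
        lig = np.atleast_2d(np.asarray(window["ligand_mean"], dtype=float)
                            .reshape(-1, 3))
        for res, coords in residues.items():
            c = np.atleast_2d(np.asarray(coords, dtype=float).reshape(-1, 3))
            d = np.sqrt(np.sum((c[:, None, :] - lig[None, :, :]) ** 2, axis=2))
            counts.setdefault(res, 0)
            if np.min(d) < cutoff:
                counts[res] += 1
    if mode == "per_trajectory":
        denom = n_trajectories
    elif mode == "fraction":
        denom = max(len(stable_windows), 1)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return {res: n / denom for res, n in counts.items()}


def specific_sites(f_int_maps: dict, nonspecific_threshold: float = 0.1
                   ) -> InteractionMap:
    """Split residues into nonspecific and per-ligand specific binding sites.

    ``f_int_maps`` maps ligand name -> {residue: f_int}.  Residues whose
    f_int exceeds the threshold for *every* ligand are nonspecific; the
    remaining residues with nonzero f_int are returned per ligand, ranked
    by decreasing f_int.
    """
    if len(f_int_maps) < 2:
        raise ValueError("need maps for at least 2 ligands")
    residues = sorted({r for m in f_int_maps.values() for r in m})
    nonspecific = [r for r in residues
                   if all(m.get(r, 0.0) > nonspecific_threshold
                          for m in f_int_maps.values())]
    specific = {}
    for ligand, m in f_int_maps.items():
        cands = [(r, f) for r, f in m.items()
                 if r not in nonspecific and f > 0]
        cands.sort(key=lambda rf: (-rf[1], rf[0]))
        specific[ligand] = [r for r, _ in cands]
    return InteractionMap(f_int=dict(f_int_maps), nonspecific=nonspecific,
                          specific=specific)
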