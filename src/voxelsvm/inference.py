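"""Permutation significance mapping of SVM voxel weights.

The trained linear SVM assigns one weight per masked voxel. Retraining the
SVM B times with randomly permuted class labels yields, voxel by voxel, a
null distribution of weights; count-based p-values (floored at 1/B), a
Benjamini-Hochberg FDR decision over the whole mask, and connected-component
cluster extraction with an extent threshold produce the significance map
and the cluster table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from .preprocess import FeatureMatrix
from .svm import LinearSVM
from .volume import VolumeGrid

__all__ = [
    "WeightNullTallies",
    "SignificanceMap",
    "ClusterRecord",
    "weight_null",
    "voxel_pvalues",
    "fdr_bh",
    "extract_clusters",
    "cluster_table",
    "clusters_to_label_volume",
    "overlap_map",
]

SIDEDNESS = ("two-sided-magnitude", "one-sided")


@dataclass
class WeightNullTallies:
    """Streaming per-voxel tallies of the permutation null of SVM weights.

    Only O(voxels) running counts are kept: for each voxel v,
    ``count_abs[v]`` = #{b : |w_null_b[v]| >= |w_obs[v]|} and
    ``count_signed[v]`` = #{b : w_null_b[v] >= w_obs[v]}. Set
    ``store=True`` in :func:`weight_null` to additionally keep the full
    (B, p) null matrix (small toys only).
    """

    w_obs: np.ndarray
    count_abs: np.ndarray
    count_signed: np.ndarray
    B: int
    W_null: np.ndarray | None = None


def weight_null(
    X,
    y,
    C: float,
    w_obs: np.ndarray | None = None,
    B: int = 5000,
    seed: int = 0,
    permutations=None,
    store: bool = False,
    chunk: int = 64,
) -> WeightNullTallies:
    """Retrain the SVM B times with permuted labels; tally the weight null.

    The Gram matrix is computed once; each iteration solves the dual with
    the permuted labels at the fixed C of the unpermuted fit and the null
    weight vectors are materialized in chunks for the running tallies.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    K = X @ X.T
    if w_obs is None:
        w_obs = LinearSVM(C=C).fit_gram(K, y).dual_coef_ @ X
    w_obs = np.asarray(w_obs, dtype=np.float64)
    rng = np.random.default_rng(seed)
    if permutations is None:
        perms = (rng.permutation(len(y)) for _ in range(B))
        n_perms = B
    else:
        perm_list = [np.asarray(p, dtype=int) for p in permutations]
        perms = iter(perm_list)
        n_perms = len(perm_list)

    count_abs = np.zeros(X.shape[1], dtype=np.int64)
    count_signed = np.zeros(X.shape[1], dtype=np.int64)
    stored = [] if store else None
    coefs: list[np.ndarray] = []

    def _flush():
        nonlocal count_abs, count_signed
        if not coefs:
            return
        W = np.asarray(coefs) @ X  # (chunk, p)
        count_abs += (np.abs(W) >= np.abs(w_obs)).sum(axis=0)
        count_signed += (W >= w_obs).sum(axis=0)
        if stored is not None:
            stored.append(W)
        coefs.clear()

    for b, perm in enumerate(perms):
        try:
            model = LinearSVM(C=C).fit_gram(K, y[perm])
        except Exception as exc:  # pragma: no cover - solver failures are rare
            raise RuntimeError(f"solver failed at permutation iteration {b}") from exc
        coefs.append(model.dual_coef_)
        if len(coefs) >= chunk:
            _flush()
    _flush()

    return WeightNullTallies(
        w_obs=w_obs,
        count_abs=count_abs,
        count_signed=count_signed,
        B=n_perms,
        W_null=np.vstack(stored) if stored else None,
    )


@dataclass
class SignificanceMap:
    """Per-voxel permutation p-values and (optionally) FDR decisions."""

    p: np.ndarray
    B: int
    sidedness: str
    q: float | None = None
    significant: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)


def voxel_pvalues(tallies: WeightNullTallies, sidedness: str = "two-sided-magnitude") -> SignificanceMap:
    """Count-based p per voxel, floored at 1/B.

    Default compares null and observed weights in magnitude (two-sided); the
    literal one-sided rule (signed ``>=``) is selectable, under which large
    negative weights are never significant.
    """
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}")
    counts = tallies.count_abs if sidedness == "two-sided-magnitude" else tallies.count_signed
    p = np.maximum(counts, 1) / tallies.B
    return SignificanceMap(p=p, B=tallies.B, sidedness=sidedness)


def fdr_bh(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up decisions over one family of p-values."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def significance_volume(sig_map: SignificanceMap, features: FeatureMatrix, q: float = 0.05) -> VolumeGrid:
    """Scatter FDR significance decisions back onto the lattice."""
    sig = fdr_bh(sig_map.p, q=q)
    sig_map.q = q
    sig_map.significant = sig
    return features.row_to_volume(sig.astype(np.float64))


@dataclass
class ClusterRecord:
    """One connected component of significant voxels."""

    index: int
    n_voxels: int
    cog_mm: tuple[float, float, float]
    voxel_ijk: np.ndarray = field(repr=False)
    mean_weight: float | None = None


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_clusters(
    sig_volume: VolumeGrid | np.ndarray,
    affine: np.ndarray | None = None,
    connectivity: int = 26,
    min_size: int = 100,
) -> list[ClusterRecord]:
    """Connected components of the significance mask above an extent cutoff.

    Components with voxel count <= ``min_size`` are discarded ("more than
    100 voxels" is strict). Records are sorted ascending by size and
    re-indexed from 1. The center of gravity is the unweighted centroid of
    member voxel centers mapped through the affine to mm.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    if isinstance(sig_volume, VolumeGrid):
        mask = sig_volume.values > 0
        affine = sig_volume.affine
    else:
        mask = np.asarray(sig_volume) > 0
        if affine is None:
            affine = np.eye(4)
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    records = []
    for lab in range(1, n + 1):
        ijk = np.argwhere(labels == lab)
        if len(ijk) <= min_size:
            continue
        cog_vox = ijk.mean(axis=0)
        cog_mm = affine[:3, :3] @ cog_vox + affine[:3, 3]
        records.append(
            ClusterRecord(index=0, n_voxels=len(ijk), cog_mm=tuple(cog_mm), voxel_ijk=ijk)
        )
    records.sort(key=lambda r: r.n_voxels)
    for i, rec in enumerate(records, start=1):
        rec.index = i
    return records


def cluster_table(clusters: list[ClusterRecord], w_volume: VolumeGrid | np.ndarray) -> pd.DataFrame:
    """Tabulate clusters with their mean SVM weight (Table-style report).

    Columns: cluster index, voxel count, center of gravity (x, y, z in mm),
    arithmetic mean of the observed weight over member voxels.
    """
    w = w_volume.values if isinstance(w_volume, VolumeGrid) else np.asarray(w_volume)
    rows = []
    for rec in clusters:
        vals = w[rec.voxel_ijk[:, 0], rec.voxel_ijk[:, 1], rec.voxel_ijk[:, 2]]
        rec.mean_weight = float(vals.mean())
        rows.append(
            {
                "cluster_index": rec.index,
                "voxels": rec.n_voxels,
                "cog_x_mm": rec.cog_mm[0],
                "cog_y_mm": rec.cog_mm[1],
                "cog_z_mm": rec.cog_mm[2],
                "mean_weight": rec.mean_weight,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cluster_index", "voxels", "cog_x_mm", "cog_y_mm", "cog_z_mm", "mean_weight"],
    )


def clusters_to_label_volume(
    clusters: list[ClusterRecord], shape: tuple[int, int, int], affine: np.ndarray
) -> VolumeGrid:
    """Integer lattice with each cluster's index at its member voxels."""
    vol = np.zeros(shape, dtype=np.float64)
    for rec in clusters:
        vol[rec.voxel_ijk[:, 0], rec.voxel_ijk[:, 1], rec.voxel_ijk[:, 2]] = rec.index
    return VolumeGrid(values=vol, affine=affine)


def overlap_map(a: VolumeGrid, b: VolumeGrid) -> VolumeGrid:
    """Voxelwise AND of two binary maps (overlap of two models' regions)."""
    if a.shape != b.shape:
        raise ValueError("overlap requires identical lattices")
    return a.like(((a.values > 0) & (b.values > 0)).astype(np.float64))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient between two boolean lattices."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else np.nan
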