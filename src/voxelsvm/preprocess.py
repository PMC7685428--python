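"""Mask construction, smoothing, nuisance-covariate removal and feature assembly.

The analysis operates on gray-matter density volumes that are already in a
common space. This module turns a set of such volumes into a subjects x
masked-voxels feature matrix:

1. smooth every volume with a Gaussian kernel (default 8 mm FWHM),
2. build a brain mask from the mean smoothed image of ALL subjects
   (density strictly above 0.2),
3. flatten the masked voxels into rows (x varying fastest),
4. regress nuisance covariates (age, sex by default) out of every voxel
   column, independently per acquisition site, keeping the site mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .volume import VolumeGrid, check_same_grid

__all__ = [
    "MaskVolume",
    "FeatureMatrix",
    "SiteResidualizer",
    "build_mask",
    "smooth_volume",
    "residualize",
    "assemble_features",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class MaskVolume:
    """Boolean analysis mask on the same lattice as the input volumes."""

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_ijk(self) -> np.ndarray:
        """Lattice coordinates of masked voxels, x varying fastest, shape (p, 3)."""
        flat = np.flatnonzero(self.mask.ravel(order="F"))
        return np.stack(np.unravel_index(flat, self.mask.shape, order="F"), axis=1)


@dataclass
class FeatureMatrix:
    """Subjects x masked-voxels matrix with the voxel-index <-> lattice map.

    Rows follow ``subject_ids`` order; column j corresponds to lattice
    coordinate ``voxel_ijk[j]`` (columns enumerate mask voxels with the x
    index varying fastest).
    """

    X: np.ndarray
    subject_ids: list[str]
    voxel_ijk: np.ndarray
    affine: np.ndarray
    shape: tuple[int, int, int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2D")
        if self.X.shape[0] != len(self.subject_ids):
            raise ValueError("row count != number of subject ids")
        if self.X.shape[1] != self.voxel_ijk.shape[0]:
            raise ValueError("column count != number of mapped voxels")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def row_to_volume(self, row: int | np.ndarray, fill: float = 0.0) -> VolumeGrid:
        """Scatter one row (or any length-p vector) back onto the lattice."""
        vec = self.X[row] if np.isscalar(row) else np.asarray(row, dtype=np.float64)
        vol = np.full(self.shape, fill, dtype=np.float64)
        vol[self.voxel_ijk[:, 0], self.voxel_ijk[:, 1], self.voxel_ijk[:, 2]] = vec
        return VolumeGrid(values=vol, affine=self.affine)

    def save(self, prefix: str | Path) -> None:
        """Persist as flat binary (.npy) plus a JSON sidecar."""
        prefix = Path(prefix)
        np.save(str(prefix) + ".npy", self.X)
        sidecar = {
            "subject_ids": list(self.subject_ids),
            "voxel_ijk": self.voxel_ijk.tolist(),
            "affine": self.affine.tolist(),
            "shape": list(self.shape),
            "provenance": self.provenance,
        }
        Path(str(prefix) + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, prefix: str | Path) -> "FeatureMatrix":
        prefix = Path(prefix)
        X = np.load(str(prefix) + ".npy")
        meta = json.loads(Path(str(prefix) + ".json").read_text())
        return cls(
            X=X,
            subject_ids=meta["subject_ids"],
            voxel_ijk=np.asarray(meta["voxel_ijk"], dtype=int),
            affine=np.asarray(meta["affine"]),
            shape=tuple(meta["shape"]),
            provenance=meta["provenance"],
        )


def build_mask(volumes: list[VolumeGrid], threshold: float = 0.2) -> MaskVolume:
    """Mask = voxels whose mean density across ALL subjects is > threshold.

    The mean is taken over every provided volume (both sites together), and
    the comparison is strict: a voxel exactly at the threshold is excluded.
    """
    if not volumes:
        raise ValueError("need at least one volume to build a mask")
    check_same_grid(volumes)
    mean = np.mean([v.values for v in volumes], axis=0)
    return MaskVolume(mask=mean > threshold, affine=volumes[0].affine)


def smooth_volume(v: VolumeGrid, fwhm_mm: float = 8.0) -> VolumeGrid:
    """Gaussian smoothing with per-axis sigma derived from the affine.

    sigma_axis = fwhm_mm / (2 sqrt(2 ln 2)) / voxel_size_axis. The boundary
    is handled by normalized convolution (divide by the smoothed indicator),
    which conserves the total density of interior impulses and avoids the
    darkening that zero-padding alone would cause at the lattice edge.
    fwhm_mm = 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return v.like(v.values.copy())
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / v.voxel_sizes_mm
    # normalized convolution with the renormalization applied at the source:
    # dividing the INPUT by the smoothed indicator makes the total density
    # exactly conserved (sum_x g(x-c) = norm(c) for a symmetric kernel),
    # while matching plain convolution everywhere the kernel fits inside
    norm = gaussian_filter(np.ones_like(v.values), sigma=sigma_vox, mode="constant", cval=0.0)
    out = gaussian_filter(v.values / norm, sigma=sigma_vox, mode="constant", cval=0.0)
    return v.like(out)


class SiteResidualizer(BaseEstimator, TransformerMixin):
    """Remove nuisance covariates from every voxel, independently per site.

    For each site, each voxel column is regressed (OLS) on an intercept plus
    the site-centered covariates; the output is the residual plus the fitted
    intercept, i.e. the site mean is retained so densities stay on the GM
    scale. Covariates are configurable (age and sex by default; intracranial
    volume or any other numeric column may be added).

    Parameters
    ----------
    covariates : list of str
        Column names in the covariate table passed to :meth:`fit`.
    """

    def __init__(self, covariates: tuple[str, ...] = ("age", "sex")):
        self.covariates = covariates

    def fit(self, X, y=None, *, covariate_table: pd.DataFrame, sites: np.ndarray):
        X = np.asarray(X, dtype=np.float64)
        sites = np.asarray(sites)
        if len(covariate_table) != X.shape[0] or len(sites) != X.shape[0]:
            raise ValueError("covariate rows must align with feature rows")
        self.coef_: dict = {}
        self.means_: dict = {}
        self.site_labels_ = [str(s) for s in pd.unique(sites)]
        for site in pd.unique(sites):
            idx = np.flatnonzero(sites == site)
            D = self._design(covariate_table.iloc[idx], site)
            if len(idx) <= D.shape[1]:
                raise ValueError(
                    f"site {site!r} has {len(idx)} subjects but the design has "
                    f"{D.shape[1]} columns; need more subjects than covariates + 1"
                )
            beta, *_ = np.linalg.lstsq(D, X[idx], rcond=None)
            self.coef_[str(site)] = beta
        return self

    def _design(self, cov: pd.DataFrame, site) -> np.ndarray:
        cols = [np.ones(len(cov))]
        means = {}
        for name in self.covariates:
            if name not in cov.columns:
                raise ValueError(f"covariate {name!r} missing from table")
            x = _encode_covariate(cov[name])
            if np.allclose(x.std(), 0.0):
                raise ValueError(
                    f"covariate {name!r} is constant within site {site!r} "
                    "(rank-deficient design)"
                )
            means[name] = float(x.mean())
            cols.append(x - x.mean())
        D = np.column_stack(cols)
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError(f"rank-deficient design for site {site!r}")
        self.means_[str(site)] = means
        return D

    def transform(self, X, *, covariate_table: pd.DataFrame, sites: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        sites = np.asarray(sites)
        out = np.empty_like(X)
        for site in pd.unique(sites):
            key = str(site)
            if key not in self.coef_:
                raise ValueError(f"site {site!r} was not seen during fit")
            idx = np.flatnonzero(sites == site)
            cov = covariate_table.iloc[idx]
            cols = [np.ones(len(idx))]
            for name in self.covariates:
                x = _encode_covariate(cov[name])
                cols.append(x - self.means_[key][name])
            D = np.column_stack(cols)
            beta = self.coef_[key]
            fitted = D @ beta
            # residual + fitted intercept: site mean is kept
            out[idx] = X[idx] - fitted + beta[0]
        return out


def _encode_covariate(col: pd.Series) -> np.ndarray:
    """Numeric passthrough; sex-like string columns coded F=0, M=1."""
    if col.dtype.kind in "OUS":
        vals = col.astype(str).str.upper()
        known = {"F": 0.0, "M": 1.0, "FEMALE": 0.0, "MALE": 1.0}
        if not set(vals).issubset(known):
            raise ValueError(f"cannot encode non-numeric covariate {col.name!r}")
        return vals.map(known).to_numpy(dtype=np.float64)
    return col.to_numpy(dtype=np.float64)


def residualize(
    features: FeatureMatrix,
    covariate_table: pd.DataFrame,
    sites: np.ndarray,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> FeatureMatrix:
    """Per-site OLS removal of covariates from every voxel column.

    Thin functional wrapper over :class:`SiteResidualizer` fitted and applied
    on the same subjects (the classical in-sample residualization).
    """
    res = SiteResidualizer(covariates=covariates)
    res.fit(features.X, covariate_table=covariate_table, sites=sites)
    Xr = res.transform(features.X, covariate_table=covariate_table, sites=sites)
    prov = dict(features.provenance)
    prov["residualized_covariates"] = list(covariates)
    return FeatureMatrix(
        X=Xr,
        subject_ids=features.subject_ids,
        voxel_ijk=features.voxel_ijk,
        affine=features.affine,
        shape=features.shape,
        provenance=prov,
    )


def assemble_features(
    volumes: dict[str, VolumeGrid] | list[VolumeGrid],
    mask: MaskVolume,
    subject_ids: list[str],
    provenance: dict | None = None,
) -> FeatureMatrix:
    """Stack masked voxels of each subject into rows, x index varying fastest."""
    if isinstance(volumes, list):
        if len(volumes) != len(subject_ids):
            raise ValueError("volume list length != subject id count")
        volumes = dict(zip(subject_ids, volumes))
    missing = [sid for sid in subject_ids if sid not in volumes]
    if missing:
        raise ValueError(f"missing volumes for subjects: {missing}")
    vols = [volumes[sid] for sid in subject_ids]
    check_same_grid(vols, names=list(subject_ids))
    if vols[0].shape != mask.mask.shape:
        raise ValueError("mask shape does not match volume shape")
    flat_mask = mask.mask.ravel(order="F")
    X = np.stack([v.values.ravel(order="F")[flat_mask] for v in vols])
    return FeatureMatrix(
        X=X,
        subject_ids=list(subject_ids),
        voxel_ijk=mask.voxel_ijk,
        affine=mask.affine,
        shape=mask.mask.shape,
        provenance=dict(provenance or {}),
    )
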