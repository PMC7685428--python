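"""End-to-end two-site experiment orchestration.

simulate -> smooth -> mask -> residualize -> for each direction (train on
one site, test on the other): C selection, cross-validated and cross-site
performance with permutation p-values, weight-map significance, cluster
table, clinical correlations -> overlap of the two models' maps. Every
artifact is written under a run directory with a hash manifest and a
deterministic seed chain derived from one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin
from . import inference as inf
from . import svm as svm_mod
from .cohort import Cohort, CohortSpec, default_two_site_spec, generate_cohort
from .preprocess import (
    FeatureMatrix,
    SiteResidualizer,
    assemble_features,
    build_mask,
    smooth_volume,
)
from .volume import save_volume

__all__ = ["RunConfig", "run_experiment", "prepare_features"]

log = logging.getLogger("voxelsvm")

#: stage names of the seed chain, spawned in this order from the master seed
_STAGES = ("simulate", "cv_a", "cv_b", "perf_a", "perf_b", "weights_a", "weights_b")


@dataclass
class RunConfig:
    """Every analysis constant of the pipeline, with the protocol defaults.

    Defaults: GM mask threshold 0.2, 8 mm FWHM smoothing, age + sex
    residualized per site, ten-fold CV for C, 5000 permutation iterations,
    FDR q < 0.05, cluster extent > 100 voxels.
    """

    cohort_spec: CohortSpec | None = None
    dataset: str | None = None
    mask_threshold: float = 0.2
    fwhm_mm: float = 8.0
    covariates: tuple[str, ...] = ("age", "sex")
    c_grid: tuple[float, ...] | None = None
    folds: int = 10
    b_performance: int = 5000
    b_weights: int = 5000
    q: float = 0.05
    min_cluster_size: int = 100
    connectivity: int = 26
    sidedness: str = "two-sided-magnitude"
    seed: int = 0
    strict_split: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort_spec is not None:
            d["cohort_spec"] = self.cohort_spec.to_dict()
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        spec_raw = raw.pop("cohort_spec", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if isinstance(spec_raw, dict):
            cfg.cohort_spec = _lenient_spec(spec_raw, seed=cfg.seed)
        return cfg


def _lenient_spec(d: dict, seed: int) -> CohortSpec:
    """Build a CohortSpec from a (possibly partial) config mapping."""
    from .cohort import ClinicalDistributions, EffectRegion, SiteSpec

    factory_kwargs = {}
    for key in ("grid_shape", "voxel_size_mm"):
        if key in d:
            val = d[key]
            factory_kwargs[key] = tuple(val) if isinstance(val, list) else val
    spec = default_two_site_spec(seed=d.get("seed", seed), **factory_kwargs)
    simple = (
        "age_slope", "sex_effect", "subject_noise_sd",
        "smoothness_mm", "background", "interior_range", "seed",
    )
    for key in simple:
        if key in d:
            val = d[key]
            setattr(spec, key, tuple(val) if isinstance(val, list) else val)
    if "sites" in d:
        spec.sites = [
            SiteSpec(**{
                **s,
                "clinical": ClinicalDistributions(
                    **{k: tuple(v) for k, v in s.get("clinical", {}).items()}
                ),
            })
            for s in d["sites"]
        ]
    if "effect_regions" in d:
        spec.effect_regions = [
            EffectRegion(
                center_mm=tuple(r["center_mm"]),
                radii_mm=tuple(r["radii_mm"]),
                effect_d=r.get("effect_d", 0.0),
                clinical_link=tuple(r["clinical_link"]) if r.get("clinical_link") else None,
            )
            for r in d["effect_regions"]
        ]
    return spec


def prepare_features(
    cohort: Cohort,
    fwhm_mm: float = 8.0,
    mask_threshold: float = 0.2,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """Smooth, mask, assemble and residualize one cohort.

    Returns (features, labels in {-1 patient, +1 control}, site labels),
    rows aligned with the participants table.
    """
    from .preprocess import residualize

    smoothed = {sid: smooth_volume(v, fwhm_mm) for sid, v in cohort.volumes.items()}
    mask = build_mask(list(smoothed.values()), threshold=mask_threshold)
    feats = assemble_features(smoothed, mask, cohort.subject_ids)
    p = cohort.participants
    sites = p["site"].to_numpy()
    feats = residualize(feats, p[list(covariates)], sites, covariates=covariates)
    y = np.where(p["diagnosis"] == "patient", svm_mod.PATIENT, svm_mod.CONTROL)
    return feats, y, sites


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministically spawn one sub-seed per pipeline stage (< 2^31)."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def run_experiment(config: RunConfig, outdir: str | Path, cohort: Cohort | None = None) -> dict:
    """Run the full two-site experiment; returns the manifest dict.

    ``cohort`` may be passed directly (e.g. a pre-generated or loaded
    study); otherwise it is simulated from ``config.cohort_spec`` with the
    seed chain's simulate seed.
    """
    outdir = Path(outdir)
    for sub in ("models", "maps", "tables", "logs"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir / "logs" / "run.log")
    seeds = stage_seeds(config.seed)
    log.info("seed chain: %s", seeds)

    if cohort is None:
        if config.dataset is not None:
            from .cohort import load_cohort

            cohort = load_cohort(config.dataset)
        else:
            spec = config.cohort_spec or default_two_site_spec()
            spec = dataclasses.replace(spec, seed=seeds["simulate"])
            log.info("simulating cohort (grid=%s, seed=%d)", spec.grid_shape, spec.seed)
            cohort = generate_cohort(spec)

    participants = cohort.participants
    site_names = list(pd.unique(participants["site"]))
    if len(site_names) != 2:
        raise ValueError(f"experiment needs exactly 2 sites, found {site_names}")
    participants.to_csv(outdir / "tables" / "participants.tsv", sep="\t", index=False)

    log.info("smoothing %d volumes at %.1f mm FWHM", len(cohort.volumes), config.fwhm_mm)
    smoothed = {
        sid: smooth_volume(vol, config.fwhm_mm) for sid, vol in cohort.volumes.items()
    }
    subject_ids = list(participants["subject_id"])
    sites = participants["site"].to_numpy()
    y_all = np.where(participants["diagnosis"] == "patient", svm_mod.PATIENT, svm_mod.CONTROL)

    perf_rows = []
    sig_vols = {}
    direction_letter = dict(zip(site_names, ("a", "b")))

    if not config.strict_split:
        mask = build_mask(list(smoothed.values()), threshold=config.mask_threshold)
        save_volume(mask_vol := _mask_volume(mask), outdir / "maps" / "mask.nii.gz", dtype=np.uint8)
        feats = assemble_features(smoothed, mask, subject_ids)
        feats = _residualize_all(feats, participants, sites, config)

    for train_site in site_names:
        test_site = next(s for s in site_names if s != train_site)
        letter = direction_letter[train_site]
        log.info("direction %s -> %s", train_site, test_site)

        if config.strict_split:
            train_ids = [s for s, st in zip(subject_ids, sites) if st == train_site]
            mask = build_mask([smoothed[s] for s in train_ids], threshold=config.mask_threshold)
            feats = assemble_features(smoothed, mask, subject_ids)
            feats = _residualize_strict(feats, participants, sites, train_site, config)

        tr = np.flatnonzero(sites == train_site)
        te = np.flatnonzero(sites == test_site)
        assert not set(np.asarray(subject_ids)[tr]) & set(np.asarray(subject_ids)[te])
        X_tr, y_tr = feats.X[tr], y_all[tr]
        X_te, y_te = feats.X[te], y_all[te]

        grid = config.c_grid if config.c_grid is not None else svm_mod.default_c_grid()
        C_best, cv_acc = svm_mod.select_C(
            X_tr, y_tr, grid=grid, k=config.folds, seed=seeds[f"cv_{letter}"]
        )
        log.info("selected C=%g (cv accuracy %.3f)", C_best, cv_acc.max())
        cv_obs, cv_p = svm_mod.permutation_test_cv_accuracy(
            X_tr, y_tr, C_best, k=config.folds,
            B=config.b_performance, seed=seeds[f"perf_{letter}"],
        )
        model = svm_mod.LinearSVM(C=C_best).fit(X_tr, y_tr)
        report = svm_mod.permutation_test_performance(
            X_tr, y_tr, X_te, y_te, C=C_best,
            B=config.b_performance, seed=seeds[f"perf_{letter}"],
        )
        perf_rows.append(
            {"model": train_site, "phase": "cv", "accuracy": cv_obs, "p_accuracy": cv_p, "C": C_best}
        )
        perf_rows.append(
            {"model": train_site, "phase": f"test_{test_site}", "C": C_best, **report.to_dict()}
        )
        _save_model(model, feats, seeds, outdir / "models" / f"model_{train_site}")

        tallies = inf.weight_null(
            X_tr, y_tr, C=C_best, w_obs=model.coef_.ravel(),
            B=config.b_weights, seed=seeds[f"weights_{letter}"],
        )
        sig_map = inf.voxel_pvalues(tallies, sidedness=config.sidedness)
        save_volume(feats.row_to_volume(sig_map.p, fill=1.0),
                    outdir / "maps" / f"pmap_{train_site}.nii.gz")
        sig = inf.fdr_bh(sig_map.p, q=config.q)
        sig_vol = feats.row_to_volume(sig.astype(float))
        sig_vols[train_site] = sig_vol
        save_volume(sig_vol, outdir / "maps" / f"sig_{train_site}.nii.gz", dtype=np.uint8)

        clusters = inf.extract_clusters(
            sig_vol, connectivity=config.connectivity, min_size=config.min_cluster_size
        )
        w_vol = feats.row_to_volume(model.coef_.ravel())
        ctable = inf.cluster_table(clusters, w_vol)
        ctable.to_csv(outdir / "tables" / f"clusters_{train_site}.tsv", sep="\t", index=False)
        label_vol = inf.clusters_to_label_volume(clusters, feats.shape, feats.affine)
        save_volume(label_vol, outdir / "maps" / f"clusters_{train_site}.nii.gz", dtype=np.int16)
        log.info("%d clusters above extent threshold", len(clusters))

        if clusters:
            pat_rows = np.flatnonzero((sites == train_site) & (y_all == svm_mod.PATIENT))
            pat_ids = [subject_ids[i] for i in pat_rows]
            pat_vols = {subject_ids[i]: feats.row_to_volume(i) for i in pat_rows}
            roi_means = clin.roi_mean_gm(pat_vols, label_vol, subject_ids=pat_ids)
            corr = clin.correlate_rois_clinical(
                roi_means, participants[participants["subject_id"].isin(pat_ids)], q=config.q
            )
            corr.to_csv(outdir / "tables" / f"clinical_{train_site}.tsv", sep="\t", index=False)
            if roi_means.shape[1] >= 2:
                clin.roi_roi_correlation(roi_means).to_csv(
                    outdir / "tables" / f"roi_roi_{train_site}.tsv", sep="\t"
                )

    if len(sig_vols) == 2:
        overlap = inf.overlap_map(*sig_vols.values())
        save_volume(overlap, outdir / "maps" / "overlap.nii.gz", dtype=np.uint8)

    perf = pd.DataFrame(perf_rows)
    perf.to_csv(outdir / "tables" / "performance.tsv", sep="\t", index=False)

    manifest = {
        "config": config.to_dict(),
        "seeds": seeds,
        "artifacts": _hash_tree(outdir, exclude=("logs", "manifest.json")),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run complete: %s", outdir)
    return manifest


def _mask_volume(mask):
    from .volume import VolumeGrid

    return VolumeGrid(mask.mask.astype(np.float64), mask.affine)


def _residualize_all(feats, participants, sites, config) -> FeatureMatrix:
    from .preprocess import residualize

    return residualize(
        feats, participants[list(config.covariates)], sites, covariates=config.covariates
    )


def _residualize_strict(feats, participants, sites, train_site, config) -> FeatureMatrix:
    """Fit nuisance regression on the training site only; apply to both."""
    res = SiteResidualizer(covariates=config.covariates)
    tr = np.flatnonzero(sites == train_site)
    cov = participants[list(config.covariates)]
    res.fit(feats.X[tr], covariate_table=cov.iloc[tr], sites=np.array(["fit"] * len(tr)))
    Xr = res.transform(
        feats.X, covariate_table=cov, sites=np.array(["fit"] * len(sites))
    )
    prov = dict(feats.provenance)
    prov["residualized_covariates"] = list(config.covariates)
    prov["strict_split_train_site"] = str(train_site)
    return FeatureMatrix(
        X=Xr, subject_ids=feats.subject_ids, voxel_ijk=feats.voxel_ijk,
        affine=feats.affine, shape=feats.shape, provenance=prov,
    )


def _save_model(model, feats: FeatureMatrix, seeds: dict, prefix: Path) -> None:
    np.save(str(prefix) + "_w.npy", model.coef_.ravel())
    voxel_hash = hashlib.sha256(feats.voxel_ijk.tobytes()).hexdigest()[:16]
    meta = {
        "b": float(model.intercept_[0]),
        "C": float(model.C),
        "label_convention": {"patient": -1, "control": 1},
        "voxel_map_hash": voxel_hash,
        "n_support": int(len(model.support_)),
        "seeds": seeds,
    }
    Path(str(prefix) + ".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _hash_tree(outdir: Path, exclude: tuple[str, ...]) -> dict[str, str]:
    out = {}
    for path in sorted(outdir.rglob("*")):
        rel = path.relative_to(outdir)
        if not path.is_file() or rel.parts[0] in exclude or str(rel) in exclude:
            continue
        out[str(rel)] = hashlib.sha256(path.read_bytes()).hexdigest()
    return out


def _setup_logging(logfile: Path) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        log.addHandler(sh)
    for h in [h for h in log.handlers if isinstance(h, logging.FileHandler)]:
        log.removeHandler(h)
        h.close()
    fh = logging.FileHandler(logfile)
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
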