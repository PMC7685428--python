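"""Two-site synthetic gray-matter cohorts with known ground truth.

Generates per-subject GM-density volumes plus a participants table with the
statistical structure the downstream analysis assumes:

* two acquisition sites with different cohort sizes, age distributions and
  scanner effects (a site-wide intensity offset and extra scanner noise),
* age- and sex-related GM variation,
* disease-linked GM reduction in configurable ellipsoidal regions, scaled so
  the within-site patient-vs-control difference at the region core has a
  prescribed Cohen's d,
* optional coupling between regional GM and a patient clinical score with a
  prescribed population Spearman correlation,
* spatially autocorrelated noise (white noise smoothed at the generator's
  intrinsic FWHM), so permutation inference sees realistic smoothness.

Everything is deterministic given the spec's seed, and the ground-truth
voxel mask of all effect regions is returned for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, zoom
from .volume import VolumeGrid, save_volume

__all__ = [
    "ClinicalDistributions",
    "SiteSpec",
    "EffectRegion",
    "CohortSpec",
    "Cohort",
    "generate_template",
    "generate_cohort",
    "write_cohort",
    "default_two_site_spec",
]

#: clinical variables measured only in the patient group
PATIENT_ONLY_VARIABLES = (
    "PANSS_total",
    "PANSS_positive",
    "PANSS_negative",
    "onset_age",
    "duration",
    "CPZ_mg",
)


@dataclass
class ClinicalDistributions:
    """(mean, SD) of each clinical variable for one site's patient group.

    JART (premorbid-IQ estimate) is also measured in controls, so a control
    mean/SD pair is carried separately.
    """

    panss_positive: tuple[float, float] = (16.0, 6.3)
    panss_negative: tuple[float, float] = (16.9, 6.8)
    panss_total: tuple[float, float] = (67.3, 23.5)
    onset_age: tuple[float, float] = (24.1, 6.4)
    cpz_mg: tuple[float, float] = (584.4, 406.6)
    jart_patients: tuple[float, float] = (98.9, 10.2)
    jart_controls: tuple[float, float] = (108.0, 6.4)


@dataclass
class SiteSpec:
    """One acquisition site: cohort sizes, ages and scanner effects."""

    name: str
    n_patients: int
    n_controls: int
    age_mean: float
    age_sd: float
    site_intensity_shift: float = 0.0
    site_noise_sd: float = 0.0
    clinical: ClinicalDistributions = field(default_factory=ClinicalDistributions)

    def validate(self) -> None:
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError(f"site {self.name!r}: cohort sizes must be >= 0")
        if self.age_sd < 0 or self.site_noise_sd < 0:
            raise ValueError(f"site {self.name!r}: SDs must be >= 0")


@dataclass
class EffectRegion:
    """Ellipsoidal disease-effect region in world (mm) coordinates.

    ``effect_d >= 0`` means patients have LOWER gray-matter density at the
    region core; the reduction is scaled per site so that the within-group
    Cohen's d at the core equals ``effect_d``. ``clinical_link`` optionally
    couples the region's mean GM (patients) to a clinical variable at a
    target Spearman correlation.
    """

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    effect_d: float = 0.0
    clinical_link: tuple[str, float] | None = None

    def validate(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("effect-region radii must be positive")
        if self.effect_d < 0:
            raise ValueError("effect_d must be >= 0 (sign convention: patients lower)")
        if self.clinical_link is not None:
            var, rho = self.clinical_link
            if not abs(rho) < 1:
                raise ValueError(f"clinical_link target |rho| must be < 1, got {rho}")
            if var not in PATIENT_ONLY_VARIABLES and var != "JART":
                raise ValueError(f"unknown clinical_link variable {var!r}")


@dataclass
class CohortSpec:
    """Full parameterization of a synthetic two-site study."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 4.0
    sites: list[SiteSpec] = field(default_factory=list)
    age_slope: float = -0.002
    sex_effect: float = 0.01
    subject_noise_sd: float = 0.08
    smoothness_mm: float = 8.0
    effect_regions: list[EffectRegion] = field(default_factory=list)
    background: float = 0.05
    interior_range: tuple[float, float] = (0.3, 0.8)
    seed: int = 0

    def validate(self) -> None:
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("grid_shape must be >= 8 voxels along every axis")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be >= 0")
        if self.smoothness_mm < 0:
            raise ValueError("smoothness_mm must be >= 0")
        if not self.sites:
            raise ValueError("at least one site is required")
        for s in self.sites:
            s.validate()
        for r in self.effect_regions:
            r.validate()

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_two_site_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The default two-site study design.

    Sites mirror a two-scanner schizophrenia case-control design: 50/51
    subjects aged 38.8+-6.9 / 36.5+-7.1 years at the first site and 49/48
    subjects aged 28.1+-5.0 / 26.9+-3.3 years at the second, with
    site-specific clinical-score distributions. Two ellipsoidal GM-reduction
    regions (Cohen's d = 1.2 at core) stand in for the unknown disease
    effect; the second region's GM is negatively coupled to antipsychotic
    dose (Spearman rho = -0.35).
    """
    site1 = SiteSpec(
        name="site1",
        n_patients=50,
        n_controls=51,
        age_mean=38.8,
        age_sd=6.9,
        site_intensity_shift=0.001,
        site_noise_sd=0.02,
        clinical=ClinicalDistributions(),
    )
    site2 = SiteSpec(
        name="site2",
        n_patients=49,
        n_controls=48,
        age_mean=28.1,
        age_sd=5.0,
        site_intensity_shift=-0.001,
        site_noise_sd=0.03,
        clinical=ClinicalDistributions(
            panss_positive=(13.4, 5.8),
            panss_negative=(18.2, 7.9),
            panss_total=(64.6, 21.3),
            onset_age=(22.5, 5.1),
            cpz_mg=(441.9, 416.7),
            jart_patients=(101.6, 10.2),
            jart_controls=(111.0, 5.9),
        ),
    )
    spec = CohortSpec(sites=[site1, site2], seed=seed)
    for key, val in overrides.items():
        if not hasattr(spec, key):
            raise TypeError(f"unknown CohortSpec field {key!r}")
        setattr(spec, key, val)
    if "effect_regions" not in overrides:
        # default effect regions: fixed anatomical (mm) radii, placed
        # off-center inside the brain support relative to the lattice extent
        extent = np.asarray(spec.grid_shape) * spec.voxel_size_mm
        spec.effect_regions = [
            EffectRegion(
                center_mm=tuple(float(c) for c in extent * (0.38, 0.42, 0.55)),
                radii_mm=(16.0, 16.0, 16.0),
                effect_d=1.2,
            ),
            EffectRegion(
                center_mm=tuple(float(c) for c in extent * (0.62, 0.58, 0.42)),
                radii_mm=(14.0, 14.0, 14.0),
                effect_d=1.2,
                clinical_link=("CPZ_mg", -0.35),
            ),
        ]
    return spec


@dataclass
class Cohort:
    """A generated study: participants table, volumes, and ground truth."""

    spec: CohortSpec
    participants: pd.DataFrame
    volumes: dict[str, VolumeGrid]
    truth_mask: VolumeGrid

    @property
    def subject_ids(self) -> list[str]:
        return list(self.participants["subject_id"])


# ---------------------------------------------------------------------------
# template


def generate_template(spec: CohortSpec) -> VolumeGrid:
    """Smooth seed-dependent baseline GM map.

    An ellipsoidal "brain" support (semi-axes 0.42 of the lattice extent)
    carries a base density of 0.55 modulated by a low-frequency random field
    (white noise on a coarse 4x4x4 lattice, cubic-upsampled), tapered to the
    background level at the support edge. Interior values stay within
    ``spec.interior_range`` so the 0.2 mask threshold cleanly separates
    brain from background.
    """
    spec.validate()
    shape = spec.grid_shape
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7E]))
    # low-frequency bump field
    coarse = rng.normal(size=(4, 4, 4))
    factors = [s / 4 for s in shape]
    bumps = zoom(coarse, factors, order=3, mode="nearest")
    bumps = bumps / max(np.abs(bumps).max(), 1e-12) * 0.12

    taper = _support_profile(spec)
    lo, hi = spec.interior_range
    base = 0.5 * (lo + hi) + bumps * (hi - lo)
    values = spec.background + (base - spec.background) * taper
    values = np.clip(values, 0.0, 1.0)
    return VolumeGrid(values=values, affine=spec.affine)


def _cos_taper(r: np.ndarray, r0: float, r1: float) -> np.ndarray:
    """1 inside r0, raised-cosine falloff to 0 at r1, 0 outside."""
    t = np.clip((r - r0) / (r1 - r0), 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def _support_profile(spec: CohortSpec) -> np.ndarray:
    """Ellipsoidal brain support: 1 in the interior, tapering to 0 outside."""
    shape = spec.grid_shape
    idx = np.indices(shape, dtype=np.float64)
    center = (np.asarray(shape, dtype=np.float64) - 1) / 2
    semi = np.asarray(shape, dtype=np.float64) * 0.42
    u = (idx - center.reshape(3, 1, 1, 1)) / semi.reshape(3, 1, 1, 1)
    r = np.sqrt((u**2).sum(axis=0))
    return _cos_taper(r, r0=0.75, r1=1.0)


def region_profile(spec: CohortSpec, region: EffectRegion) -> np.ndarray:
    """Smooth spatial profile of one effect region, 1 at center, 0 outside."""
    idx = np.indices(spec.grid_shape, dtype=np.float64)
    aff = spec.affine
    world = np.einsum("ab,b...->a...", aff[:3, :3], idx) + aff[:3, 3].reshape(3, 1, 1, 1)
    u = (world - np.reshape(region.center_mm, (3, 1, 1, 1))) / np.reshape(
        region.radii_mm, (3, 1, 1, 1)
    )
    r = np.sqrt((u**2).sum(axis=0))
    return np.where(r < 1.0, np.cos(np.pi * np.clip(r, 0, 1) / 2.0) ** 2, 0.0)


def _smooth_field(arr: np.ndarray, spec: CohortSpec) -> np.ndarray:
    """Plain Gaussian smoothing at the generator's intrinsic FWHM.

    Unlike the pipeline's mass-conserving smoother, no edge renormalization
    is applied here: renormalizing would inflate the noise SD at the lattice
    faces and cause spurious clipping against the [0, 1] density range.
    """
    if spec.smoothness_mm == 0:
        return arr
    sigma = spec.smoothness_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / spec.voxel_size_mm
    return gaussian_filter(arr, sigma=sigma, mode="constant", cval=0.0)


def _smoothing_gain(spec: CohortSpec) -> float:
    """||g||^2 of the generator's discrete smoothing operator.

    Smoothing white noise of SD s yields voxel SD s*sqrt(||g||^2); measured
    exactly by smoothing a unit impulse at the lattice center.
    """
    if spec.smoothness_mm == 0:
        return 1.0
    imp = np.zeros(spec.grid_shape)
    imp[tuple(s // 2 for s in spec.grid_shape)] = 1.0
    return float((_smooth_field(imp, spec) ** 2).sum())


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate participants, volumes and the ground-truth effect mask.

    Each subject volume is
    ``template + site_shift + age_slope*(age - site_age_mean)
    + sex_effect*(sex==M) - patient_effects + smoothed_noise``
    clipped to [0, 1]. The patient effect in each region is
    ``effect_d * sigma_within_site * profile``, where ``sigma_within_site``
    is the analytic within-group SD at the region core (smoothed noise plus
    age- and sex-related variance), so the realized Cohen's d at the core
    approximates ``effect_d`` per site.
    """
    spec.validate()
    template = generate_template(spec)
    support = _support_profile(spec)
    gain = _smoothing_gain(spec)
    profiles = [region_profile(spec, reg) for reg in spec.effect_regions]
    truth = np.zeros(spec.grid_shape, dtype=bool)
    for prof in profiles:
        truth |= prof > 0.5

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0]))
    rows: list[dict] = []
    volumes: dict[str, VolumeGrid] = {}
    region_gm: dict[int, list[float]] = {i: [] for i in range(len(profiles))}
    patient_row_idx: list[int] = []

    for site in spec.sites:
        noise_sd = float(np.hypot(spec.subject_noise_sd, site.site_noise_sd))
        sigma_within = np.sqrt(
            noise_sd**2 * gain
            + (spec.age_slope * site.age_sd) ** 2
            + spec.sex_effect**2 * 0.25
        )
        amps = [reg.effect_d * sigma_within for reg in spec.effect_regions]
        n_total = site.n_patients + site.n_controls
        diagnoses = ["patient"] * site.n_patients + ["control"] * site.n_controls
        for k in range(n_total):
            diagnosis = diagnoses[k]
            sid = f"{site.name}_{'p' if diagnosis == 'patient' else 'c'}{k:03d}"
            age = float(np.clip(rng.normal(site.age_mean, site.age_sd), 18.0, 70.0))
            sex = "M" if rng.integers(0, 2) == 1 else "F"
            # site/age/sex offsets modulate brain tissue only, not background
            vol = template.values.copy()
            offset = (
                site.site_intensity_shift
                + spec.age_slope * (age - site.age_mean)
                + spec.sex_effect * (1.0 if sex == "M" else 0.0)
            )
            vol += offset * support
            if diagnosis == "patient":
                for amp, prof in zip(amps, profiles):
                    vol -= amp * prof
            noise = _smooth_field(rng.normal(0.0, 1.0, size=spec.grid_shape) * noise_sd, spec)
            vol = np.clip(vol + noise, 0.0, 1.0)
            volumes[sid] = VolumeGrid(values=vol, affine=spec.affine)
            if diagnosis == "patient":
                patient_row_idx.append(len(rows))
                for i, prof in enumerate(profiles):
                    m = prof > 0.5
                    region_gm[i].append(float(vol[m].mean()) if m.any() else np.nan)
            rows.append(
                {
                    "subject_id": sid,
                    "site": site.name,
                    "diagnosis": diagnosis,
                    "age": round(age, 1),
                    "sex": sex,
                    "seed": spec.seed,
                }
            )

    participants = pd.DataFrame(rows)
    _draw_clinical(spec, participants, rng, region_gm, patient_row_idx)
    return Cohort(
        spec=spec,
        participants=participants,
        volumes=volumes,
        truth_mask=VolumeGrid(truth.astype(np.float64), spec.affine),
    )


def _draw_clinical(
    spec: CohortSpec,
    participants: pd.DataFrame,
    rng: np.random.Generator,
    region_gm: dict[int, list[float]],
    patient_row_idx: list[int],
) -> None:
    """Fill clinical columns in place; controls get NaN for patient-only ones."""
    for col in PATIENT_ONLY_VARIABLES + ("JART",):
        participants[col] = np.nan

    linked: dict[str, tuple[int, float]] = {}
    for i, reg in enumerate(spec.effect_regions):
        if reg.clinical_link is not None:
            var, rho = reg.clinical_link
            if var in linked:
                raise ValueError(f"multiple regions link the same variable {var!r}")
            linked[var] = (i, rho)

    # latent standardized scores per linked variable, per site's patients
    site_of = participants["site"].to_numpy()
    is_patient = (participants["diagnosis"] == "patient").to_numpy()

    for site in spec.sites:
        pmask = (site_of == site.name) & is_patient
        pidx = np.flatnonzero(pmask)
        n_pat = len(pidx)
        cmask = (site_of == site.name) & ~is_patient
        cidx = np.flatnonzero(cmask)
        cl = site.clinical

        def latent(var: str, n: int, local_rows: np.ndarray) -> np.ndarray:
            """Standardized latent score; correlated with regional GM if linked."""
            eps = rng.normal(size=n)
            if var not in linked:
                return eps
            region_i, rho_t = linked[var]
            g = np.asarray(region_gm[region_i])[local_rows]
            g_sd = g.std()
            if not np.isfinite(g_sd) or g_sd < 1e-12:
                raise RuntimeError(
                    f"clinical_link on region {region_i} unattainable: regional GM "
                    f"has no variance at site {site.name!r} (target rho={rho_t})"
                )
            z = (g - g.mean()) / g_sd
            r = 2.0 * np.sin(np.pi * rho_t / 6.0)  # Pearson for target Spearman
            return r * z + np.sqrt(1.0 - r**2) * eps

        # local row positions of this site's patients among all patients
        local = np.asarray([patient_row_idx.index(i) for i in pidx], dtype=int)

        ages = participants.loc[pidx, "age"].to_numpy(dtype=float)
        pos = np.clip(
            cl.panss_positive[0] + cl.panss_positive[1] * latent("PANSS_positive", n_pat, local),
            7, 49,
        ).round()
        neg = np.clip(
            cl.panss_negative[0] + cl.panss_negative[1] * latent("PANSS_negative", n_pat, local),
            7, 49,
        ).round()
        gen_mean = cl.panss_total[0] - cl.panss_positive[0] - cl.panss_negative[0]
        gen_sd = np.sqrt(
            max(cl.panss_total[1] ** 2 - cl.panss_positive[1] ** 2 - cl.panss_negative[1] ** 2, 25.0)
        )
        if "PANSS_total" in linked:
            total = cl.panss_total[0] + cl.panss_total[1] * latent("PANSS_total", n_pat, local)
            total = np.maximum(total.round(), pos + neg + 16)
        else:
            general = np.clip(gen_mean + gen_sd * rng.normal(size=n_pat), 16, 112).round()
            total = pos + neg + general
        onset = np.clip(
            cl.onset_age[0] + cl.onset_age[1] * latent("onset_age", n_pat, local),
            15.0,
            ages - 0.5,
        ).round(1)
        if "duration" in linked:
            dur_mean = site.age_mean - cl.onset_age[0]
            dur = np.clip(
                dur_mean + cl.onset_age[1] * latent("duration", n_pat, local), 0.5, ages - 15.0
            ).round(1)
            onset = (ages - dur).round(1)
        duration = (ages - onset).round(1)
        cpz = np.clip(
            cl.cpz_mg[0] + cl.cpz_mg[1] * latent("CPZ_mg", n_pat, local), 0.0, None
        ).round(1)
        jart_p = np.clip(
            cl.jart_patients[0] + cl.jart_patients[1] * latent("JART", n_pat, local), 60, 135
        ).round(1)

        participants.loc[pidx, "PANSS_positive"] = pos
        participants.loc[pidx, "PANSS_negative"] = neg
        participants.loc[pidx, "PANSS_total"] = total
        participants.loc[pidx, "onset_age"] = onset
        participants.loc[pidx, "duration"] = duration
        participants.loc[pidx, "CPZ_mg"] = cpz
        participants.loc[pidx, "JART"] = jart_p
        participants.loc[cidx, "JART"] = np.clip(
            cl.jart_controls[0] + cl.jart_controls[1] * rng.normal(size=len(cidx)), 60, 135
        ).round(1)


# ---------------------------------------------------------------------------
# persistence


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write NIfTI volumes, participants.tsv, truth mask and a spec sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, vol in cohort.volumes.items():
        save_volume(vol, outdir / f"{sid}.nii.gz")
    cohort.participants.to_csv(outdir / "participants.tsv", sep="\t", index=False)
    save_volume(cohort.truth_mask, outdir / "truth_mask.nii.gz", dtype=np.uint8)
    (outdir / "cohort_spec.json").write_text(json.dumps(cohort.spec.to_dict(), indent=2))
    return outdir


def load_cohort(indir: str | Path) -> Cohort:
    """Load a cohort previously written with :func:`write_cohort`."""
    from .volume import load_volume

    indir = Path(indir)
    raw = json.loads((indir / "cohort_spec.json").read_text())
    spec = _spec_from_dict(raw)
    participants = pd.read_csv(indir / "participants.tsv", sep="\t")
    volumes = {
        sid: load_volume(indir / f"{sid}.nii.gz") for sid in participants["subject_id"]
    }
    truth = load_volume(indir / "truth_mask.nii.gz")
    return Cohort(spec=spec, participants=participants, volumes=volumes, truth_mask=truth)


def _spec_from_dict(d: dict) -> CohortSpec:
    sites = [
        SiteSpec(
            **{**s, "clinical": ClinicalDistributions(
                **{k: tuple(v) for k, v in s["clinical"].items()}
            )}
        )
        for s in d["sites"]
    ]
    regions = [
        EffectRegion(
            center_mm=tuple(r["center_mm"]),
            radii_mm=tuple(r["radii_mm"]),
            effect_d=r["effect_d"],
            clinical_link=tuple(r["clinical_link"]) if r["clinical_link"] else None,
        )
        for r in d["effect_regions"]
    ]
    return CohortSpec(
        grid_shape=tuple(d["grid_shape"]),
        voxel_size_mm=d["voxel_size_mm"],
        sites=sites,
        age_slope=d["age_slope"],
        sex_effect=d["sex_effect"],
        subject_noise_sd=d["subject_noise_sd"],
        smoothness_mm=d["smoothness_mm"],
        effect_regions=regions,
        background=d["background"],
        interior_range=tuple(d["interior_range"]),
        seed=d["seed"],
    )
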