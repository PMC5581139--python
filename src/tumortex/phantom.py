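"""Synthetic contrast-enhanced tumor phantoms and clinical covariates.

The generator emulates the study material the pipeline is designed for:
a cohort of peripheral lung adenocarcinomas on contrast-enhanced CT with
a binary tumor segmentation, plus per-patient clinical covariates (age,
sex, smoking, stage, histologic subtype) in two pathologic-grade groups.

Each phantom is a connected, roughly ellipsoidal blob of "enhancing"
tissue on an air background (−1000 HU).  Its intensity field is the sum
of two zero-mean Gaussian components on top of the base enhancement:

* a *structural* field with a several-mm correlation length and fixed
  amplitude, mimicking the coarse vascular enhancement pattern, and
* a *fine texture* field at near-voxel scale whose standard deviation is
  ``noise_sd`` times ``heterogeneity_contrast`` in the high-grade class.

Because gray-level discretization is equal-width over each tumor's own
HU range, scaling a single field changes no texture feature; what makes
a tumor *textured* after quantization is the amplitude of its fine-scale
component relative to the coarse one.  The contrast knob therefore acts
on the fine component only, which monotonically lowers GLCM Homogeneity
in the high-grade class — the designed, recoverable group difference.

Intensities are rounded to integer HU, as CT images are.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .volume_io import VolumeWithMask

AIR_HU = -1000.0

#: histologic subtype frequencies within each grade group (cohort-like)
SUBTYPE_FREQS = {
    "intermediate": {"acinar": 65, "lepidic": 36, "papillary": 12},
    "high": {"solid": 27, "micropapillary": 6, "invasive mucinous": 2},
}

# radius perturbation amplitude at lumpiness = 1 (fraction of the radius)
_LUMP_AMPLITUDE = 0.12


@dataclass
class PhantomSpec:
    """Parameters of a two-grade synthetic cohort.

    Defaults mirror a 148-patient adenocarcinoma cohort: 113 intermediate
    + 35 high grade, tumors around 30 mm, enhancing to ~60 HU, with
    never-smoker fractions 68/113 and 13/35 per class.
    """

    n_intermediate: int = 113
    n_high: int = 35
    mean_diameter: float = 30.0  # mm
    diameter_sd: float = 8.0  # mm
    base_enhancement: float = 60.0  # HU
    structure_sd: float = 40.0  # HU, coarse enhancement pattern
    noise_sd: float = 15.0  # HU, fine texture (intermediate grade)
    correlation_length: float = 4.0  # mm, structural field
    texture_correlation_length: float = 1.0  # mm, fine field
    heterogeneity_contrast: float = 2.0  # multiplies high-grade noise_sd
    patient_sd_dispersion: float = 0.2  # lognormal sigma on per-patient SDs
    lumpiness: float = 0.3
    smoking_never_prob: dict = field(
        default_factory=lambda: {"intermediate": 68 / 113, "high": 13 / 35}
    )
    smoking_exact_counts: bool = False  # reproduce the expected 2x2 exactly
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_intermediate < 1 or self.n_high < 1:
            raise ParameterError("class sizes must be >= 1")
        for name in ("diameter_sd", "structure_sd", "noise_sd", "patient_sd_dispersion"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for g, p in self.smoking_never_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"smoking_never_prob[{g}] must be in [0,1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ClinicalRecord:
    patient_id: str
    age: int
    sex: str  # "male" / "female"
    smoking: str  # "never" / "smoker"
    stage: str  # "I".."IV"
    subtype: str
    grade: str  # "intermediate" / "high"


def _grid_for_diameter(diameter: float, spacing, margin_vox: int = 5):
    shape = tuple(int(np.ceil(diameter / s)) + 2 * margin_vox for s in spacing)
    center = tuple((n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    return shape, center


def _radial_field(shape, spacing, center) -> np.ndarray:
    axes = [
        (np.arange(n) * s - c) for n, s, c in zip(shape, spacing, center)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(zz**2 + yy**2 + xx**2)


def _smooth_unit_field(shape, spacing, correlation_length, rng) -> np.ndarray:
    """White noise, optionally Gaussian-smoothed, rescaled to unit SD."""
    f = rng.standard_normal(shape)
    if correlation_length > 0:
        sigma_vox = [correlation_length / s for s in spacing]
        f = ndimage.gaussian_filter(f, sigma=sigma_vox, mode="reflect")
    sd = f.std()
    if sd > 0:
        f = f / sd
    return f


def generate_mask(
    diameter: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    lumpiness: float = 0.0,
    seed: int = 0,
) -> VolumeWithMask:
    """Generate a connected, approximately ellipsoidal binary tumor mask.

    ``lumpiness`` in [0, 1] perturbs the blob boundary with a smooth
    random radial field; 0 yields a digital sphere.  The maximum 3D
    caliper diameter stays within ~15% of the request.  Intensities of
    the returned volume are all air; callers paint them afterwards.
    """
    if not 0.0 <= lumpiness <= 1.0:
        raise ParameterError("lumpiness must be in [0,1]")
    if diameter <= 2 * max(spacing):
        raise ParameterError(
            f"diameter {diameter} mm too small for voxel spacing {spacing}"
        )
    shape, center = _grid_for_diameter(diameter, spacing)
    r = _radial_field(shape, spacing, center)
    radius = diameter / 2.0
    rho = r / radius
    if lumpiness > 0:
        rng = np.random.default_rng(seed)
        g = _smooth_unit_field(shape, spacing, correlation_length=radius / 2, rng=rng)
        # clip so the worst-case radial inflation (amplitude x clip) stays
        # below 15%, keeping the caliper-diameter contract by construction
        np.clip(g, -1.2, 1.2, out=g)
        mask = rho <= 1.0 + _LUMP_AMPLITUDE * lumpiness * g
    else:
        mask = rho <= 1.0
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n > 1:  # keep the component containing (or nearest) the center
        counts = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(counts)) + 1)
    intensities = np.full(shape, AIR_HU, dtype=np.float64)
    return VolumeWithMask(intensities, spacing, (0.0, 0.0, 0.0), mask)


def generate_intensity(
    mask_volume: VolumeWithMask,
    base: float,
    noise_sd: float,
    correlation_length: float,
    seed: int = 0,
) -> VolumeWithMask:
    """Paint a spatially correlated enhancement field into the ROI.

    ROI intensities are ``base`` plus a zero-mean Gaussian field
    (Gaussian-kernel-smoothed white noise, smoothing sigma =
    ``correlation_length`` mm; 0 means unsmoothed) rescaled so the ROI
    standard deviation equals ``noise_sd``, then rounded to integer HU.
    Background is air (−1000 HU).
    """
    mask_volume.require_roi()
    mask = mask_volume.mask
    spacing = mask_volume.spacing
    intensities = np.full(mask.shape, AIR_HU, dtype=np.float64)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = _smooth_unit_field(mask.shape, spacing, correlation_length, rng)
        roi_sd = f[mask].std()
        roi_mean = f[mask].mean()
        f = (f - roi_mean) / roi_sd * noise_sd
        intensities[mask] = np.round(base + f[mask])
    else:
        intensities[mask] = np.round(base)
    return VolumeWithMask(intensities, spacing, mask_volume.origin, mask)


def _compose_intensity(
    mask_volume: VolumeWithMask,
    base: float,
    structure_sd: float,
    correlation_length: float,
    texture_sd: float,
    texture_correlation_length: float,
    rng: np.random.Generator,
) -> VolumeWithMask:
    """ROI = base + coarse structural field + fine texture field."""
    mask = mask_volume.mask
    spacing = mask_volume.spacing
    total = np.zeros(mask.shape)
    for sd, cl in (
        (structure_sd, correlation_length),
        (texture_sd, texture_correlation_length),
    ):
        if sd <= 0:
            continue
        f = _smooth_unit_field(mask.shape, spacing, cl, rng)
        roi = f[mask]
        total += (f - roi.mean()) / roi.std() * sd
    intensities = np.full(mask.shape, AIR_HU, dtype=np.float64)
    intensities[mask] = np.round(base + total[mask])
    return VolumeWithMask(intensities, spacing, mask_volume.origin, mask)


def _n_never(spec: PhantomSpec, grade: str, n: int, rng) -> np.ndarray:
    """Boolean never-smoker assignment for one class."""
    p = spec.smoking_never_prob[grade]
    if spec.smoking_exact_counts:
        k = int(round(p * n))
        flags = np.zeros(n, dtype=bool)
        flags[:k] = True
        return flags
    return rng.random(n) < p


def _sample_clinical(spec: PhantomSpec, grade: str, idx: int, rng) -> dict:
    freqs = SUBTYPE_FREQS[grade]
    names = list(freqs)
    probs = np.array(list(freqs.values()), dtype=float)
    probs /= probs.sum()
    subtype = names[rng.choice(len(names), p=probs)]
    # age / sex / stage distributions loosely follow the cohort table
    age_mu = 58.0 if grade == "intermediate" else 59.5
    age = int(np.clip(np.round(rng.normal(age_mu, 9.0)), 30, 80))
    p_female = 71 / 113 if grade == "intermediate" else 16 / 35
    sex = "female" if rng.random() < p_female else "male"
    p_early = 77 / 113 if grade == "intermediate" else 23 / 35
    if rng.random() < p_early:
        stage = "I" if rng.random() < 86 / 100 else "II"
    else:
        stage = "III" if rng.random() < 40 / 48 else "IV"
    return {"age": age, "sex": sex, "stage": stage, "subtype": subtype}


def generate_cohort(spec: PhantomSpec) -> list[tuple[VolumeWithMask, ClinicalRecord]]:
    """Generate the full two-grade phantom cohort.

    Deterministic: an identical spec (including seed) yields bit-identical
    volumes, masks and records.  High-grade phantoms use fine-texture SD
    ``noise_sd × heterogeneity_contrast``; per-patient SDs additionally
    carry lognormal biological dispersion.
    """
    root = np.random.SeedSequence(spec.seed)
    out: list[tuple[VolumeWithMask, ClinicalRecord]] = []
    plan = [("intermediate", spec.n_intermediate), ("high", spec.n_high)]
    child_seeds = root.spawn(sum(n for _, n in plan) + len(plan))
    smoke_rngs = {
        g: np.random.default_rng(child_seeds[-(i + 1)]) for i, (g, _) in enumerate(plan)
    }
    k = 0
    for grade, n in plan:
        never_flags = _n_never(spec, grade, n, smoke_rngs[grade])
        for i in range(n):
            rng = np.random.default_rng(child_seeds[k])
            k += 1
            diameter = float(
                np.clip(
                    rng.normal(spec.mean_diameter, spec.diameter_sd),
                    2.5 * max(spec.spacing) + 2.0,
                    70.0,
                )
            )
            mask_vol = generate_mask(
                diameter,
                spacing=spec.spacing,
                lumpiness=spec.lumpiness,
                seed=int(rng.integers(2**31)),
            )
            disp = spec.patient_sd_dispersion
            s_struct = spec.structure_sd * float(np.exp(rng.normal(0, disp)))
            s_tex = spec.noise_sd * float(np.exp(rng.normal(0, disp)))
            if grade == "high":
                s_tex *= spec.heterogeneity_contrast
            vol = _compose_intensity(
                mask_vol,
                spec.base_enhancement,
                s_struct,
                spec.correlation_length,
                s_tex,
                spec.texture_correlation_length,
                rng,
            )
            clin = _sample_clinical(spec, grade, i, rng)
            rec = ClinicalRecord(
                patient_id=f"{grade[:3]}-{i + 1:03d}",
                age=clin["age"],
                sex=clin["sex"],
                smoking="never" if never_flags[i] else "smoker",
                stage=clin["stage"],
                subtype=clin["subtype"],
                grade=grade,
            )
            out.append((vol, rec))
    return out
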