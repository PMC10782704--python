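"""Synthetic paired CT / pseudo-CT phantom cases with SRT-like dose.

Emulates the study conditions the pipeline is meant to evaluate: a head-like
phantom (soft tissue inside a bone shell inside air), 1-4 spherical lesions
of 0.5-27.3 cm^3, stereotactic prescriptions 1x(20-24) Gy / 3x7 Gy / 5x6 Gy
with the prescription at ~80% of the maximum dose, 1.25 mm isotropic dose
grids, and a pseudo-CT whose HU-mean sits slightly below the CT and whose
HU-min is raised by smoothing.  The pseudo-CT dose is a controlled
perturbation (global scale + sub-voxel rigid shift) of the CT dose so every
downstream comparison stage sees a realistic, known deviation structure.

Everything is fully deterministic under (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core_volumes import (
    Geometry,
    ImageVolume,
    RigidTransform,
    StructureMask,
    apply_rigid,
    structure_volume_cc,
    write_mask,
    write_volume,
)

__all__ = [
    "PhantomConfig",
    "PhantomCase",
    "PRESCRIPTION_SCHEMES",
    "generate_anatomy",
    "generate_pct",
    "generate_dose",
    "perturb_dose",
    "generate_case",
    "generate_cohort",
    "write_case",
]

#: allowed fractionation schemes: fractions -> allowed per-fraction dose (Gy)
PRESCRIPTION_SCHEMES = {
    1: (20.0, 24.0),  # single fraction, 20-24 Gy
    3: (7.0, 7.0),    # 3 x 7 Gy
    5: (6.0, 6.0),    # 5 x 6 Gy
}

_SOFT_TISSUE_HU = 40.0
_BONE_HU = 1000.0
_AIR_HU = -1000.0

#: prescription is ~80% of the maximum dose (SRT planning convention)
PRESCRIPTION_ISODOSE = 0.8


@dataclass
class PhantomConfig:
    """Knobs of the phantom generator; defaults are the emulated study
    conditions."""

    n_lesions: int = 1
    lesion_volumes_cc: tuple[float, ...] = (3.4,)
    fractions: int = 1
    prescription_Gy: float = 21.0
    hu_mean_offset: float = -8.0       # pCT minus CT, HU (negative: CT above pCT)
    hu_min_smoothing_sigma: float = 2.0  # mm, smoothed-floor width in the pCT
    noise_sd: float = 10.0             # HU, pCT additive noise
    ct_noise_sd: float = 8.0           # HU, CT texture noise inside the body
    dose_falloff_sigma: float = 3.0    # mm, Gaussian dose falloff outside PTV
    ptv_margin_mm: float = 2.0
    grid: Geometry = field(
        default_factory=lambda: Geometry((1.25, 1.25, 1.25), (0.0, 0.0, 0.0), (88, 88, 88))
    )
    # pseudo-CT dose perturbation profile ("image-type" analog labels A/B)
    dose_scale_sd: float = 0.004
    dose_shift_sd_mm: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_lesions <= 4:
            raise ValueError("n_lesions must be in [1, 4]")
        if len(self.lesion_volumes_cc) != self.n_lesions:
            raise ValueError("one lesion volume per lesion required")
        for v in self.lesion_volumes_cc:
            if not 0.5 <= v <= 27.3:
                raise ValueError(f"lesion volume {v} cc outside [0.5, 27.3]")
        if self.fractions not in PRESCRIPTION_SCHEMES:
            raise ValueError(f"fractions must be one of {sorted(PRESCRIPTION_SCHEMES)}")
        lo, hi = PRESCRIPTION_SCHEMES[self.fractions]
        per_fx = self.prescription_Gy / self.fractions
        if not lo - 1e-9 <= per_fx <= hi + 1e-9:
            raise ValueError(
                f"prescription {self.prescription_Gy} Gy in {self.fractions} fx "
                f"outside the allowed scheme ({lo}-{hi} Gy/fx)"
            )


@dataclass
class PhantomCase:
    """One paired case: CT, pseudo-CT, their dose grids, masks and manifest."""

    ct: ImageVolume
    pct: ImageVolume
    dose_ct: ImageVolume
    dose_pct: ImageVolume
    structures: dict[str, StructureMask]
    manifest: dict

    @property
    def ptv_masks(self) -> list[StructureMask]:
        return [m for r, m in self.structures.items() if r.startswith("PTV")]

    @property
    def gtv_masks(self) -> list[StructureMask]:
        return [m for r, m in self.structures.items() if r.startswith("GTV")]


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------

def _ellipsoid(geom: Geometry, centre_mm, semi_mm) -> np.ndarray:
    idx = np.indices(geom.shape, dtype=float)
    pos = [idx[a] * geom.spacing[a] + geom.origin[a] for a in range(3)]
    q = sum(((pos[a] - centre_mm[a]) / semi_mm[a]) ** 2 for a in range(3))
    return q <= 1.0


def _cylinder_z(geom: Geometry, centre_xy_mm, radius_mm, z_lo, z_hi) -> np.ndarray:
    idx = np.indices(geom.shape, dtype=float)
    x = idx[0] * geom.spacing[0] + geom.origin[0]
    y = idx[1] * geom.spacing[1] + geom.origin[1]
    z = idx[2] * geom.spacing[2] + geom.origin[2]
    r2 = (x - centre_xy_mm[0]) ** 2 + (y - centre_xy_mm[1]) ** 2
    return (r2 <= radius_mm**2) & (z >= z_lo) & (z <= z_hi)


def _sphere(geom: Geometry, centre_mm, radius_mm) -> np.ndarray:
    return _ellipsoid(geom, centre_mm, (radius_mm,) * 3)


def _dilate_mm(mask: np.ndarray, margin_mm: float, spacing) -> np.ndarray:
    """Isotropic dilation by Euclidean-distance-transform thresholding
    (spacing independent, unlike a structuring element)."""
    if margin_mm <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_mm


def generate_anatomy(config: PhantomConfig) -> tuple[dict[str, StructureMask], ImageVolume]:
    """Build the head-like phantom CT and all structure masks.

    Soft-tissue ellipsoid (~40 HU) within a bone shell (~1000 HU) within air
    (-1000 HU); OARs (brainstem/cord cylinders, lens/optic-nerve/chiasm
    ellipsoids) placed non-overlapping with the GTV spheres; PTV = GTV
    dilated isotropically by the configured margin.

    Raises ``ValueError`` when a requested lesion cannot be placed without
    overlap.
    """
    geom = config.grid
    rng = np.random.default_rng(config.seed)
    lo, hi = geom.extent_mm()
    centre = (lo + hi) / 2.0
    half = (hi - lo) / 2.0

    body_semi = tuple(0.92 * h for h in half)
    body = _ellipsoid(geom, centre, body_semi)
    inner = _ellipsoid(geom, centre, tuple(0.94 * s for s in body_semi))
    bone = body & ~inner
    brain = _ellipsoid(geom, centre, tuple(0.86 * s for s in body_semi))

    cx, cy, cz = centre
    z0 = lo[2]
    structures: dict[str, StructureMask] = {}

    def add(role: str, vox: np.ndarray) -> None:
        structures[role] = StructureMask(geom, vox, role)

    add("body", body)
    add("brain", brain)
    add("spinal_cord", _cylinder_z(geom, (cx, cy), 3.0, z0 + 10.0, z0 + 24.0) & inner)
    add("brainstem", _cylinder_z(geom, (cx, cy), 5.0, z0 + 24.0, z0 + 46.0) & inner)
    add("lens_L", _sphere(geom, (cx - 16.0, cy + 0.72 * body_semi[1], cz), 2.5))
    add("lens_R", _sphere(geom, (cx + 16.0, cy + 0.72 * body_semi[1], cz), 2.5))
    add("opt_nerve_L", _ellipsoid(geom, (cx - 11.0, cy + 0.48 * body_semi[1], cz), (2.0, 8.0, 2.0)))
    add("opt_nerve_R", _ellipsoid(geom, (cx + 11.0, cy + 0.48 * body_semi[1], cz), (2.0, 8.0, 2.0)))
    add("opt_chiasm", _ellipsoid(geom, (cx, cy + 0.24 * body_semi[1], cz), (6.0, 3.0, 2.5)))

    oar_union = np.zeros(geom.shape, dtype=bool)
    for role in ("spinal_cord", "brainstem", "lens_L", "lens_R",
                 "opt_nerve_L", "opt_nerve_R", "opt_chiasm"):
        oar_union |= structures[role].voxels

    # candidate lesion centres: deep enough inside the brain, clear of OARs
    brain_depth = ndimage.distance_transform_edt(brain, sampling=geom.spacing)
    oar_dist = ndimage.distance_transform_edt(~oar_union, sampling=geom.spacing)

    placed: list[tuple[np.ndarray, float]] = []
    clearance = 3.0  # mm between PTV and any OAR / other PTV
    for li, vol_cc in enumerate(config.lesion_volumes_cc):
        r_gtv = (3.0 * vol_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        r_ptv = r_gtv + config.ptv_margin_mm
        ok = (brain_depth >= r_ptv + 1.0) & (oar_dist >= r_ptv + clearance)
        for c, r in placed:
            idx = np.indices(geom.shape, dtype=float)
            pos = np.stack(
                [idx[a] * geom.spacing[a] + geom.origin[a] for a in range(3)], axis=-1
            )
            d = np.linalg.norm(pos - c, axis=-1)
            ok &= d >= r + r_ptv + clearance
        cand = np.argwhere(ok)
        if cand.size == 0:
            raise ValueError(
                f"lesion {li} of {vol_cc:.2f} cc not placeable without overlap"
            )
        pick = cand[rng.integers(len(cand))]
        c_mm = geom.indices_to_physical(pick.astype(float))
        placed.append((c_mm, r_ptv))
        gtv = _sphere(geom, c_mm, r_gtv)
        suffix = "" if config.n_lesions == 1 else f"_{li + 1}"
        add(f"GTV{suffix}", gtv)
        add(f"PTV{suffix}", _dilate_mm(gtv, config.ptv_margin_mm, geom.spacing))

    hu = np.full(geom.shape, _AIR_HU)
    hu[body] = _SOFT_TISSUE_HU
    hu[bone] = _BONE_HU
    if config.ct_noise_sd > 0:
        # low-frequency texture + fine noise, body only
        coarse = ndimage.gaussian_filter(rng.normal(0.0, 1.0, geom.shape), 4.0)
        coarse *= config.ct_noise_sd / max(coarse.std(), 1e-12)
        fine = rng.normal(0.0, 0.5 * config.ct_noise_sd, geom.shape)
        hu = np.where(body, hu + coarse + fine, hu)

    ct = ImageVolume(geom, hu, modality="CT")
    return structures, ct


# ---------------------------------------------------------------------------
# pseudo-CT
# ---------------------------------------------------------------------------

def generate_pct(ct: ImageVolume, config: PhantomConfig) -> ImageVolume:
    """Derive the pseudo-CT from the CT: a (negative) mean HU offset, a
    Gaussian-smoothed floor that raises the HU-min inside tissue, and
    additive noise.  The body outline is identical to the CT."""
    rng = np.random.default_rng(config.seed + 1)
    geom = ct.geometry
    body = ct.values > -500.0  # tissue + bone; air untouched
    vals = ct.values.copy()
    shifted = ct.values + config.hu_mean_offset
    if config.noise_sd > 0:
        shifted = shifted + rng.normal(0.0, config.noise_sd, geom.shape)
    if config.hu_min_smoothing_sigma > 0:
        sigma_vox = [config.hu_min_smoothing_sigma / s for s in geom.spacing]
        floor = ndimage.gaussian_filter(ct.values, sigma_vox) + config.hu_mean_offset
        shifted = np.maximum(shifted, floor)
    vals[body] = shifted[body]
    return ImageVolume(geom, vals, modality="pCT")


# ---------------------------------------------------------------------------
# dose
# ---------------------------------------------------------------------------

def _signed_distance_mm(mask: np.ndarray, spacing, smooth_vox: float = 1.0) -> np.ndarray:
    """Signed Euclidean distance to the mask surface: positive outside,
    negative inside.  Lightly smoothed so equidistant voxel shells do not
    collapse onto identical values (which would put atoms into the DVH)."""
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    t = outside - inside
    if smooth_vox > 0:
        t = ndimage.gaussian_filter(t, smooth_vox)
    return t


def generate_dose(
    ptv_masks: list[StructureMask],
    prescription_Gy: float,
    fractions: int,
    falloff_mm: float = 3.0,
    dose_geometry: Geometry | None = None,
    heterogeneity_sd: float = 0.01,
    seed: int = 0,
) -> ImageVolume:
    """Analytic SRT-like dose with a Gaussian falloff outside the target.

    Per lesion, with t the signed distance to the PTV surface (positive
    outside) and delta = sigma * sqrt(ln 1.25):

        outside (t >= 0):  D = Dmax * exp(-((t + delta) / sigma)^2)
        inside  (t <  0):  D = Dmax * exp(-((delta * (1 + t/t_c)) / sigma)^2)

    where t_c is the lesion's maximal interior depth, so the dose ramps from
    Dmax at the lesion centre down to exactly the prescription
    (= 0.8 * Dmax, the "prescription at ~80% of maximum" planning rule) at
    the PTV surface and keeps falling as a Gaussian beyond it.  Doses of
    multiple lesions sum; the grid is the 1.25 mm isotropic dose geometry.

    A smooth multiplicative modulation field (``heterogeneity_sd``, default
    1%) emulates plan heterogeneity and keeps the DVH free of the exact-tie
    atoms a perfectly symmetric analytic field would otherwise produce; set
    it to 0 for a strictly symmetric field.
    """
    if not ptv_masks:
        raise ValueError("at least one PTV mask required")
    geom = dose_geometry or ptv_masks[0].geometry
    d_max = prescription_Gy / PRESCRIPTION_ISODOSE
    # exp(-(delta/sigma)^2) = 0.8  =>  delta = sigma * sqrt(ln 1.25)
    delta = falloff_mm * np.sqrt(np.log(1.0 / PRESCRIPTION_ISODOSE))
    dose = np.zeros(geom.shape)
    for ptv in ptv_masks:
        if not ptv.geometry.approx_equal(geom):
            raise ValueError("PTV masks must live on the dose geometry")
        t = _signed_distance_mm(ptv.voxels, geom.spacing)
        depth = max(float(-t.min()), 1e-9)
        eff = np.where(t >= 0, t + delta, delta * (1.0 + t / depth))
        dose += d_max * np.exp(-((eff / falloff_mm) ** 2))
    if heterogeneity_sd > 0:
        rng = np.random.default_rng(seed)
        g = ndimage.gaussian_filter(rng.normal(0.0, 1.0, geom.shape), 4.0)
        g /= max(g.std(), 1e-12)
        dose *= 1.0 + heterogeneity_sd * g
    return ImageVolume(geom, np.clip(dose, 0.0, None), modality="dose")


def perturb_dose(
    dose: ImageVolume,
    scale: float = 1.0,
    shift: RigidTransform | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ImageVolume:
    """Controlled deviation of a dose grid: global scale, rigid shift and
    optional smooth additive noise.  scale=1 with an identity shift and no
    noise returns the input unchanged."""
    out = dose
    if shift is not None and not shift.is_identity():
        out = apply_rigid(out, shift, interpolation="trilinear")
    vals = out.values * float(scale)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = ndimage.gaussian_filter(rng.normal(0.0, 1.0, vals.shape), 2.0)
        noise *= noise_sd / max(noise.std(), 1e-12)
        vals = np.clip(vals + noise, 0.0, None)
    return ImageVolume(dose.geometry, vals, modality="dose")


# ---------------------------------------------------------------------------
# full cases and cohorts
# ---------------------------------------------------------------------------

def generate_case(config: PhantomConfig, case_id: str = "case") -> PhantomCase:
    """Generate one complete paired case (CT, pCT, both dose grids, masks,
    manifest)."""
    structures, ct = generate_anatomy(config)
    pct = generate_pct(ct, config)
    dose_ct = generate_dose(
        [m for r, m in structures.items() if r.startswith("PTV")],
        config.prescription_Gy,
        config.fractions,
        falloff_mm=config.dose_falloff_sigma,
        seed=config.seed + 3,
    )
    rng = np.random.default_rng(config.seed + 2)
    scale = 1.0 + rng.normal(0.0, config.dose_scale_sd)
    shift = RigidTransform(
        translation_mm=tuple(rng.normal(0.0, config.dose_shift_sd_mm, 3))
    )
    dose_pct = perturb_dose(dose_ct, scale=scale, shift=shift)
    manifest = {
        "case_id": case_id,
        "prescription_Gy": config.prescription_Gy,
        "fractions": config.fractions,
        "n_lesions": config.n_lesions,
        "lesion_volumes_cc": list(config.lesion_volumes_cc),
        "perturbation": {"scale": float(scale), "shift_mm": list(shift.translation_mm)},
        "labels": {
            "lesions": config.n_lesions,
            "fractions": config.fractions,
            # analog of the T1W / T1W-CE binary image-type label
            "profile": int(config.seed % 2),
        },
    }
    return PhantomCase(ct, pct, dose_ct, dose_pct, structures, manifest)


def _sample_config(rng: np.random.Generator, seed: int) -> PhantomConfig:
    n_lesions = int(rng.choice([1, 2, 3, 4], p=[0.7, 0.14, 0.12, 0.04]))
    if n_lesions == 1:
        # log-uniform over the emulated 0.5-27.3 cc range (median ~3.7 cc)
        vols = (float(np.exp(rng.uniform(np.log(0.5), np.log(27.3)))),)
    else:
        vols = tuple(float(np.exp(rng.uniform(np.log(0.5), np.log(10.0))))
                     for _ in range(n_lesions))
    fractions = int(rng.choice([1, 3, 5], p=[0.42, 0.42, 0.16]))
    if fractions == 1:
        prescription = float(rng.uniform(20.0, 24.0))
    else:
        prescription = fractions * PRESCRIPTION_SCHEMES[fractions][0]
    return PhantomConfig(
        n_lesions=n_lesions,
        lesion_volumes_cc=vols,
        fractions=fractions,
        prescription_Gy=prescription,
        seed=seed,
    )


def generate_cohort(n_cases: int, seed: int = 0) -> list[PhantomCase]:
    """Generate a cohort of varied cases (lesion count, volume, scheme all
    drawn from the emulated study distributions)."""
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        case_seed = int(rng.integers(0, 2**31 - 1))
        for attempt in range(20):  # re-draw configs that fail placement
            try:
                cfg = _sample_config(rng, case_seed + attempt)
                cases.append(generate_case(cfg, case_id=f"case_{i:03d}"))
                break
            except ValueError:
                continue
        else:  # pragma: no cover - placement failure is pathological
            raise RuntimeError(f"could not place case {i}")
    return cases


def write_case(case: PhantomCase, out_dir: str | Path) -> Path:
    """Write a case to disk as NRRD volumes plus a JSON manifest; returns the
    manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dict(case.manifest)
    manifest["volumes"] = {}
    for name, vol in (
        ("ct", case.ct), ("pct", case.pct),
        ("dose_ct", case.dose_ct), ("dose_pct", case.dose_pct),
    ):
        path = out / f"{name}.nrrd"
        write_volume(vol, path)
        manifest["volumes"][name] = path.name
    manifest["structures"] = {}
    for role, mask in case.structures.items():
        path = out / f"mask_{role}.nrrd"
        write_mask(mask, path)
        manifest["structures"][role] = path.name
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return mpath
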