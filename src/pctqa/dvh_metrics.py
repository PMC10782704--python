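"""Dose-volume histograms and every DVH-derived plan metric.

Cumulative and differential DVHs are built from the dose voxels inside a
structure mask (point-sample convention, default bin width 0.01 Gy).  On top
of them sit the stereotactic plan-quality metrics:

* ``Dmax`` / ``Dmin`` — voxel extremes; ``D_0.1cc`` — dose exceeded by the
  hottest 0.1 cm^3; ``Dx%`` — dose received by the hottest x% of the volume.
* ``R100%`` / ``R50%`` — body volume inside the 100% / 50% prescription
  isodose divided by the PTV volume (overflow and gradient surrogates).
* D95% renormalization — rescale the dose grid so the PTV's D95% equals the
  prescription ("95% of the PTV receives at least 100% of the prescription").
* PTV Dmin/Dmax/Dmean reported divided by the prescription; OAR metrics in Gy.

All interpolation is linear on the cumulative curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_volumes import ImageVolume, StructureMask, resample_mask, structure_volume_cc

__all__ = [
    "DVHCurve",
    "DVHMetrics",
    "DEFAULT_BIN_WIDTH_GY",
    "compute_dvh",
    "dose_at_volume",
    "dose_at_absolute_volume",
    "volume_fraction_at_dose",
    "conformity_indices",
    "normalize_to_d95",
    "dvh_metrics",
    "dvh_metric_table",
]

DEFAULT_BIN_WIDTH_GY = 0.01


@dataclass
class DVHCurve:
    """Differential + cumulative DVH for one structure.

    ``edges`` are the uniform dose-bin edges (Gy, starting at 0);
    ``differential_cc`` the absolute volume per bin (cm^3, len = nbins);
    ``cumulative_fraction`` the fraction of the structure receiving at least
    each edge dose (len = nbins + 1, starts at 1, monotone nonincreasing).
    """

    edges: np.ndarray
    differential_cc: np.ndarray
    cumulative_fraction: np.ndarray
    role: str
    total_volume_cc: float

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.differential_cc = np.asarray(self.differential_cc, dtype=float)
        self.cumulative_fraction = np.asarray(self.cumulative_fraction, dtype=float)
        if len(self.edges) != len(self.differential_cc) + 1:
            raise ValueError("edges must be one longer than differential bins")
        if len(self.cumulative_fraction) != len(self.edges):
            raise ValueError("cumulative curve must align with edges")
        if np.any(self.differential_cc < -1e-12):
            raise ValueError("negative differential volume")
        if abs(self.differential_cc.sum() - self.total_volume_cc) > 1e-9:
            raise ValueError("differential bins do not sum to the total volume")

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def bin_centres(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    @property
    def fractional_volumes(self) -> np.ndarray:
        """Differential bin volumes as fractions summing to 1."""
        return self.differential_cc / self.total_volume_cc

    def scaled(self, factor: float) -> "DVHCurve":
        """DVH of the same structure under a global dose scale."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return DVHCurve(
            self.edges * factor,
            self.differential_cc.copy(),
            self.cumulative_fraction.copy(),
            self.role,
            self.total_volume_cc,
        )


def compute_dvh(
    dose: ImageVolume,
    mask: StructureMask,
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
) -> DVHCurve:
    """Histogram the masked dose voxels into uniform bins from 0 Gy.

    The cumulative fraction at edge d is the fraction of the structure volume
    with dose >= d (voxels sit in the half-open bin [edge, edge + width), so
    the hottest voxel contributes to the cumulative curve up to its bin's
    upper edge).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not mask.geometry.approx_equal(dose.geometry):
        mask = resample_mask(mask, dose.geometry)
    vals = dose.values[mask.voxels]
    if vals.size == 0:
        raise ValueError(f"empty structure {mask.role!r}")
    voxel_cc = mask.geometry.voxel_volume_mm3 / 1000.0
    n_bins = int(np.floor(vals.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(vals, bins=edges)
    diff_cc = counts * voxel_cc
    total = vals.size * voxel_cc
    cum = np.concatenate([[total], total - np.cumsum(diff_cc)]) / total
    cum = np.clip(cum, 0.0, 1.0)
    return DVHCurve(edges, diff_cc, cum, mask.role, total)


def _interp_on_cumulative(dvh: DVHCurve, fraction: float) -> float:
    """Dose at which the cumulative fraction equals ``fraction`` (linear
    interpolation; the curve is nonincreasing in dose)."""
    cum = dvh.cumulative_fraction
    edges = dvh.edges
    # np.interp needs increasing x: walk the curve reversed
    return float(np.interp(fraction, cum[::-1], edges[::-1]))


def dose_at_volume(dvh: DVHCurve, x_percent: float) -> float:
    """Dx% — dose received by the hottest x% of the structure volume."""
    if not 0 < x_percent <= 100:
        raise ValueError("x must be in (0, 100]")
    return _interp_on_cumulative(dvh, x_percent / 100.0)


def dose_at_absolute_volume(dvh: DVHCurve, v_cc: float) -> float:
    """D_v cc — dose exceeded by exactly v cm^3 of the structure."""
    if v_cc <= 0:
        raise ValueError("volume must be positive")
    if v_cc > dvh.total_volume_cc + 1e-12:
        raise ValueError(
            f"requested {v_cc} cc exceeds structure volume {dvh.total_volume_cc:.4f} cc"
        )
    return _interp_on_cumulative(dvh, v_cc / dvh.total_volume_cc)


def volume_fraction_at_dose(dvh: DVHCurve, dose_gy: float) -> float:
    """Fraction of the structure receiving at least ``dose_gy`` (linear
    interpolation on the cumulative curve; inverse of :func:`dose_at_volume`
    within one bin width)."""
    if dose_gy <= dvh.edges[0]:
        return 1.0
    if dose_gy >= dvh.edges[-1]:
        return 0.0
    return float(np.interp(dose_gy, dvh.edges, dvh.cumulative_fraction))


def conformity_indices(
    dose: ImageVolume,
    ptv: StructureMask,
    body: StructureMask,
    prescription_Gy: float,
) -> tuple[float, float]:
    """(R100%, R50%): body volume at >= 100% (50%) of the prescription dose
    divided by the PTV volume.  Evaluated over the whole body mask."""
    if prescription_Gy <= 0:
        raise ValueError("prescription must be positive")
    if not ptv.voxels.any():
        raise ValueError("empty PTV")
    if not body.geometry.approx_equal(dose.geometry):
        body = resample_mask(body, dose.geometry)
    if not ptv.geometry.approx_equal(dose.geometry):
        ptv = resample_mask(ptv, dose.geometry)
    voxel_cc = dose.geometry.voxel_volume_mm3 / 1000.0
    body_dose = dose.values[body.voxels]
    vol_100 = np.count_nonzero(body_dose >= prescription_Gy) * voxel_cc
    vol_50 = np.count_nonzero(body_dose >= prescription_Gy / 2.0) * voxel_cc
    ptv_cc = structure_volume_cc(ptv)
    return vol_100 / ptv_cc, vol_50 / ptv_cc


def normalize_to_d95(
    dose: ImageVolume,
    ptv: StructureMask,
    prescription_Gy: float,
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
) -> tuple[ImageVolume, float]:
    """Rescale the dose grid so the PTV's D95% equals the prescription.

    Returns the rescaled dose and the scale factor prescription / D95%.
    """
    dvh = compute_dvh(dose, ptv, bin_width)
    d95 = dose_at_volume(dvh, 95.0)
    if d95 <= 0:
        raise ValueError("PTV D95% is zero; cannot renormalize")
    factor = prescription_Gy / d95
    return ImageVolume(dose.geometry, dose.values * factor, modality="dose"), factor


@dataclass(frozen=True)
class DVHMetrics:
    role: str
    Dmin: float
    Dmax: float
    Dmean: float
    D0_1cc: float | None
    D50: float
    R100: float | None = None
    R50: float | None = None


def dvh_metrics(
    dose: ImageVolume,
    mask: StructureMask,
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
) -> DVHMetrics:
    """Voxel-exact Dmin/Dmax/Dmean plus interpolated D_0.1cc and D50%."""
    if not mask.geometry.approx_equal(dose.geometry):
        mask = resample_mask(mask, dose.geometry)
    vals = dose.values[mask.voxels]
    if vals.size == 0:
        raise ValueError(f"empty structure {mask.role!r}")
    dvh = compute_dvh(dose, mask, bin_width)
    d01 = (
        dose_at_absolute_volume(dvh, 0.1)
        if dvh.total_volume_cc >= 0.1
        else None
    )
    return DVHMetrics(
        role=mask.role,
        Dmin=float(vals.min()),
        Dmax=float(vals.max()),
        Dmean=float(vals.mean()),
        D0_1cc=d01,
        D50=dose_at_volume(dvh, 50.0),
    )


#: structures whose D0.1cc is the reported maximum-dose pair
_OAR_MAX_DOSE_ROLES = (
    "opt_chiasm", "opt_nerve_L", "opt_nerve_R", "lens_L", "lens_R",
    "brainstem", "spinal_cord",
)


def dvh_metric_table(
    case,
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
    renormalize: bool = True,
) -> pd.DataFrame:
    """Plan-metric table for one paired case (structure x image x metric).

    PTV Dmin/Dmax/Dmean are divided by the prescription dose; OAR metrics
    stay in Gy.  When ``renormalize`` is set both dose grids are first
    rescaled so their PTV D95% equals the prescription (multi-lesion cases
    use the union of PTVs).  Missing structures yield flagged rows, not
    errors.
    """
    prescription = float(case.manifest["prescription_Gy"])
    ptvs = case.ptv_masks
    if not ptvs:
        raise ValueError("case has no PTV")
    ptv_union = ptvs[0].voxels.copy()
    for m in ptvs[1:]:
        ptv_union |= m.voxels
    union_mask = StructureMask(ptvs[0].geometry, ptv_union, "PTV")

    doses = {"CT": case.dose_ct, "pCT": case.dose_pct}
    if renormalize:
        doses = {
            k: normalize_to_d95(v, union_mask, prescription, bin_width)[0]
            for k, v in doses.items()
        }

    # normal brain = brain minus all GTVs
    structures: dict[str, StructureMask] = dict(case.structures)
    if "brain" in structures:
        brain = structures["brain"].voxels.copy()
        for m in case.gtv_masks:
            brain &= ~m.voxels
        structures["brain_minus_GTV"] = StructureMask(
            structures["brain"].geometry, brain, "brain_minus_GTV", allow_empty=True
        )

    rows = []
    cid = case.manifest["case_id"]

    def metric_rows(role, mask, per_image_values, missing=False):
        for metric, vals in per_image_values.items():
            row = {"case": cid, "structure": role, "metric": metric, "missing": missing}
            if not missing:
                row["value_CT"], row["value_pCT"] = vals
                row["deviation"] = vals[0] - vals[1]
                row["abs_deviation"] = abs(vals[0] - vals[1])
            rows.append(row)

    # PTV block: prescription-normalized extremes + conformity indices
    body = structures.get("body")
    per_img = {}
    for img, dose in doses.items():
        m = dvh_metrics(dose, union_mask, bin_width)
        vals = {
            "Dmin/PD": m.Dmin / prescription,
            "Dmax/PD": m.Dmax / prescription,
            "Dmean/PD": m.Dmean / prescription,
        }
        if body is not None:
            r100, r50 = conformity_indices(dose, union_mask, body, prescription)
            vals["R100%"] = r100
            vals["R50%"] = r50
        for k, v in vals.items():
            per_img.setdefault(k, []).append(v)
    metric_rows("PTV", union_mask, {k: tuple(v) for k, v in per_img.items()})

    for role in _OAR_MAX_DOSE_ROLES + ("brain_minus_GTV",):
        mask = structures.get(role)
        if mask is None or not mask.voxels.any():
            metrics = ["D50%"] if role == "brain_minus_GTV" else ["Dmax", "D0.1cc"]
            metric_rows(role, None, {m: None for m in metrics}, missing=True)
            continue
        per_img = {}
        for img, dose in doses.items():
            m = dvh_metrics(dose, mask, bin_width)
            if role == "brain_minus_GTV":
                vals = {"D50%": m.D50}
            else:
                vals = {"Dmax": m.Dmax}
                if m.D0_1cc is not None:
                    vals["D0.1cc"] = m.D0_1cc
            for k, v in vals.items():
                per_img.setdefault(k, []).append(v)
        metric_rows(role, mask, {k: tuple(v) for k, v in per_img.items()})

    return pd.DataFrame(rows)
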