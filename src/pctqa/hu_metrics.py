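"""Per-structure HU summary statistics and CT-vs-pCT deviations.

The comparability question for a pseudo-CT starts with plain intensity
statistics inside each delineated structure: maximum, minimum, mean and
standard deviation of the HU values, plus the structure volume.  Deviations
between the planning-CT and pseudo-CT statistics are reported signed and
absolute.

The standard deviation uses the population formula (N divisor).  Structures
below a voxel-count floor (default 5) are flagged unreliable — very small
organs such as the lenses (< 0.2 cm^3) make these statistics noisy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_volumes import ImageVolume, StructureMask, structure_volume_cc

__all__ = ["HUStats", "HUDeviation", "hu_summary", "hu_deviation", "hu_table"]

#: below this many voxels the statistics are flagged unreliable
SMALL_STRUCTURE_VOXEL_FLOOR = 5

_FIELDS = ("max", "min", "mean", "sd", "volume_cc")


@dataclass(frozen=True)
class HUStats:
    role: str
    max: float
    min: float
    mean: float
    sd: float
    volume_cc: float
    n_voxels: int
    unreliable: bool = False


@dataclass(frozen=True)
class HUDeviation:
    """Signed (a - b) and absolute deviations per statistic."""

    role: str
    signed: dict
    absolute: dict


def hu_summary(
    volume: ImageVolume,
    mask: StructureMask,
    small_floor: int = SMALL_STRUCTURE_VOXEL_FLOOR,
) -> HUStats:
    """Summary statistics over exactly the voxels with mask = 1."""
    if not mask.geometry.approx_equal(volume.geometry):
        raise ValueError("mask and volume geometries differ; resample first")
    vals = volume.values[mask.voxels]
    if vals.size == 0:
        raise ValueError(f"empty structure {mask.role!r}")
    return HUStats(
        role=mask.role,
        max=float(vals.max()),
        min=float(vals.min()),
        mean=float(vals.mean()),
        sd=float(vals.std()),  # population (N divisor)
        volume_cc=structure_volume_cc(mask),
        n_voxels=int(vals.size),
        unreliable=vals.size < small_floor,
    )


def hu_deviation(a: HUStats, b: HUStats) -> HUDeviation:
    """Per-field deviation record between two stats of the same structure."""
    if a.role != b.role:
        raise ValueError(f"role mismatch: {a.role!r} vs {b.role!r}")
    signed = {f: getattr(a, f) - getattr(b, f) for f in _FIELDS}
    return HUDeviation(a.role, signed, {f: abs(v) for f, v in signed.items()})


def hu_table(cases: list, structures: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Tidy table: one row per (case, structure, image, statistic).

    ``cases`` are :class:`~pctqa.synthetic_data.PhantomCase` objects (or
    anything with ``ct``, ``pct``, ``structures`` and a manifest).
    """
    rows = []
    for case in cases:
        cid = case.manifest["case_id"]
        roles = structures or tuple(case.structures)
        for role in roles:
            mask = case.structures.get(role)
            if mask is None or not mask.voxels.any():
                continue
            s_ct = hu_summary(case.ct, mask)
            s_pct = hu_summary(case.pct, mask)
            dev = hu_deviation(s_ct, s_pct)
            for f in _FIELDS:
                rows.append(
                    {
                        "case": cid,
                        "structure": role,
                        "statistic": f,
                        "value_CT": getattr(s_ct, f),
                        "value_pCT": getattr(s_pct, f),
                        "deviation": dev.signed[f],
                        "abs_deviation": dev.absolute[f],
                        "unreliable": s_ct.unreliable,
                    }
                )
    return pd.DataFrame(rows)
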