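"""EQD2 conversion, gEUD, logistic TCP and Lyman-Kutcher-Burman NTCP.

The radiobiological layer converts each differential DVH bin to its 2 Gy-
equivalent dose under the linear-quadratic model,

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta),   d = D / n_fractions,

then condenses the distribution to an equivalent uniform dose:

* tumours — gEUD = (sum_i v_i D_i^a)^(1/a) with volume exponent a, and
  TCP = 1 / (1 + (TCD50 / EUD)^(4 * gamma50)) — the EUD-based logistic model.
  TCD50 is the homogeneous dose controlling 50% of tumours; gamma50 the
  change in TCP per 1% dose change about TCD50.
* organs at risk — Deff = (sum_i v_i D_i^(1/n))^n, t = (Deff - TD50)/(m*TD50),
  NTCP = Phi(t) — the Lyman-Kutcher-Burman model.  TD50 is the whole-organ
  uniform dose giving 50% complication risk, m the sigmoid slope, n the
  volume effect (n -> 0: serial organ, n = 1: mean-dose organ).

The shipped parameter defaults use alpha/beta = 3 Gy for normal tissues and
classic Burman-style OAR values; tumour values are PLACEHOLDERS, not
clinical data — edit the parameter table for any real analysis.  Spinal-cord
NTCP is excluded by default (the LKB model does not predict cord tolerance
to stereotactic fractionation well); pass ``include_spinal_cord=True`` to
override.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dvh_metrics import DVHCurve, compute_dvh

__all__ = [
    "RadiobiologicalParams",
    "DEFAULT_PARAMS",
    "load_params",
    "eqd2",
    "eqd2_dvh",
    "geud",
    "tcp_logistic",
    "ntcp_lkb",
    "outcome_table",
]


@dataclass(frozen=True)
class RadiobiologicalParams:
    """Per-structure model parameters.  Tumour roles need (alpha_beta, TCD50,
    gamma50, a); OAR roles need (alpha_beta, TD50, m, n)."""

    role: str
    kind: str  # "tumor" | "oar"
    alpha_beta: float
    TCD50: float | None = None
    gamma50: float | None = None
    a: float | None = None
    TD50: float | None = None
    m: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise ValueError("alpha/beta must be positive")
        if self.kind == "tumor":
            if self.TCD50 is None or self.gamma50 is None:
                raise ValueError(f"tumor params incomplete for {self.role!r}")
            if self.TCD50 <= 0:
                raise ValueError("TCD50 must be positive")
        elif self.kind == "oar":
            if self.TD50 is None or self.m is None or self.n is None:
                raise ValueError(f"OAR params incomplete for {self.role!r}")
            if self.TD50 <= 0 or self.m <= 0:
                raise ValueError("TD50 and m must be positive")
            if not 0 < self.n <= 1:
                raise ValueError("n must be in (0, 1]")
        else:
            raise ValueError(f"kind must be tumor or oar, got {self.kind!r}")


def _defaults() -> dict[str, RadiobiologicalParams]:
    # NON-CLINICAL placeholders (tumour) + classic Burman-style OAR values,
    # alpha/beta = 3 Gy for normal tissue.
    oar = lambda role, TD50, m, n: RadiobiologicalParams(  # noqa: E731
        role, "oar", alpha_beta=3.0, TD50=TD50, m=m, n=n
    )
    return {
        "PTV": RadiobiologicalParams(
            "PTV", "tumor", alpha_beta=10.0, TCD50=24.5, gamma50=1.5, a=-10.0
        ),
        "brain_minus_GTV": oar("brain_minus_GTV", 60.0, 0.15, 0.25),
        "brainstem": oar("brainstem", 65.0, 0.14, 0.16),
        "opt_chiasm": oar("opt_chiasm", 65.0, 0.14, 0.25),
        "opt_nerve_L": oar("opt_nerve_L", 65.0, 0.14, 0.25),
        "opt_nerve_R": oar("opt_nerve_R", 65.0, 0.14, 0.25),
        "lens_L": oar("lens_L", 18.0, 0.27, 0.30),
        "lens_R": oar("lens_R", 18.0, 0.27, 0.30),
        "spinal_cord": oar("spinal_cord", 66.5, 0.175, 0.05),
    }


DEFAULT_PARAMS = _defaults()


def load_params(path: str | Path) -> dict[str, RadiobiologicalParams]:
    """Load a JSON/YAML parameter table keyed by structure role and validate
    completeness."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return {role: RadiobiologicalParams(role=role, **spec) for role, spec in raw.items()}


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def eqd2(total_dose, n_fractions: int, alpha_beta: float):
    """2 Gy-equivalent dose under the linear-quadratic model (uniform
    fractionation: per-fraction dose d = D / n)."""
    if alpha_beta <= 0:
        raise ValueError("alpha/beta must be positive")
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    D = np.asarray(total_dose, dtype=float)
    if np.any(D < 0):
        raise ValueError("dose must be >= 0")
    d = D / n_fractions
    out = D * (d + alpha_beta) / (2.0 + alpha_beta)
    return float(out) if np.isscalar(total_dose) else out


def eqd2_dvh(dvh: DVHCurve, n_fractions: int, alpha_beta: float) -> tuple[np.ndarray, np.ndarray]:
    """Differential DVH in EQD2 space: (bin EQD2 doses, fractional volumes).

    The conversion is applied per differential bin using the bin-centre dose
    divided into the plan's fraction number.
    """
    doses = eqd2(dvh.bin_centres, n_fractions, alpha_beta)
    return np.asarray(doses), dvh.fractional_volumes


def geud(doses: np.ndarray, volumes: np.ndarray, a: float) -> float:
    """Generalized EUD: power mean (sum_i v_i D_i^a)^(1/a), v_i summing to 1.

    ``a = 0`` (geometric-mean limit) is not implemented and raises.
    """
    if a == 0:
        raise ValueError("a = 0 (geometric-mean limit) is not supported")
    doses = np.asarray(doses, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    total = volumes.sum()
    if total <= 0:
        raise ValueError("empty DVH")
    v = volumes / total
    nz = v > 0
    if a < 0 and np.any(doses[nz] <= 0):
        # zero-dose bins dominate negative exponents: EUD -> 0
        return 0.0
    pos = nz & (doses > 0)
    if not pos.any():
        return 0.0
    # log-domain power mean: stable for the serial-organ exponents (|a| >> 1)
    from scipy.special import logsumexp

    log_sum = logsumexp(a * np.log(doses[pos]), b=v[pos])
    return float(np.exp(log_sum / a))


def geud_from_dvh(dvh: DVHCurve, a: float, n_fractions: int | None = None,
                  alpha_beta: float | None = None) -> float:
    """gEUD of a DVH, optionally EQD2-converted first."""
    if n_fractions is not None and alpha_beta is not None:
        doses, vols = eqd2_dvh(dvh, n_fractions, alpha_beta)
    else:
        doses, vols = dvh.bin_centres, dvh.fractional_volumes
    return geud(doses, vols, a)


def tcp_logistic(eud: float, params: RadiobiologicalParams) -> float:
    """EUD-based logistic tumour control probability.

    TCP = 1 / (1 + (TCD50/EUD)^(4*gamma50)); EUD = TCD50 gives exactly 0.5,
    and the slope at TCD50 is gamma50 per 1% dose change.
    """
    if params.kind != "tumor":
        raise ValueError(f"{params.role!r} is not a tumor parameter set")
    if eud <= 0:
        import warnings

        warnings.warn("EUD <= 0: TCP set to 0", stacklevel=2)
        return 0.0
    return 1.0 / (1.0 + (params.TCD50 / eud) ** (4.0 * params.gamma50))


def ntcp_lkb(
    doses: np.ndarray, volumes: np.ndarray, params: RadiobiologicalParams
) -> float:
    """Lyman-Kutcher-Burman NTCP from a differential DVH (EQD2 space).

    Deff = (sum_i v_i D_i^(1/n))^n; NTCP = Phi((Deff - TD50)/(m*TD50)).
    Uniform whole-organ dose at TD50 gives exactly 0.5.
    """
    if params.kind != "oar":
        raise ValueError(f"{params.role!r} is not an OAR parameter set")
    if params.n <= 0:
        raise ValueError("n must be positive")
    deff = geud(doses, volumes, 1.0 / params.n)
    t = (deff - params.TD50) / (params.m * params.TD50)
    return float(norm.cdf(t))


# ---------------------------------------------------------------------------
# cohort outcome table
# ---------------------------------------------------------------------------

def _format_prob(p: float) -> str:
    """Probabilities below 1e-6 are reported as '<1e-6' rather than 0."""
    return "<1e-6" if 0 < p < 1e-6 else f"{p:.6g}"


def _case_outcomes(case, params, include_spinal_cord, bin_width):
    from .core_volumes import StructureMask

    prescription = float(case.manifest["prescription_Gy"])
    fractions = int(case.manifest["fractions"])
    structures = dict(case.structures)
    if "brain" in structures:
        brain = structures["brain"].voxels.copy()
        for m in case.gtv_masks:
            brain &= ~m.voxels
        structures["brain_minus_GTV"] = StructureMask(
            structures["brain"].geometry, brain, "brain_minus_GTV", allow_empty=True
        )

    ptvs = case.ptv_masks
    union = ptvs[0].voxels.copy()
    for m in ptvs[1:]:
        union |= m.voxels
    structures["PTV"] = StructureMask(ptvs[0].geometry, union, "PTV")

    out = {}
    for role, mask in structures.items():
        p = params.get(role)
        if p is None or not mask.voxels.any():
            continue
        if role == "spinal_cord" and not include_spinal_cord:
            continue
        vals = {}
        for img, dose in (("CT", case.dose_ct), ("pCT", case.dose_pct)):
            dvh = compute_dvh(dose, mask, bin_width)
            doses, vols = eqd2_dvh(dvh, fractions, p.alpha_beta)
            if p.kind == "tumor":
                eud = geud(doses, vols, p.a if p.a is not None else -10.0)
                vals[img] = tcp_logistic(eud, p)
            else:
                vals[img] = ntcp_lkb(doses, vols, p)
        out[role] = vals
    return out


def outcome_table(
    cases,
    params: dict[str, RadiobiologicalParams] | None = None,
    include_spinal_cord: bool = False,
    bin_width: float = 0.05,
) -> pd.DataFrame:
    """Per-structure TCP/NTCP for the CT and pseudo-CT dose with mean, range
    and absolute deviation over a cohort — the outcome comparison table.

    Structures without parameters are skipped with a log warning.
    """
    import logging

    log = logging.getLogger(__name__)
    params = params or DEFAULT_PARAMS
    per_structure: dict[str, dict[str, list[float]]] = {}
    for case in cases:
        res = _case_outcomes(case, params, include_spinal_cord, bin_width)
        for role, vals in res.items():
            d = per_structure.setdefault(role, {"CT": [], "pCT": [], "dev": []})
            d["CT"].append(vals["CT"])
            d["pCT"].append(vals["pCT"])
            d["dev"].append(abs(vals["CT"] - vals["pCT"]))
    known = {r for c in cases for r in c.structures} | {"PTV", "brain_minus_GTV"}
    for role in sorted(known - set(params) - {"brain", "body"} -
                       {r for r in known if r.startswith(("GTV", "PTV"))}):
        log.warning("no radiobiological parameters for %s; skipped", role)

    rows = []
    for role, d in per_structure.items():
        kind = params[role].kind
        ct, pct, dev = map(np.asarray, (d["CT"], d["pCT"], d["dev"]))
        rows.append(
            {
                "structure": role,
                "model": "TCP" if kind == "tumor" else "NTCP",
                "mean_CT": ct.mean(),
                "range_CT": (ct.min(), ct.max()),
                "mean_pCT": pct.mean(),
                "range_pCT": (pct.min(), pct.max()),
                "mean_abs_deviation": dev.mean(),
                "max_abs_deviation": dev.max(),
                "mean_CT_fmt": _format_prob(float(ct.mean())),
                "mean_pCT_fmt": _format_prob(float(pct.mean())),
                "n_cases": len(ct),
            }
        )
    return pd.DataFrame(rows)
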