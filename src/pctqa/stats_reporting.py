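"""Paired nonparametric statistics and report assembly.

The comparison layer of the pipeline: Wilcoxon signed-rank tests between
matched CT / pseudo-CT quantities (exact null enumeration for small n,
normal approximation with tie correction otherwise), a Shapiro-Wilk
normality pre-check that records why the nonparametric test is used,
Spearman rank correlation with the conventional significance stars
(* < 0.05, ** < 0.01, *** < 0.001), mean absolute deviation (MAD), and the
assembly of every report product into a deterministic CSV/JSON bundle.

Raw p-values are reported without multiple-testing correction (matching the
presentation this pipeline mirrors); a Benjamini-Hochberg column is emitted
alongside for transparency.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "PairedSample",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "normality_check",
    "spearman",
    "mad",
    "stars",
    "CorrelationMatrix",
    "correlation_report",
    "build_report",
]


@dataclass
class PairedSample:
    """Matched (CT, pCT) value pairs across cases for one metric."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("paired sample requires two equal-length 1-D arrays")
        if self.a.size < 1:
            raise ValueError("need at least one pair")

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # min(W+, W-)
    p_value: float
    n_nonzero: int
    exact: bool
    degenerate: bool = False


def _signed_rank_distribution(ranks2: np.ndarray) -> dict[int, int]:
    """Exact distribution of 2*W+ over all sign assignments: number of sign
    patterns achieving each doubled positive-rank sum (mid-ranks doubled to
    integers).  Dynamic program over the rank multiset."""
    dist = {0: 1}
    for r in ranks2:
        nxt: dict[int, int] = {}
        for s, c in dist.items():
            nxt[s] = nxt.get(s, 0) + c
            nxt[s + r] = nxt.get(s + r, 0) + c
        dist = nxt
    return dist


def wilcoxon_signed_rank(
    s: PairedSample,
    exact_threshold: int = 15,
    zero_method: str = "wilcox",
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (``wilcox``, the default) or
    ranked and split (``pratt``).  With ``n`` nonzero differences at or below
    ``exact_threshold`` the p-value is the exact enumeration over all 2^n
    sign assignments, P(|W+ - mu| >= |w+ - mu|); otherwise the normal
    approximation with tie and continuity correction is used.
    """
    d = s.differences
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    if zero_method == "wilcox":
        d = d[d != 0]
    if d.size == 0 or np.all(d == 0):
        return WilcoxonResult(0.0, 1.0, 0, exact=True, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    if zero_method == "pratt":
        keep = d != 0
        ranks, d = ranks[keep], d[keep]
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    n = d.size
    mu = ranks.sum() / 2.0

    if n <= exact_threshold:
        ranks2 = np.round(2.0 * ranks).astype(np.int64)
        dist = _signed_rank_distribution(ranks2)
        w2 = round(2.0 * w_plus)
        mu2 = ranks2.sum() / 2.0
        thresh = abs(w2 - mu2)
        count = sum(c for v, c in dist.items() if abs(v - mu2) >= thresh - 1e-9)
        p = count / 2.0**n
        return WilcoxonResult(min(w_plus, w_minus), min(p, 1.0), n, exact=True)

    # normal approximation: Var(W+) = sum(r^2)/4 (tie-corrected via mid-ranks)
    sigma = np.sqrt((ranks**2).sum() / 4.0)
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
    p = 2.0 * sps.norm.sf(abs(z))
    return WilcoxonResult(min(w_plus, w_minus), min(p, 1.0), n, exact=False)


def normality_check(sample, alpha: float = 0.05) -> tuple[bool | None, float | None]:
    """Shapiro-Wilk pre-check: (normal?, p).  Inconclusive (None) for n < 3
    or constant samples.  Used only to justify the nonparametric choice."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return None, None
    stat, p = sps.shapiro(x)
    return bool(p > alpha), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson of mid-ranks, t-approximation
    two-sided p).  Returns (nan, nan) for undefined (constant) inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def mad(s: PairedSample) -> float:
    """Mean absolute deviation over pairs: mean |a_i - b_i|."""
    return float(np.abs(s.differences).mean())


def stars(p: float) -> str:
    """Significance label: * < 0.05, ** < 0.01, *** < 0.001; 'x' otherwise."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "x"


@dataclass
class CorrelationMatrix:
    variables: list[str]
    rho: np.ndarray
    p: np.ndarray
    star_labels: np.ndarray

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, vi in enumerate(self.variables):
            for j, vj in enumerate(self.variables):
                rows.append(
                    {
                        "var_x": vi,
                        "var_y": vj,
                        "rho": self.rho[i, j],
                        "p_value": self.p[i, j],
                        "stars": self.star_labels[i, j],
                    }
                )
        return pd.DataFrame(rows)


def correlation_report(case_table: pd.DataFrame, columns: list[str] | None = None) -> CorrelationMatrix:
    """Full Spearman rho/p/star matrix over the numeric case-level factors
    (lesion count, fraction number, PTV volume, gamma passing rates, metric
    deviations, binary image-type code, ...).  Constant columns are flagged
    (NaN), not fatal.
    """
    if len(case_table) < 3:
        raise ValueError("need >= 3 cases for correlation analysis")
    cols = columns or [
        c for c in case_table.columns if np.issubdtype(case_table[c].dtype, np.number)
    ]
    k = len(cols)
    rho = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    labels = np.full((k, k), "", dtype=object)
    for i in range(k):
        for j in range(k):
            if i == j:
                rho[i, j], p[i, j] = 1.0, 0.0
            elif j < i:
                rho[i, j], p[i, j] = rho[j, i], p[j, i]
            else:
                xi = case_table[cols[i]].to_numpy(dtype=float)
                xj = case_table[cols[j]].to_numpy(dtype=float)
                ok = np.isfinite(xi) & np.isfinite(xj)
                if ok.sum() >= 3 and np.ptp(xi[ok]) > 0 and np.ptp(xj[ok]) > 0:
                    rho[i, j], p[i, j] = spearman(xi[ok], xj[ok])
            labels[i, j] = stars(p[i, j])
    return CorrelationMatrix(cols, rho, p, labels)


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps)
    adj = ps[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.clip(adj, 0, 1)
    out[ok] = res
    return out


def case_factor_table(cases, gamma_table: pd.DataFrame | None = None,
                      dvh_tables: dict | None = None,
                      hu_table_df: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per case with the correlation factors: lesion count, fraction
    number, PTV volume, per-criterion gamma passing rates, DVH / HU metric
    deviations, PTV volume deviation and the binary profile code."""
    from .core_volumes import structure_volume_cc

    rows = []
    for case in cases:
        cid = case.manifest["case_id"]
        labels = case.manifest.get("labels", {})
        ptvs = case.ptv_masks
        ptv_cc = sum(structure_volume_cc(m) for m in ptvs)
        row = {
            "case": cid,
            "lesions": labels.get("lesions"),
            "fractions": labels.get("fractions"),
            "ptv_volume_cc": ptv_cc,
            "profile": labels.get("profile"),
        }
        if gamma_table is not None:
            sub = gamma_table[gamma_table["case"] == cid]
            for _, r in sub.iterrows():
                row[f"gamma_{r['label']}"] = r["passing_rate"]
        if dvh_tables is not None and cid in dvh_tables:
            t = dvh_tables[cid]
            for _, r in t[~t.get("missing", False)].iterrows():
                row[f"dev_{r['structure']}_{r['metric']}"] = r["deviation"]
        if hu_table_df is not None:
            sub = hu_table_df[
                (hu_table_df["case"] == cid) & (hu_table_df["structure"].str.startswith("PTV"))
            ]
            for _, r in sub.iterrows():
                row[f"dev_HU_{r['statistic']}"] = r["deviation"]
        rows.append(row)
    return pd.DataFrame(rows)


def build_report(
    cases,
    out_dir: str | Path,
    criteria_list=None,
    include_radiomics: bool = False,
    radiomics_roles: tuple[str, ...] = ("PTV",),
    plots: bool = False,
) -> dict:
    """Run every analysis stage over a cohort and write the report bundle:
    CSV tables (HU, DVH, gamma, TCP/NTCP, correlations, optional radiomics)
    plus a JSON summary.  Deterministic given the inputs.

    Returns the summary dict.
    """
    from .dvh_metrics import dvh_metric_table
    from .gamma_analysis import CRITERIA_GRID, passing_rate_table, summarize_passing_rates
    from .hu_metrics import hu_table
    from .radiobiology import outcome_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    criteria_list = criteria_list or CRITERIA_GRID

    hu_df = hu_table(cases)
    hu_df.to_csv(out / "hu_metrics.csv", index=False)

    dvh_tables = {}
    for case in cases:
        try:
            dvh_tables[case.manifest["case_id"]] = dvh_metric_table(case)
        except ValueError as exc:
            log.warning("case %s excluded from DVH table: %s", case.manifest["case_id"], exc)
    dvh_df = pd.concat(dvh_tables.values(), ignore_index=True)

    # MAD and Wilcoxon per (structure, metric) across cases
    comp_rows = []
    for (structure, metric), grp in dvh_df[~dvh_df["missing"]].groupby(["structure", "metric"]):
        s = PairedSample(grp["value_CT"].to_numpy(), grp["value_pCT"].to_numpy())
        res = wilcoxon_signed_rank(s)
        comp_rows.append(
            {
                "structure": structure,
                "metric": metric,
                "mean_CT": s.a.mean(),
                "mean_pCT": s.b.mean(),
                "MAD": mad(s),
                "p_value": res.p_value,
                "n": len(grp),
            }
        )
    comp = pd.DataFrame(comp_rows)
    if len(comp):
        comp["p_bh"] = _benjamini_hochberg(comp["p_value"].to_numpy())
    comp.to_csv(out / "dvh_metrics_comparison.csv", index=False)
    dvh_df.to_csv(out / "dvh_metrics.csv", index=False)

    gamma_df = passing_rate_table(cases, criteria_list)
    gamma_df.to_csv(out / "gamma_passing_rates.csv", index=False)
    for by in ("lesion_group", "fractions"):
        summarize_passing_rates(gamma_df, by).to_csv(
            out / f"gamma_summary_by_{by}.csv", index=False
        )

    outcomes = outcome_table(cases)
    outcomes.to_csv(out / "tcp_ntcp.csv", index=False)

    factors = case_factor_table(cases, gamma_df, dvh_tables, hu_df)
    factors.to_csv(out / "case_factors.csv", index=False)
    corr = None
    if len(factors) >= 3:
        corr = correlation_report(factors)
        corr.to_long().to_csv(out / "correlation_matrix.csv", index=False)
    else:
        log.warning("fewer than 3 cases: correlation matrix skipped")

    if include_radiomics:
        from .radiomics_features import compare_features, extract_features

        for role in radiomics_roles:
            a, b = {}, {}
            for case in cases:
                masks = (
                    case.ptv_masks if role == "PTV" else [case.structures.get(role)]
                )
                m = masks[0]
                if m is None or not m.voxels.any():
                    continue
                cid = case.manifest["case_id"]
                a[cid] = extract_features(case.ct, m, image_tag="CT")
                b[cid] = extract_features(case.pct, m, image_tag="pCT")
            if a:
                compare_features(a, b).to_csv(
                    out / f"radiomics_comparison_{role}.csv", index=False
                )

    if plots and corr is not None:
        _write_plots(gamma_df, corr, out)

    summary = {
        "n_cases": len(cases),
        "gamma_median_by_label": {
            lbl: float(g["passing_rate"].median())
            for lbl, g in gamma_df.groupby("label")
        },
        "tcp_mad": float(
            outcomes.loc[outcomes["model"] == "TCP", "mean_abs_deviation"].mean()
        )
        if (outcomes["model"] == "TCP").any()
        else None,
        "tables": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def _write_plots(gamma_df: pd.DataFrame, corr: CorrelationMatrix, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    labels = sorted(gamma_df["label"].unique())
    data = [gamma_df.loc[gamma_df["label"] == l, "passing_rate"] for l in labels]
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("gamma passing rate (%)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(out / "gamma_boxplot.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(corr.rho, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.variables)), corr.variables, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr.variables)), corr.variables, fontsize=6)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(out / "correlation_heatmap.png", dpi=120)
    plt.close(fig)
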