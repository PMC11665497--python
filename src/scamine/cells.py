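"""Per-cell concentrations and group comparisons.

A dispensing-time diameter gives each cell a spherical volume; dividing the
back-calculated absolute amount (fmol) by the volume (pL) yields the
intracellular concentration (fmol/pL = mmol/L).  Cell types are compared per
analyte with Kruskal-Wallis + Dunn's post-hoc on concentrations and Levene's
test on variances; only in-range results enter the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quant_calibration import IN_RANGE


def volume_from_diameter(d_um: float) -> float:
    """Spherical cell volume (pL) from diameter (μm): (π/6)·d³·10⁻³."""
    if d_um <= 0:
        raise ValueError("diameter must be > 0")
    return math.pi / 6.0 * d_um**3 * 1e-3


def concentration(amount_fmol: float, volume_pl: float) -> float:
    """Intracellular concentration in mol/L (fmol/pL ≡ mmol/L, hence ·10⁻³)."""
    if volume_pl <= 0:
        raise ValueError("volume must be > 0")
    return amount_fmol / volume_pl * 1e-3


@dataclass
class CellRecord:
    cell_id: str
    cell_type: str
    diameter_um: float
    run_id: str
    channel: str

    @property
    def volume_pl(self) -> float:
        return volume_from_diameter(self.diameter_um)


@dataclass
class CellAnalyteResult:
    cell_id: str
    analyte: str
    amount_fmol: float
    concentration_molar: float
    range_flag: str


def cell_results(
    manifest: pd.DataFrame, amounts: pd.DataFrame
) -> pd.DataFrame:
    """Join back-calculated amounts onto the cell manifest.

    ``manifest`` columns: cell_id, cell_type, diameter_um, run_id, channel.
    ``amounts`` columns: run_id, channel, analyte, amount_fmol, range_flag.
    Cells with missing or nonpositive diameters are dropped (never imputed).
    Returns tidy rows (cell_id, cell_type, analyte, amount_fmol, volume_pL,
    conc_mM, flag).
    """
    man = manifest.copy()
    ok = man["diameter_um"].notna() & (man["diameter_um"] > 0)
    man = man[ok]
    merged = man.merge(amounts, on=["run_id", "channel"], how="inner")
    merged["volume_pL"] = merged["diameter_um"].map(volume_from_diameter)
    merged["conc_mM"] = merged.apply(
        lambda r: concentration(r["amount_fmol"], r["volume_pL"]) * 1e3, axis=1
    )
    cols = ["cell_id", "cell_type", "analyte", "amount_fmol", "volume_pL",
            "conc_mM", "range_flag"]
    return merged[cols].reset_index(drop=True)


def _check_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError(">= 2 groups required")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs n >= 2")
    return groups


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Rank-based H with tie correction; p from chi-square with k-1 df."""
    groups = _check_groups(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


@dataclass
class DunnPair:
    i: int
    j: int
    z: float
    p: float
    p_adjusted: float


def dunn_posthoc(
    groups: list[np.ndarray], alpha: float = 0.05, adjustment: str = "bonferroni"
) -> list[DunnPair]:
    """Dunn's post-hoc pairwise rank comparisons after Kruskal-Wallis.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with the tie
    term T = Σ(t³−t)/(12(N−1)); two-sided normal p-values adjusted by
    'none', 'bonferroni' or 'holm'.
    """
    if adjustment not in {"none", "bonferroni", "holm"}:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    groups = _check_groups(groups)
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[k]:bounds[k + 1]].mean() for k in range(len(groups))]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    raw: list[tuple[int, int, float, float]] = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
            if var <= 0:
                z = 0.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
            p = float(2 * sps.norm.sf(abs(z)))
            raw.append((i, j, z, p))
    m = len(raw)
    if adjustment == "none":
        adj = [p for *_, p in raw]
    elif adjustment == "bonferroni":
        adj = [min(1.0, m * p) for *_, p in raw]
    else:  # holm
        order = np.argsort([p for *_, p in raw])
        adj = [0.0] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw[idx][3])
            adj[idx] = min(1.0, running)
    return [DunnPair(i, j, z, p, a) for (i, j, z, p), a in zip(raw, adj)]


def levene(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classic (mean-centered) Levene test of equal variances."""
    groups = _check_groups(groups)
    devs = [np.abs(g - g.mean()) for g in groups]
    if all(np.all(d == 0) for d in devs):
        return 0.0, 1.0
    w, p = sps.levene(*groups, center="mean")
    return float(w), float(p)


@dataclass
class GroupTestResult:
    analyte: str
    kw_h: float
    kw_p: float
    dunn: list[DunnPair]
    levene_w: float
    levene_p: float


def group_tests(
    results: pd.DataFrame, adjustment: str = "bonferroni"
) -> list[GroupTestResult]:
    """Run KW + Dunn + Levene per analyte on in-range concentrations only.

    ``results`` is the tidy frame from :func:`cell_results`; out-of-range rows
    never contribute (exclusion by construction).
    """
    out = []
    usable = results[results["range_flag"] == IN_RANGE]
    for analyte, sub in usable.groupby("analyte", sort=True):
        groups = [
            sub.loc[sub["cell_type"] == t, "conc_mM"].to_numpy()
            for t in sorted(sub["cell_type"].unique())
        ]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            continue
        h, p = kruskal_wallis(groups)
        dunn = dunn_posthoc(groups, adjustment=adjustment)
        w, lp = levene(groups)
        out.append(GroupTestResult(analyte, h, p, dunn, w, lp))
    return out
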