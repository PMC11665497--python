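"""Simulator for multiplexed single-cell amine runs with known ground truth.

Each simulated LC-MS2 run carries nine used TMT10plex channels (six single
cells, an analyte-abundant carrier, a blank and an internal-standard blank;
127C unused by default), Gaussian LC elution per analyte, isobaric channel
cross-talk through an impurity matrix, an optional phenomenological
coalescence bleed from the carrier into the 127 channels, proportional plus
additive Gaussian intensity noise (truncated at zero), and per-scan
compositional rescaling that caps the summed intensity at the AGC target.

Ground-truth bookkeeping uses the exact same arithmetic as the cells module:
amount (fmol) = concentration (mol/L) × volume (pL) × 10³ with the spherical
volume derived from the dispensing-time diameter.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .cells import volume_from_diameter
from .channels import CHANNEL_NAMES, REPORTER_MZ, labeled_precursor_mz
from .quant_calibration import ImpurityMatrix
from .reporter_extraction import Ms2Scan
from .untargeted import FeatureTable

GAUSS_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...

#: mass shift of the heavy-isotope internal standards (six 13C substitutions)
HEAVY_IS_SHIFT = 6 * 1.003354835

# ---------------------------------------------------------------------------
# Analytes and plex design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LcPeak:
    rt_min: float
    fwhm_min: float


@dataclass(frozen=True)
class AnalyteSpec:
    """One targeted analyte: formula, labeling stoichiometry and LC behaviour.

    Amino acids with two amine groups (cystine, lysine) carry two tags and
    two charges; the rest are singly labeled, singly protonated.
    """

    name: str
    formula: str
    n_labels: int = 1
    charge: int = 1
    lc: LcPeak | None = None

    @property
    def neutral_mass(self) -> float:
        return _pmass.calculate_mass(formula=self.formula)

    @property
    def precursor_mz(self) -> float:
        return labeled_precursor_mz(self.neutral_mass, self.n_labels, self.charge)

    @property
    def is_precursor_mz(self) -> float:
        """Precursor m/z of the co-eluting heavy internal standard."""
        return labeled_precursor_mz(
            self.neutral_mass + HEAVY_IS_SHIFT, self.n_labels, self.charge
        )

    @property
    def is_target_id(self) -> str:
        return f"{self.name}__IS"


#: Default panel: the ten quantifiable amino acids with their observed
#: retention times and peak widths.
DEFAULT_ANALYTES: tuple[AnalyteSpec, ...] = (
    AnalyteSpec("aspartic acid", "C4H7NO4", lc=LcPeak(13.40, 2.15)),
    AnalyteSpec("cystine", "C6H12N2O4S2", n_labels=2, charge=2, lc=LcPeak(19.60, 0.15)),
    AnalyteSpec("glutamic acid", "C5H9NO4", lc=LcPeak(16.09, 0.33)),
    AnalyteSpec("isoleucine", "C6H13NO2", lc=LcPeak(24.88, 0.13)),
    AnalyteSpec("leucine", "C6H13NO2", lc=LcPeak(25.56, 0.11)),
    AnalyteSpec("lysine", "C6H14N2O2", n_labels=2, charge=2, lc=LcPeak(18.39, 0.09)),
    AnalyteSpec("methionine", "C5H11NO2S", lc=LcPeak(21.57, 0.20)),
    AnalyteSpec("phenylalanine", "C9H11NO2", lc=LcPeak(26.91, 0.05)),
    AnalyteSpec("tyrosine", "C9H11NO3", lc=LcPeak(21.52, 0.14)),
    AnalyteSpec("valine", "C5H11NO2", lc=LcPeak(20.96, 0.18)),
)


@dataclass(frozen=True)
class ChannelRole:
    kind: str  # cell | carrier | blank | is_blank | unused
    cell_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"cell", "carrier", "blank", "is_blank", "unused"}:
            raise ValueError(f"unknown role {self.kind!r}")
        if (self.kind == "cell") != (self.cell_id is not None):
            raise ValueError("cell roles (and only they) need a cell_id")


@dataclass
class PlexDesign:
    """Assignment of the ten channels of one run to roles."""

    run_id: str
    roles: dict[str, ChannelRole]

    def __post_init__(self) -> None:
        if set(self.roles) != set(CHANNEL_NAMES):
            raise ValueError("plex must assign a role to every channel")
        kinds = [r.kind for r in self.roles.values()]
        counts = {k: kinds.count(k) for k in set(kinds)}
        if counts.get("cell") != 6:
            raise ValueError("exactly 6 cell channels required")
        for k in ("carrier", "blank", "is_blank", "unused"):
            if counts.get(k) != 1:
                raise ValueError(f"exactly one {k} channel required")
        cell_ids = [r.cell_id for r in self.roles.values() if r.kind == "cell"]
        if len(set(cell_ids)) != 6:
            raise ValueError("cell ids must be distinct")

    def _one(self, kind: str) -> str:
        return next(c for c, r in self.roles.items() if r.kind == kind)

    @property
    def carrier_channel(self) -> str:
        return self._one("carrier")

    @property
    def blank_channel(self) -> str:
        return self._one("blank")

    @property
    def is_blank_channel(self) -> str:
        return self._one("is_blank")

    @property
    def unused_channel(self) -> str:
        return self._one("unused")

    @property
    def cell_channels(self) -> list[tuple[str, str]]:
        """(channel, cell_id) pairs in channel (m/z) order."""
        return [
            (c, self.roles[c].cell_id)
            for c in CHANNEL_NAMES
            if self.roles[c].kind == "cell"
        ]


def default_plex(run_id: str, cell_ids: list[str]) -> PlexDesign:
    """Default layout: carrier=126, blank=127N, unused=127C, cells=128N-130C,
    IS-blank=131."""
    if len(cell_ids) != 6:
        raise ValueError("exactly 6 cell ids required")
    roles = {
        "126": ChannelRole("carrier"),
        "127N": ChannelRole("blank"),
        "127C": ChannelRole("unused"),
        "131": ChannelRole("is_blank"),
    }
    for ch, cid in zip(("128N", "128C", "129N", "129C", "130N", "130C"), cell_ids):
        roles[ch] = ChannelRole("cell", cid)
    return PlexDesign(run_id, roles)


# ---------------------------------------------------------------------------
# Cell population
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellTypeParams:
    """Sampling distributions for one cell type: Gaussian diameter (μm) and
    per-analyte log10-normal concentration (log10 mol/L)."""

    diameter_mean_um: float
    diameter_sd_um: float
    conc_log10_mean: dict[str, float]
    conc_log10_sd: float

    def __post_init__(self) -> None:
        if self.diameter_mean_um <= 0:
            raise ValueError("diameter mean must be > 0")
        if self.diameter_sd_um < 0 or self.conc_log10_sd < 0:
            raise ValueError("distribution scale parameters must be >= 0")


@dataclass
class TrueCellState:
    cell_id: str
    cell_type: str
    diameter_um: float
    concentrations: dict[str, float]  # analyte -> mol/L

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be > 0")
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be >= 0")

    @property
    def volume_pl(self) -> float:
        return volume_from_diameter(self.diameter_um)

    def amount_fmol(self, analyte: str) -> float:
        """fmol = (mol/L) × pL × 10³ — the inverse of the concentration step."""
        return self.concentrations[analyte] * self.volume_pl * 1e3


_BASE_LOG10 = {
    "aspartic acid": -2.3,
    "cystine": -4.3,
    "glutamic acid": -2.2,
    "isoleucine": -3.1,
    "leucine": -3.0,
    "lysine": -2.9,
    "methionine": -3.9,
    "phenylalanine": -3.2,
    "tyrosine": -3.3,
    "valine": -2.9,
}


def default_cell_types() -> dict[str, CellTypeParams]:
    """Three cohorts: HEK-293 (small cells, higher amino-acid levels) and the
    two larger ovarian-carcinoma lines, with a glutamate shift between the
    cisplatin-resistant variant and its parent."""
    hek = dict(_BASE_LOG10)
    for a in ("glutamic acid", "lysine", "methionine", "valine"):
        hek[a] += 0.25
    tyknu = dict(_BASE_LOG10)
    cpr = dict(_BASE_LOG10)
    cpr["glutamic acid"] -= 0.25
    return {
        "HEK-293": CellTypeParams(15.1, 1.2, hek, 0.25),
        "TYK-nu": CellTypeParams(21.6, 1.5, tyknu, 0.25),
        "TYK-nu.CP-r": CellTypeParams(20.0, 1.8, cpr, 0.25),
    }


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Amounts are fmol, times minutes, intensities arbitrary counts.  The
    carrier carries the top of the calibration range per analyte; internal
    standards sit at 12 fmol.  Noise has a proportional part (noise_cv) and
    an additive floor (noise_sd) that drives the S/N-based LOD/LOQ.
    """

    analytes: tuple[AnalyteSpec, ...] = DEFAULT_ANALYTES
    cell_types: dict[str, CellTypeParams] = field(default_factory=default_cell_types)
    n_cells_per_type: int = 20
    carrier_amount: float = 120.0
    is_amount: float = 12.0
    response_factor: float = 1e4  # counts per fmol at peak apex
    noise_sd: float = 20.0
    noise_cv: float = 0.02
    agc_target: float = 1e8
    impurity: ImpurityMatrix = field(default_factory=ImpurityMatrix.default)
    coalescence_bleed: float = 0.0
    missing_feature_prob: float = 0.2
    scan_interval: float = 0.02
    span_fwhms: float = 3.0
    volume_range_pl: tuple[float, float] = (1.0, 8.5)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("carrier_amount", "is_amount", "response_factor",
                     "noise_sd", "noise_cv", "missing_feature_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.agc_target <= 0:
            raise ValueError("agc_target must be > 0")
        if not 0 <= self.coalescence_bleed < 1:
            raise ValueError("coalescence_bleed must be in [0, 1)")
        if self.scan_interval <= 0 or self.span_fwhms <= 0:
            raise ValueError("scan grid parameters must be > 0")


def _diameter_bounds(volume_range_pl: tuple[float, float]) -> tuple[float, float]:
    lo, hi = volume_range_pl
    return tuple((6.0 * v * 1e3 / math.pi) ** (1.0 / 3.0) for v in (lo, hi))


def generate_cell_population(config: SimConfig) -> list[TrueCellState]:
    """Draw the cohort: per-type Gaussian diameters (clipped so volumes stay
    inside the configured range) and log-normal concentrations.

    Deterministic given ``config.rng_seed``; zero-variance parameters
    reproduce the configured means exactly.
    """
    if config.n_cells_per_type < 1:
        raise ValueError("n_cells_per_type must be >= 1")
    rng = np.random.default_rng(config.rng_seed)
    d_lo, d_hi = _diameter_bounds(config.volume_range_pl)
    cells = []
    for cell_type in sorted(config.cell_types):
        params = config.cell_types[cell_type]
        for i in range(config.n_cells_per_type):
            d = params.diameter_mean_um + params.diameter_sd_um * rng.standard_normal()
            d = min(max(d, d_lo), d_hi)
            conc = {
                a.name: 10.0
                ** (
                    params.conc_log10_mean[a.name]
                    + params.conc_log10_sd * rng.standard_normal()
                )
                for a in config.analytes
            }
            cells.append(
                TrueCellState(f"{cell_type}-{i + 1:03d}", cell_type, d, conc)
            )
    return cells


# ---------------------------------------------------------------------------
# Run simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedRun:
    plex: PlexDesign
    scans: list[Ms2Scan]
    truth: dict[str, dict[str, float]]  # target -> channel -> amount (fmol)
    feature_truth: dict[str, dict[str, float]] | None = None


def _apply_noise_and_agc(
    obs: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.noise_cv > 0:
        obs = obs * (1.0 + config.noise_cv * rng.standard_normal(obs.size))
    if config.noise_sd > 0:
        obs = obs + config.noise_sd * rng.standard_normal(obs.size)
    obs = np.clip(obs, 0.0, None)
    total = obs.sum()
    while total > config.agc_target:
        obs = obs * (config.agc_target / total)
        total = obs.sum()
    return obs


def _simulate_target(
    run_id: str,
    target_id: str,
    precursor_mz: float,
    lc: LcPeak,
    amounts: np.ndarray,
    carrier_idx: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[Ms2Scan]:
    sigma = lc.fwhm_min / GAUSS_FWHM_FACTOR
    half_span = config.span_fwhms * lc.fwhm_min
    n_steps = int(round(2 * half_span / config.scan_interval))
    times = lc.rt_min - half_span + config.scan_interval * np.arange(n_steps + 1)
    bleed_idx = [CHANNEL_NAMES.index("127N"), CHANNEL_NAMES.index("127C")]
    scans = []
    for i, t in enumerate(times):
        g = math.exp(-((t - lc.rt_min) ** 2) / (2.0 * sigma**2))
        ideal = config.response_factor * amounts * g
        obs = config.impurity.mix(ideal)
        if config.coalescence_bleed > 0:
            for b in bleed_idx:
                obs[b] += config.coalescence_bleed * ideal[carrier_idx]
        obs = _apply_noise_and_agc(obs, config, rng)
        peaks = [
            (REPORTER_MZ[ch], float(v))
            for ch, v in zip(CHANNEL_NAMES, obs)
            if v > 0
        ]
        scans.append(
            Ms2Scan(f"{run_id}:{target_id}:{i:04d}", target_id, float(t),
                    precursor_mz, peaks)
        )
    return scans


def simulate_run_amounts(
    plex: PlexDesign,
    amounts_by_target: dict[str, dict[str, float]],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedRun:
    """Simulate a run from explicit per-target per-channel amounts (fmol).

    ``amounts_by_target`` maps a target id (analyte or its ``__IS`` twin) to
    {channel: fmol}; unlisted channels get 0.  This is the engine behind
    :func:`simulate_run` and the calibration scenarios.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    specs = {a.name: a for a in config.analytes}
    carrier_idx = CHANNEL_NAMES.index(plex.carrier_channel)
    scans: list[Ms2Scan] = []
    truth: dict[str, dict[str, float]] = {}
    for target_id, by_channel in amounts_by_target.items():
        base = target_id.removesuffix("__IS")
        spec = specs.get(base)
        if spec is None or spec.lc is None:
            raise ValueError(f"no LC parameters for analyte {base!r}")
        precursor = spec.is_precursor_mz if target_id.endswith("__IS") else spec.precursor_mz
        amounts = np.array([by_channel.get(ch, 0.0) for ch in CHANNEL_NAMES])
        scans.extend(
            _simulate_target(plex.run_id, target_id, precursor, spec.lc,
                             amounts, carrier_idx, config, rng)
        )
        truth[target_id] = {ch: float(a) for ch, a in zip(CHANNEL_NAMES, amounts)}
    return SimulatedRun(plex, scans, truth)


def simulate_run(
    plex: PlexDesign,
    truth: list[TrueCellState],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedRun:
    """Simulate one multiplexed run from the true cell states.

    Per analyte, cell channels carry concentration × volume fmol, the carrier
    its fixed amount and everything else zero; each analyte also gets a heavy
    internal-standard transition with ``is_amount`` in the IS-blank channel.
    """
    by_id = {c.cell_id: c for c in truth}
    amounts: dict[str, dict[str, float]] = {}
    for spec in config.analytes:
        per_channel: dict[str, float] = {}
        for ch, cid in plex.cell_channels:
            cell = by_id.get(cid)
            if cell is None:
                raise ValueError(f"no TrueCellState for cell {cid!r}")
            per_channel[ch] = cell.amount_fmol(spec.name)
        per_channel[plex.carrier_channel] = config.carrier_amount
        amounts[spec.name] = per_channel
        amounts[spec.is_target_id] = {plex.is_blank_channel: config.is_amount}
    return simulate_run_amounts(plex, amounts, config, rng)


# ---------------------------------------------------------------------------
# Run serialization
# ---------------------------------------------------------------------------

_SCAN_COLUMNS = ["scan_id", "target_id", "rt_min", "precursor_mz", "channel",
                 "intensity"]


def write_run(run: SimulatedRun, path: str | Path) -> None:
    """Write one run as ``run.json`` (plex + truth) and ``scans.csv``.

    The scan table stores one row per channel per scan (zeros included);
    floats are written with ``repr`` so the round-trip is bit-exact.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "run_id": run.plex.run_id,
        "roles": {
            ch: {"kind": r.kind, "cell_id": r.cell_id}
            for ch, r in run.plex.roles.items()
        },
        "truth": run.truth,
        "feature_truth": run.feature_truth,
    }
    (path / "run.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    with open(path / "scans.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SCAN_COLUMNS)
        for scan in run.scans:
            by_mz = {mz: i for mz, i in scan.peaks}
            for ch in CHANNEL_NAMES:
                writer.writerow(
                    [scan.scan_id, scan.target_id, repr(scan.rt),
                     repr(scan.precursor_mz), ch,
                     repr(by_mz.get(REPORTER_MZ[ch], 0.0))]
                )


def read_run(path: str | Path) -> SimulatedRun:
    """Read a run written by :func:`write_run`; inverse on all fields."""
    path = Path(path)
    meta = json.loads((path / "run.json").read_text())
    roles = {
        ch: ChannelRole(r["kind"], r["cell_id"]) for ch, r in meta["roles"].items()
    }
    plex = PlexDesign(meta["run_id"], roles)
    scans: list[Ms2Scan] = []
    with open(path / "scans.csv", newline="") as fh:
        reader = csv.DictReader(fh)
        current: dict | None = None
        for i, row in enumerate(reader):
            if row["rt_min"] in ("", None):
                raise ValueError(f"scan record {i}: missing rt_min")
            if current is None or row["scan_id"] != current["scan_id"]:
                if current is not None:
                    scans.append(_scan_from_record(current))
                current = {
                    "scan_id": row["scan_id"],
                    "target_id": row["target_id"],
                    "rt": float(row["rt_min"]),
                    "precursor_mz": float(row["precursor_mz"]),
                    "intensities": {},
                }
            current["intensities"][row["channel"]] = float(row["intensity"])
        if current is not None:
            scans.append(_scan_from_record(current))
    return SimulatedRun(plex, scans, meta["truth"], meta["feature_truth"])


def _scan_from_record(rec: dict) -> Ms2Scan:
    peaks = [
        (REPORTER_MZ[ch], rec["intensities"][ch])
        for ch in CHANNEL_NAMES
        if ch in rec["intensities"] and rec["intensities"][ch] > 0
    ]
    return Ms2Scan(rec["scan_id"], rec["target_id"], rec["rt"],
                   rec["precursor_mz"], peaks)


# ---------------------------------------------------------------------------
# Cohort / calibration / untargeted scenarios
# ---------------------------------------------------------------------------


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[SimulatedRun], pd.DataFrame, list[TrueCellState]]:
    """Full targeted cohort: population → runs of six cells → manifest.

    Cell types are interleaved across runs so every run mixes types.  Returns
    the runs, a manifest (cell_id, cell_type, diameter_um, run_id, channel)
    and the true population.  The total cell count must be divisible by 6.
    """
    population = generate_cell_population(config)
    if len(population) % 6 != 0:
        raise ValueError("total number of cells must be divisible by 6")
    n_types = len(config.cell_types)
    interleaved = []
    for i in range(config.n_cells_per_type):
        for t in range(n_types):
            interleaved.append(population[t * config.n_cells_per_type + i])
    runs, rows = [], []
    for r, start in enumerate(range(0, len(interleaved), 6)):
        group = interleaved[start:start + 6]
        plex = default_plex(f"run_{r:02d}", [c.cell_id for c in group])
        runs.append(simulate_run(plex, group, config, _child_rng(config.rng_seed, r)))
        for ch, cid in plex.cell_channels:
            cell = next(c for c in group if c.cell_id == cid)
            rows.append(
                {"cell_id": cid, "cell_type": cell.cell_type,
                 "diameter_um": cell.diameter_um, "run_id": plex.run_id,
                 "channel": ch}
            )
    return runs, pd.DataFrame(rows), population


DEFAULT_CAL_LEVELS = (0.03, 0.1, 0.3, 1.0, 3.0, 30.0, 120.0)


def simulate_calibration(
    config: SimConfig,
    levels: tuple[float, ...] = DEFAULT_CAL_LEVELS,
) -> tuple[list[SimulatedRun], pd.DataFrame]:
    """Seven-level multiplexed calibration: one run per level, every cell
    channel carrying the level amount for every analyte (intra-run
    replicates), carrier and IS as in a sample run."""
    runs, rows = [], []
    for li, level in enumerate(levels):
        plex = default_plex(f"cal_{li:02d}", [f"cal{li}_{j}" for j in range(6)])
        amounts: dict[str, dict[str, float]] = {}
        for spec in config.analytes:
            per_channel = {ch: level for ch, _ in plex.cell_channels}
            per_channel[plex.carrier_channel] = config.carrier_amount
            amounts[spec.name] = per_channel
            amounts[spec.is_target_id] = {plex.is_blank_channel: config.is_amount}
            for ch, _ in plex.cell_channels:
                rows.append(
                    {"analyte": spec.name, "level": li, "nominal_fmol": level,
                     "channel": ch, "run_id": plex.run_id}
                )
        runs.append(
            simulate_run_amounts(plex, amounts, config,
                                 _child_rng(config.rng_seed, 1000 + li))
        )
    return runs, pd.DataFrame(rows)


def simulate_repeatability(
    config: SimConfig, level_fmol: float, n_runs: int = 2, tag: str = "rep"
) -> list[SimulatedRun]:
    """Replicate runs with every cell channel at ``level_fmol`` (6 replicate
    measurements per run) for repeatability RSD assessment."""
    runs = []
    for r in range(n_runs):
        plex = default_plex(f"{tag}_{r:02d}", [f"{tag}{r}_{j}" for j in range(6)])
        amounts: dict[str, dict[str, float]] = {}
        for spec in config.analytes:
            per_channel = {ch: level_fmol for ch, _ in plex.cell_channels}
            per_channel[plex.carrier_channel] = config.carrier_amount
            amounts[spec.name] = per_channel
            amounts[spec.is_target_id] = {plex.is_blank_channel: config.is_amount}
        runs.append(
            simulate_run_amounts(plex, amounts, config,
                                 _child_rng(config.rng_seed, 2000 + r))
        )
    return runs


def generate_feature_table(
    config: SimConfig,
    n_features: int = 200,
    n_informative: int = 3,
    effect_sd_units: float = 2.0,
    n_cells_per_type: int = 16,
    n_replicates: int = 3,
) -> tuple[FeatureTable, dict]:
    """Untargeted feature × sample table with planted class structure.

    Values emulate carrier-normalized, missingness-prone DDA intensities:
    per-feature log2 baselines, per-cell and per-replicate lognormal noise,
    and Bernoulli missingness (``config.missing_feature_prob``) per
    feature × sample.  Informative features get a cell-type shift of
    ``effect_sd_units`` within-type standard deviations, where the sd is that
    of the values as analysed downstream (zero-filled log2 scale, so
    dropout-induced variance counts); without this the nominal effect size
    would be silently diluted by the missingness rate.  Returns the table and
    a truth dict with the planted informative feature ids.
    """
    rng = _child_rng(config.rng_seed, 9000)
    types = sorted(config.cell_types)
    cell_sd, rep_sd = 0.5, 0.3
    p_miss = config.missing_feature_prob
    feature_ids = [f"F{i + 1:04d}" for i in range(n_features)]
    mz = rng.uniform(250.0, 650.0, n_features)
    rt = rng.uniform(5.0, 30.0, n_features)
    baseline = rng.normal(8.0, 1.5, n_features)
    # within-type sd on the zero-filled log2 scale: biological + replicate
    # noise plus the Bernoulli dropout term p(1-p)·baseline²
    analyzed_sd = np.sqrt(
        cell_sd**2 + rep_sd**2 + p_miss * (1.0 - p_miss) * baseline**2
    )
    effect = effect_sd_units * analyzed_sd
    informative = sorted(rng.choice(n_features, size=n_informative, replace=False))
    target_type = {int(f): types[i % len(types)] for i, f in enumerate(informative)}
    cells = [
        (f"{t}-u{i + 1:03d}", t) for t in types for i in range(n_cells_per_type)
    ]
    sample_rows, columns = [], []
    values = np.empty((n_features, len(cells) * n_replicates))
    col = 0
    for cell_id, cell_type in cells:
        cell_eff = rng.normal(0.0, cell_sd, n_features)
        for rep in range(1, n_replicates + 1):
            log2v = baseline + cell_eff + rng.normal(0.0, rep_sd, n_features)
            for f in informative:
                if target_type[int(f)] == cell_type:
                    log2v[f] += effect[int(f)]
            vals = np.power(2.0, log2v)
            miss = rng.random(n_features) < config.missing_feature_prob
            vals[miss] = np.nan
            values[:, col] = vals
            sample_id = f"{cell_id}_r{rep}"
            columns.append(sample_id)
            sample_rows.append(
                {"sample_id": sample_id, "cell_id": cell_id,
                 "cell_type": cell_type, "replicate_id": rep}
            )
            col += 1
    features = pd.DataFrame({"mz": mz, "rt": rt}, index=pd.Index(feature_ids, name="feature_id"))
    table = FeatureTable(
        features=features,
        values=pd.DataFrame(values, index=features.index, columns=columns),
        samples=pd.DataFrame(sample_rows).set_index("sample_id"),
    )
    truth = {
        "informative": [feature_ids[int(f)] for f in informative],
        "target_type": {feature_ids[int(f)]: t for f, t in target_type.items()},
    }
    return table, truth
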