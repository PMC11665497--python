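"""High-level pipeline steps tying the modules together.

These functions operate on whole simulated (or deserialized) runs and are the
engine behind the command-line subcommands and the reproducibility script:
scan extraction → impurity-corrected areas → IS-normalized calibration →
per-cell amounts and concentrations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cells as cells_mod
from .quant_calibration import (
    CalibrationCurve,
    CalibrationPoint,
    ImpurityMatrix,
    back_calculate,
    calibrate_analyte,
    corrected_channel_eics,
    lod_loq,
    normalize_to_is,
    repeatability_rsd,
    target_areas,
)
from .reporter_extraction import estimate_noise
from .synthetic_data import AnalyteSpec, SimulatedRun


def extract_run_areas(
    run: SimulatedRun, impurity: ImpurityMatrix, tol_mda: float = 5.0
) -> pd.DataFrame:
    """Integrated, impurity-corrected reporter areas for every target and
    channel of one run, annotated with the channel's plex role."""
    rows = []
    for target_id in run.truth:
        areas = target_areas(run.scans, target_id, impurity, tol_mda=tol_mda)
        for ch, area in areas.items():
            role = run.plex.roles[ch]
            rows.append(
                {"run_id": run.plex.run_id, "target_id": target_id,
                 "channel": ch, "role": role.kind, "cell_id": role.cell_id,
                 "area": area}
            )
    return pd.DataFrame(rows)


def extract_areas(
    runs: list[SimulatedRun], impurity: ImpurityMatrix, tol_mda: float = 5.0
) -> pd.DataFrame:
    return pd.concat(
        [extract_run_areas(r, impurity, tol_mda) for r in runs], ignore_index=True
    )


def _is_areas(areas: pd.DataFrame) -> pd.DataFrame:
    """Per (run, analyte) internal-standard area from the IS transition."""
    is_rows = areas[
        areas["target_id"].str.endswith("__IS") & (areas["role"] == "is_blank")
    ].copy()
    is_rows["analyte"] = is_rows["target_id"].str.removesuffix("__IS")
    return is_rows.set_index(["run_id", "analyte"])["area"]


def analyte_responses(areas: pd.DataFrame) -> pd.DataFrame:
    """IS-normalized responses for every non-IS target/channel row.

    Rows whose IS area is nonpositive get a missing (NaN) response rather
    than a silent zero.
    """
    is_area = _is_areas(areas)
    main = areas[~areas["target_id"].str.endswith("__IS")].copy()
    responses = []
    for _, row in main.iterrows():
        try:
            ref = is_area.loc[(row["run_id"], row["target_id"])]
        except KeyError:
            responses.append(np.nan)
            continue
        resp = normalize_to_is(row["area"], ref)
        responses.append(np.nan if resp is None else resp)
    main["response"] = responses
    return main.rename(columns={"target_id": "analyte"})


def build_curves(
    areas: pd.DataFrame,
    design: pd.DataFrame,
    min_points: int = 5,
    loq_fmol: dict[str, float] | None = None,
) -> dict[str, CalibrationCurve]:
    """Fit one weighted calibration curve per analyte from a calibration
    design (analyte, level, nominal_fmol, channel, run_id).

    Replicate channels of a level are averaged into one calibration point,
    giving the paper-style one-point-per-level line.
    """
    responses = analyte_responses(areas)
    merged = design.merge(
        responses, on=["run_id", "channel", "analyte"], how="left"
    )
    curves = {}
    for analyte, sub in merged.groupby("analyte", sort=True):
        pts = [
            CalibrationPoint(x=float(x), y=float(sub2["response"].mean()))
            for x, sub2 in sub.dropna(subset=["response"]).groupby("nominal_fmol")
        ]
        loq = None if loq_fmol is None else loq_fmol.get(analyte)
        curves[analyte] = calibrate_analyte(
            pts, analyte, loq_fmol=loq, min_points=min_points
        )
    return curves


def quantify_cells(
    areas: pd.DataFrame,
    manifest: pd.DataFrame,
    curves: dict[str, CalibrationCurve],
) -> pd.DataFrame:
    """Back-calculate per-cell amounts and convert to concentrations.

    Returns the tidy frame of :func:`scamine.cells.cell_results`.
    """
    responses = analyte_responses(areas)
    cell_rows = responses[responses["role"] == "cell"].dropna(subset=["response"])
    rows = []
    for _, row in cell_rows.iterrows():
        curve = curves.get(row["analyte"])
        if curve is None:
            continue
        amount, flag = back_calculate(row["response"], curve)
        rows.append(
            {"run_id": row["run_id"], "channel": row["channel"],
             "analyte": row["analyte"], "amount_fmol": amount,
             "range_flag": flag}
        )
    return cells_mod.cell_results(manifest, pd.DataFrame(rows))


def analyte_lod_loq(
    run: SimulatedRun,
    spec: AnalyteSpec,
    impurity: ImpurityMatrix,
    channel: str,
    amount_fmol: float,
    tol_mda: float = 5.0,
) -> tuple[float, float]:
    """Measure LOD/LOQ (amol) for one analyte from a run with a known amount.

    Noise is the sample SD of the reporter trace on the peak-free right tail
    (beyond apex + 2·FWHM); the response is the apex height per amol in the
    given channel.  Requires at least 5 tail points, i.e. a wide enough
    elution window relative to the scan interval.
    """
    eics = corrected_channel_eics(run.scans, spec.name, impurity, tol_mda=tol_mda)
    e = eics[channel]
    if e.apex_rt is None or e.fwhm is None:
        raise ValueError(f"no quantifiable peak for {spec.name} in {channel}")
    lo = np.nextafter(e.apex_rt + 2 * e.fwhm, np.inf)
    hi = e.rt_span[1]
    noise = estimate_noise(e, (lo, hi))
    response_per_amol = e.apex_intensity / (amount_fmol * 1e3)
    return lod_loq(noise.sd_intensity, response_per_amol)


def repeatability_from_runs(
    runs: list[SimulatedRun],
    curves: dict[str, CalibrationCurve],
    impurity: ImpurityMatrix,
) -> dict[str, float]:
    """Repeatability RSD (%) per analyte from replicate-channel runs."""
    areas = extract_areas(runs, impurity)
    responses = analyte_responses(areas)
    out = {}
    for analyte, sub in responses[responses["role"] == "cell"].groupby("analyte"):
        curve = curves.get(analyte)
        if curve is None:
            continue
        amounts = [
            back_calculate(r, curve)[0] for r in sub["response"].dropna()
        ]
        out[analyte] = repeatability_rsd(amounts)
    return out
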