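import math

import numpy as np
import pytest

from scamine import ImpurityMatrix, SimConfig, default_plex, simulate_run_amounts
from scamine.reporter_extraction import Eic, eic_from_points
from scamine.synthetic_data import AnalyteSpec, LcPeak

# small panel for fast scan-level simulations
FAST_ANALYTES = (
    AnalyteSpec("cystine", "C6H12N2O4S2", n_labels=2, charge=2, lc=LcPeak(19.60, 0.15)),
    AnalyteSpec("valine", "C5H11NO2", lc=LcPeak(20.96, 0.18)),
)


def gaussian_trace(amplitude, sigma, center=10.0, step=0.02, span_sigmas=5.0):
    half = span_sigmas * sigma
    n = int(round(2 * half / step))
    rts = np.linspace(center - half, center + half, n + 1)
    ys = amplitude * np.exp(-((rts - center) ** 2) / (2 * sigma**2))
    return [(float(r), float(y)) for r, y in zip(rts, ys)]


@pytest.fixture
def gaussian_eic() -> Eic:
    return eic_from_points("t", "126", gaussian_trace(1000.0, 0.1))


@pytest.fixture(scope="session")
def noise_free_run():
    """One noise-free, identity-impurity run over the fast analyte panel with
    known per-channel amounts."""
    cfg = SimConfig(
        analytes=FAST_ANALYTES,
        noise_sd=0.0,
        noise_cv=0.0,
        impurity=ImpurityMatrix.identity(),
        rng_seed=0,
    )
    plex = default_plex("nf", [f"c{i}" for i in range(6)])
    amounts = {}
    for spec in FAST_ANALYTES:
        per = {ch: x for (ch, _), x in zip(plex.cell_channels,
                                           (0.012, 0.12, 1.2, 3.0, 12.0, 120.0))}
        per[plex.carrier_channel] = cfg.carrier_amount
        amounts[spec.name] = per
        amounts[spec.is_target_id] = {plex.is_blank_channel: cfg.is_amount}
    return simulate_run_amounts(plex, amounts, cfg), cfg
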