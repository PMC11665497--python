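"""TMT10plex channel definitions and exact-mass bookkeeping.

The ten TMT10plex reagents are isobaric: each adds the same nominal mass to a
primary amine, but the reporter cations released on HCD fragmentation differ by
their 13C/15N substitution pattern.  "N" and "C" isotopomers of the same nominal
reporter differ only by swapping a 15N for a 13C, i.e. by ~6.32 mDa, which is
what makes high-resolution MS2 detection mandatory.

All masses here are computed from elemental composition (via pyteomics) rather
than copied from vendor literature; reporter cation m/z subtracts the electron
mass and is stored to 5 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyteomics import mass as _pmass

ELECTRON_MASS = 0.000548579909  # Da
PROTON_MASS = _pmass.calculate_mass(formula="H") - ELECTRON_MASS

#: Reporter cation compositions.  The base cation is C8H16N+; channels append
#: 13C ("C[13]") and 15N ("N[15]") substitutions.  Order = increasing m/z.
_REPORTER_FORMULAS = {
    "126": "C8H16N",
    "127N": "C8H16N[15]",
    "127C": "C[13]C7H16N",
    "128N": "C[13]C7H16N[15]",
    "128C": "C[13]2C6H16N",
    "129N": "C[13]2C6H16N[15]",
    "129C": "C[13]3C5H16N",
    "130N": "C[13]3C5H16N[15]",
    "130C": "C[13]4C4H16N",
    "131": "C[13]4C4H16N[15]",
}

CHANNEL_NAMES: tuple[str, ...] = tuple(_REPORTER_FORMULAS)

#: Monoisotopic mass added to each labeled amine by a TMT10plex tag
#: (composition C8 13C4 H20 N 15N O2; identical for every channel — isobaric).
TMT10_TAG_MASS = _pmass.calculate_mass(formula="C[13]4C8H20N[15]NO2")


def reporter_mz(name: str) -> float:
    """Exact m/z of a channel's reporter cation, to 5 decimals."""
    m = _pmass.calculate_mass(formula=_REPORTER_FORMULAS[name]) - ELECTRON_MASS
    return round(m, 5)


@dataclass(frozen=True)
class Channel:
    """One TMT10plex isotopomer channel."""

    name: str
    reporter_mz: float

    def __post_init__(self) -> None:
        if self.name not in _REPORTER_FORMULAS:
            raise ValueError(f"unknown TMT10plex channel {self.name!r}")


CHANNELS: tuple[Channel, ...] = tuple(
    Channel(name, reporter_mz(name)) for name in CHANNEL_NAMES
)

REPORTER_MZ: dict[str, float] = {c.name: c.reporter_mz for c in CHANNELS}


def min_reporter_spacing_mda() -> float:
    """Smallest gap between adjacent reporter masses, in mDa (~6.32)."""
    mzs = [c.reporter_mz for c in CHANNELS]
    return min(b - a for a, b in zip(mzs, mzs[1:])) * 1000.0


def labeled_precursor_mz(neutral_mass: float, n_labels: int, charge: int) -> float:
    """m/z of an [M + n_labels·TMT10 + charge·H]^charge+ ion."""
    if n_labels < 1 or charge < 1:
        raise ValueError("n_labels and charge must be >= 1")
    return (neutral_mass + n_labels * TMT10_TAG_MASS + charge * PROTON_MASS) / charge
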