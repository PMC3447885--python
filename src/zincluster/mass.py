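"""Neutral-mass arithmetic and metal-binding stoichiometry from native ESI-MS.

Native electrospray of a folded metalloprotein preserves non-covalently bound
metal ions, so the neutral monoisotopic mass read off a charge-state series
reports directly on how many metals are bound.  Two conventions are supported
for charge deconvolution:

``nominal`` mode
    The monoisotopic m/z is multiplied by the charge and the integer charge
    is subtracted (charge-carrier mass 1.0 Da per proton), and a divalent
    metal adduct adds its neutral isotope mass minus the charge it carries
    (e.g. 64Zn: 63.929 - 2 = 61.929 Da per Zn2+).  This is the convention
    widely used for manual deconvolution of Q-TOF data.

``accurate`` mode
    The proton mass 1.007276 Da is used as the charge carrier and the metal
    adduct subtracts only the electron masses actually displaced.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.SeqUtils import molecular_weight

from .errors import InvalidPeakError, SequenceParseError

#: CODATA electron mass in daltons.
ELECTRON_MASS = 5.48579909065e-4

#: Accurate proton mass (Da) for the ``accurate`` charge-carrier mode.
PROTON_MASS = 1.007276

_CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MetalSpec:
    """A metal ion species used for adduct arithmetic.

    ``isotope_mass`` is the monoisotopic mass of the *neutral* atom in Da;
    ``charge`` is the positive charge of the ion.
    """

    name: str
    isotope_mass: float
    charge: int

    def __post_init__(self) -> None:
        if self.isotope_mass <= 0:
            raise ValueError(f"isotope_mass must be positive, got {self.isotope_mass}")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")


#: Zn2+ built from the 64Zn monoisotope.
ZN64 = MetalSpec("Zn", 63.929, 2)
#: Cd2+ built from the 113Cd NMR-active isotope (used for Cd-substituted protein).
CD113 = MetalSpec("Cd", 112.904408, 2)

METALS = {"Zn": ZN64, "Cd": CD113}


@dataclass(frozen=True)
class MassPeak:
    """A monoisotopic peak from a positive-mode charge-state series."""

    mz: float
    z: int
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.z < 1:
            raise InvalidPeakError(f"invalid peak: mz={self.mz}, z={self.z}")


@dataclass(frozen=True)
class StoichiometryResult:
    """Best-matching metal count for an observed neutral mass."""

    n_metals: int
    predicted_mass: float
    residual: float
    within_tolerance: bool


def neutral_mass_from_peak(peak: MassPeak, charge_carrier_mass: float = 1.0) -> float:
    """Neutral monoisotopic mass from one peak: ``mz*z - z*charge_carrier_mass``.

    ``charge_carrier_mass`` is 1.0 in nominal mode and 1.007276
    (:data:`PROTON_MASS`) in accurate mode.
    """
    if peak.mz <= 0 or peak.z < 1:
        raise InvalidPeakError(f"invalid peak: mz={peak.mz}, z={peak.z}")
    return peak.mz * peak.z - peak.z * charge_carrier_mass


def metal_adduct_mass(
    apo_mass: float, n: int, metal: MetalSpec, mode: str = "nominal"
) -> float:
    """Mass of the apo species plus ``n`` bound metal ions.

    In ``nominal`` mode each M(z+) adds ``isotope_mass - charge`` (the bound ion
    displaces ``charge`` protons, counted at 1 Da each); in ``accurate`` mode
    only the electron deficit of the ion itself is subtracted.
    """
    if n < 0:
        raise ValueError(f"metal count must be non-negative, got {n}")
    if mode == "nominal":
        per_metal = metal.isotope_mass - metal.charge
    elif mode == "accurate":
        per_metal = metal.isotope_mass - metal.charge * ELECTRON_MASS
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'nominal' or 'accurate'")
    return apo_mass + n * per_metal


def infer_stoichiometry(
    observed_mass: float,
    apo_mass: float,
    metal: MetalSpec,
    n_max: int = 6,
    tolerance: float = 0.5,
    mode: str = "nominal",
) -> StoichiometryResult:
    """Metal count in ``[0, n_max]`` whose adduct mass best matches the observation.

    Ties are broken toward smaller n (parsimony); a best match outside
    ``tolerance`` is returned flagged, not raised.
    """
    if n_max < 0:
        raise ValueError(f"n_max must be >= 0, got {n_max}")
    if tolerance <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance}")
    best_n, best_pred, best_res = 0, apo_mass, abs(observed_mass - apo_mass)
    for n in range(1, n_max + 1):
        pred = metal_adduct_mass(apo_mass, n, metal, mode=mode)
        res = abs(observed_mass - pred)
        if res < best_res:
            best_n, best_pred, best_res = n, pred, res
    return StoichiometryResult(
        n_metals=best_n,
        predicted_mass=best_pred,
        residual=best_res,
        within_tolerance=best_res <= tolerance,
    )


def sequence_monoisotopic_mass(sequence: str) -> float:
    """Monoisotopic mass of a peptide: residue masses plus one water.

    Only the 20 canonical one-letter codes are accepted; an unknown letter
    raises :class:`SequenceParseError` carrying its 0-based position.
    """
    if not sequence:
        raise SequenceParseError("empty sequence")
    seq = sequence.upper()
    for i, letter in enumerate(seq):
        if letter not in _CANONICAL_AA:
            raise SequenceParseError(
                f"unknown amino-acid letter {letter!r} at position {i}", position=i
            )
    return molecular_weight(seq, seq_type="protein", monoisotopic=True)


def read_peak_csv(path: str | Path) -> list[MassPeak]:
    """Read a peak list with columns ``mz`` and ``z``."""
    df = pd.read_csv(path)
    missing = {"mz", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"peak list missing columns: {sorted(missing)}")
    return [MassPeak(mz=float(r.mz), z=int(r.z)) for r in df.itertuples()]
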