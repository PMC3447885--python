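"""NOE restraint bookkeeping and metal-coordination restraint generation.

Covers the accounting side of an NMR structure determination: range
classification of distance restraints (intra-residue, sequential, medium,
long, ambiguous), restraint density per residue, volume-to-distance
calibration with the standard NOE ``V ∝ d^-6`` relation, and generation of
bond/angle restraints that hold a tetrahedral metal site together during
refinement (M-S 2.3 A bonds, S-M-S 109.5 deg angles by default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .connectivity import Assignment

#: Default clamp window (Angstrom) for calibrated NOE upper bounds.
DEFAULT_CLAMP = (2.2, 6.0)

#: Default metal-site restraint targets.
DEFAULT_BOND_LENGTH = 2.3
DEFAULT_BOND_ANGLE = 109.5

NOE_CATEGORIES = ("intra", "sequential", "medium", "long", "ambiguous")


@dataclass(frozen=True)
class DistanceRestraint:
    """One NOE-derived upper-bound restraint between two protons."""

    res_i: int
    atom_i: str
    res_j: int
    atom_j: str
    upper: float
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.upper <= 0:
            raise ValueError(f"upper bound must be positive, got {self.upper}")


@dataclass(frozen=True)
class CoordinationRestraint:
    """A bond (2 atoms) or angle (3 atoms) restraint for a metal site.

    Atoms are ``("M", label)`` for a metal or ``(residue, atom_name)`` for a
    ligand donor.
    """

    kind: str  # "bond" | "angle"
    atoms: tuple
    target: float

    def __post_init__(self) -> None:
        if self.kind not in ("bond", "angle"):
            raise ValueError(f"kind must be bond or angle, got {self.kind!r}")
        n = 2 if self.kind == "bond" else 3
        if len(self.atoms) != n:
            raise ValueError(f"{self.kind} restraint needs {n} atoms")
        if self.kind == "bond" and self.target <= 0:
            raise ValueError("bond target must be positive")
        if self.kind == "angle" and not 0 < self.target < 180:
            raise ValueError("angle target must be in (0, 180)")


def classify_noe(restraints: Iterable[DistanceRestraint]) -> dict[str, int]:
    """Count restraints per range category.

    Ambiguous restraints are counted only under ``ambiguous``; the rest by
    sequence separation |i-j|: 0 intra, 1 sequential, 2-4 medium, >=5 long.
    The five categories partition the list.
    """
    counts = dict.fromkeys(NOE_CATEGORIES, 0)
    for r in restraints:
        if r.ambiguous:
            counts["ambiguous"] += 1
            continue
        sep = abs(r.res_i - r.res_j)
        if sep == 0:
            counts["intra"] += 1
        elif sep == 1:
            counts["sequential"] += 1
        elif sep <= 4:
            counts["medium"] += 1
        else:
            counts["long"] += 1
    return counts


def restraint_density(total_restraints: int, n_residues: int) -> tuple[float, int]:
    """Restraints per residue and its nearest-integer rounding (half-to-even).

    The residue count conventionally covers the construct span
    (last - first + 1), not just assigned residues.
    """
    if n_residues <= 0:
        raise ValueError(f"n_residues must be positive, got {n_residues}")
    density = total_restraints / n_residues
    return density, round(density)


@dataclass
class CalibrationResult:
    upper_bounds: list[float | None]
    errors: list[tuple[int, str]]  # (peak index, message)


def calibrate_distances(
    peak_volumes: Sequence[float],
    reference: tuple[float, float],
    clamp: tuple[float, float] = DEFAULT_CLAMP,
) -> CalibrationResult:
    """Upper distance bounds from NOE peak volumes via ``d = d_ref (V_ref/V)^(1/6)``.

    The sixth-root form follows the isolated spin-pair approximation
    ``V ∝ d^-6``.  Results are clamped to the ``clamp`` window; non-positive
    volumes produce per-peak error records (``None`` bounds), not exceptions.
    """
    v_ref, d_ref = reference
    if v_ref <= 0 or d_ref <= 0:
        raise ValueError("reference volume and distance must be positive")
    lo, hi = clamp
    bounds: list[float | None] = []
    errors: list[tuple[int, str]] = []
    for i, v in enumerate(peak_volumes):
        if v <= 0:
            bounds.append(None)
            errors.append((i, f"non-positive peak volume {v}"))
            continue
        d = d_ref * (v_ref / v) ** (1.0 / 6.0)
        bounds.append(min(max(d, lo), hi))
    return CalibrationResult(upper_bounds=bounds, errors=errors)


def build_metal_restraints(
    a: Assignment,
    bond: float = DEFAULT_BOND_LENGTH,
    angle: float = DEFAULT_BOND_ANGLE,
    donor_atom: str = "SG",
) -> list[CoordinationRestraint]:
    """Bond and angle restraints enforcing tetrahedral metal coordination.

    One bond per metal-ligand edge and one donor-metal-donor angle per
    unordered ligand pair within each metal (C(k,2) angles for coordination
    number k).
    """
    out: list[CoordinationRestraint] = []
    for m, l in sorted(a.edges):
        out.append(
            CoordinationRestraint("bond", (("M", m), (l, donor_atom)), bond)
        )
    for m in a.metal_labels():
        ligs = sorted(a.metal_ligands(m))
        for i in range(len(ligs)):
            for j in range(i + 1, len(ligs)):
                out.append(
                    CoordinationRestraint(
                        "angle",
                        ((ligs[i], donor_atom), ("M", m), (ligs[j], donor_atom)),
                        angle,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# I/O: tabular format and a CNS/XPLOR-style "assign" dialect


def read_restraint_tsv(path: str | Path) -> list[DistanceRestraint]:
    """Read restraints from TSV columns res_i, atom_i, res_j, atom_j, upper, ambiguous."""
    df = pd.read_csv(path, sep="\t")
    required = {"res_i", "atom_i", "res_j", "atom_j", "upper"}
    if not required <= set(df.columns):
        raise ValueError(f"restraint table needs columns {sorted(required)}")
    out = []
    for r in df.itertuples():
        amb = bool(getattr(r, "ambiguous", False))
        out.append(
            DistanceRestraint(
                int(r.res_i), str(r.atom_i), int(r.res_j), str(r.atom_j),
                float(r.upper), amb,
            )
        )
    return out


def write_restraint_tsv(restraints: Iterable[DistanceRestraint], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.res_i, r.atom_i, r.res_j, r.atom_j, r.upper, r.ambiguous)
            for r in restraints
        ],
        columns=["res_i", "atom_i", "res_j", "atom_j", "upper", "ambiguous"],
    )
    df.to_csv(path, sep="\t", index=False)


_ASSIGN_RE = re.compile(
    r"assign\s*\(\s*resid\s+(\d+)\s+and\s+name\s+(\S+?)\s*\)"
    r"\s*\(\s*resid\s+(\d+)\s+and\s+name\s+(\S+?)\s*\)"
    r"\s+([\d.]+)\s+([\d.]+)\s+([\d.]+)",
    re.IGNORECASE,
)


def read_xplor_assign(text: str) -> list[DistanceRestraint]:
    """Parse simple CNS/XPLOR ``assign (resid i and name A) (resid j and name B) d dminus dplus``
    statements; the upper bound is ``d + dplus``.  Statements with OR clauses
    (multiple selections) are flagged ambiguous."""
    out = []
    for stmt in re.split(r"(?=assign)", text, flags=re.IGNORECASE):
        stmt = stmt.strip()
        if not stmt.lower().startswith("assign"):
            continue
        m = _ASSIGN_RE.match(stmt)
        if not m:
            continue
        ri, ai, rj, aj, d, _dm, dp = m.groups()
        ambiguous = bool(re.search(r"\bor\b", stmt, re.IGNORECASE))
        out.append(
            DistanceRestraint(
                int(ri), ai.upper(), int(rj), aj.upper(),
                float(d) + float(dp), ambiguous,
            )
        )
    return out


def write_xplor_coordination(restraints: Iterable[CoordinationRestraint]) -> str:
    """Emit coordination restraints in a CNS-style dialect (bonds only; angles
    as comment-annotated statements, since angle syntax is engine-specific)."""

    def sel(atom: tuple) -> str:
        if atom[0] == "M":
            return f"(segid MET and resid {atom[1]} and name ZN)"
        return f"(resid {atom[0]} and name {atom[1]})"

    lines = []
    for r in restraints:
        if r.kind == "bond":
            lines.append(f"assign {sel(r.atoms[0])} {sel(r.atoms[1])} {r.target:.2f} 0.10 0.10")
        else:
            a, b, c = r.atoms
            lines.append(
                f"! angle {sel(a)} {sel(b)} {sel(c)} target {r.target:.1f} deg"
            )
    return "\n".join(lines) + "\n"


def write_coordination_csv(
    restraints: Iterable[CoordinationRestraint], path: str | Path
) -> None:
    rows = []
    for r in restraints:
        atoms = ";".join("/".join(str(x) for x in a) for a in r.atoms)
        rows.append((r.kind, atoms, r.target))
    pd.DataFrame(rows, columns=["kind", "atoms", "target"]).to_csv(path, index=False)
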