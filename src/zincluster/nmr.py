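"""Per-residue derived NMR observables.

Three standard read-outs used to characterize a metalloprotein fold without
any spectral processing:

* chemical-shift perturbation (CSP) between two conditions (e.g. Zn-loaded vs
  Cd-substituted protein), reported per nucleus and signed;
* steady-state heteronuclear NOE from saturated/reference intensity pairs,
  with errors propagated from the spectrum background noise;
* amide-proton H/D-exchange protection classes from intensity decays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyOverlapError

#: Conventional 15N weight for composite 1H/15N shift distances.
DEFAULT_N_WEIGHT = 0.154

#: Default detection floor: intensity must exceed 3x the background noise.
DEFAULT_THRESHOLD_MULTIPLE = 3.0

#: Protection-class boundary times in minutes (first spectrum, 2 h, 24 h).
DEFAULT_CLASS_TIMES = (0.0, 120.0, 1440.0)


@dataclass
class ShiftTable:
    """Chemical shifts under one condition; (residue, nucleus) keys are unique."""

    data: pd.DataFrame  # columns: residue, nucleus, shift
    condition: str = ""

    def __post_init__(self) -> None:
        required = {"residue", "nucleus", "shift"}
        if not required <= set(self.data.columns):
            raise ValueError(f"shift table needs columns {sorted(required)}")
        dup = self.data.duplicated(subset=["residue", "nucleus"])
        if dup.any():
            bad = self.data[dup][["residue", "nucleus"]].iloc[0]
            raise ValueError(
                f"duplicate (residue, nucleus) key: ({bad.residue}, {bad.nucleus})"
            )

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[int, str, float]], condition: str = ""
    ) -> "ShiftTable":
        return cls(
            pd.DataFrame(records, columns=["residue", "nucleus", "shift"]),
            condition=condition,
        )

    @classmethod
    def from_csv(cls, path: str | Path, condition: str = "") -> "ShiftTable":
        return cls(pd.read_csv(path), condition=condition)


@dataclass
class IntensityTable:
    """Peak intensities (arbitrary units) with a background noise level.

    Rows carry ``residue`` and ``intensity``; a ``time`` column (minutes) is
    present for decay series and absent/ignored for single-condition tables.
    """

    data: pd.DataFrame
    noise_level: float

    def __post_init__(self) -> None:
        if self.noise_level <= 0:
            raise ValueError(f"noise_level must be positive, got {self.noise_level}")
        required = {"residue", "intensity"}
        if not required <= set(self.data.columns):
            raise ValueError(f"intensity table needs columns {sorted(required)}")
        if not np.isfinite(self.data["intensity"].to_numpy(dtype=float)).all():
            raise ValueError("intensities must be finite")

    @classmethod
    def from_csv(cls, path: str | Path, noise_level: float) -> "IntensityTable":
        return cls(pd.read_csv(path), noise_level=noise_level)


@dataclass
class CSPResult:
    """Signed per-nucleus shift differences, with unmatched keys listed."""

    table: pd.DataFrame  # columns: residue, nucleus, delta
    only_in_a: list[tuple[int, str]] = field(default_factory=list)
    only_in_b: list[tuple[int, str]] = field(default_factory=list)


def chemical_shift_perturbation(a: ShiftTable, b: ShiftTable) -> CSPResult:
    """Signed shift change per (residue, nucleus): ``delta = shift_b - shift_a``.

    Keys present in only one table are reported as missing, never imputed as
    zero.  Raises :class:`EmptyOverlapError` when the tables share no keys.
    """
    merged = a.data.merge(
        b.data, on=["residue", "nucleus"], how="outer", suffixes=("_a", "_b"),
        indicator=True,
    )
    both = merged[merged["_merge"] == "both"]
    if both.empty:
        raise EmptyOverlapError(
            f"no shared (residue, nucleus) keys between {a.condition!r} and {b.condition!r}"
        )
    table = both[["residue", "nucleus"]].copy()
    table["delta"] = (both["shift_b"] - both["shift_a"]).to_numpy()
    table = table.sort_values(["residue", "nucleus"]).reset_index(drop=True)
    only_a = [
        (int(r.residue), str(r.nucleus))
        for r in merged[merged["_merge"] == "left_only"].itertuples()
    ]
    only_b = [
        (int(r.residue), str(r.nucleus))
        for r in merged[merged["_merge"] == "right_only"].itertuples()
    ]
    return CSPResult(table=table, only_in_a=only_a, only_in_b=only_b)


def csp_summary(csp: CSPResult, nuclei: Sequence[str] | None = None) -> dict[str, float]:
    """Mean and max of ``|delta|``, optionally restricted to given nuclei."""
    t = csp.table
    if nuclei is not None:
        t = t[t["nucleus"].isin(list(nuclei))]
    mags = t["delta"].abs()
    return {"mean_abs": float(mags.mean()), "max_abs": float(mags.max())}


def composite_shift_distance(
    csp: CSPResult, h_nucleus: str = "H", n_nucleus: str = "N",
    n_weight: float = DEFAULT_N_WEIGHT,
) -> pd.DataFrame:
    """Optional composite 1H/15N distance: sqrt(ddH^2 + (w*ddN)^2) per residue.

    Off the main path -- the per-nucleus signed report is the default output.
    """
    t = csp.table
    h = t[t["nucleus"] == h_nucleus].set_index("residue")["delta"]
    n = t[t["nucleus"] == n_nucleus].set_index("residue")["delta"]
    shared = h.index.intersection(n.index)
    comp = np.sqrt(h.loc[shared] ** 2 + (n_weight * n.loc[shared]) ** 2)
    return pd.DataFrame({"residue": shared, "composite": comp.to_numpy()})


def heteronuclear_noe(
    saturated: IntensityTable, reference: IntensityTable
) -> pd.DataFrame:
    """Steady-state heteronuclear NOE per residue: ``I_sat / I_ref``.

    Error propagation from the common background noise sigma:
    ``err = |NOE| * sqrt((sigma/I_sat)^2 + (sigma/I_ref)^2)``.  A zero
    reference intensity yields a row flagged undefined, not an exception.
    The two tables may carry different noise levels; each intensity is
    propagated with its own table's sigma.
    """
    sat = saturated.data.set_index("residue")["intensity"]
    ref = reference.data.set_index("residue")["intensity"]
    shared = sat.index.intersection(ref.index)
    if shared.empty:
        raise EmptyOverlapError("no shared residues between saturated and reference")
    rows = []
    for res in shared:
        i_sat, i_ref = float(sat.loc[res]), float(ref.loc[res])
        if i_ref == 0.0:
            rows.append((int(res), np.nan, np.nan, False))
            continue
        noe = i_sat / i_ref
        if i_sat == 0.0:
            err = saturated.noise_level / abs(i_ref)
        else:
            err = abs(noe) * np.sqrt(
                (saturated.noise_level / i_sat) ** 2
                + (reference.noise_level / i_ref) ** 2
            )
        rows.append((int(res), noe, err, True))
    return pd.DataFrame(rows, columns=["residue", "noe", "error", "defined"])


@dataclass
class HdxResult:
    """Protection classification of amide protons after dissolution in D2O."""

    per_residue: pd.DataFrame  # residue, last_detected_time, protection_class
    counts: dict[float, int]  # detected count at each class-boundary time
    counts_per_timepoint: dict[float, int]  # detected count at every timepoint


def hdx_classify(
    decays: IntensityTable,
    timepoints: Sequence[float],
    threshold_multiple: float = DEFAULT_THRESHOLD_MULTIPLE,
    class_times: Sequence[float] = DEFAULT_CLASS_TIMES,
) -> HdxResult:
    """Classify residues by how long their amide proton resists H/D exchange.

    A residue is detected at time t iff its intensity exceeds
    ``threshold_multiple * noise_level``.  The protection class is the last
    class-boundary time at which the residue is still detected (boundaries
    default to the first spectrum, 2 h and 24 h); intermediate timepoints are
    retained in the per-timepoint counts but do not define classes.
    """
    timepoints = [float(t) for t in timepoints]
    if any(b <= a for a, b in zip(timepoints, timepoints[1:])):
        raise ValueError(f"timepoints must be strictly increasing: {timepoints}")
    if threshold_multiple <= 0:
        raise ValueError("threshold_multiple must be positive")
    class_times = [t for t in class_times if t in timepoints] or list(timepoints)
    thr = threshold_multiple * decays.noise_level
    if "time" not in decays.data.columns:
        raise ValueError("decay table needs a 'time' column")
    piv = decays.data.pivot_table(
        index="residue", columns="time", values="intensity", aggfunc="first"
    )
    rows = []
    counts_tp = {t: 0 for t in timepoints}
    counts_cls = {t: 0 for t in class_times}
    for res in piv.index:
        detected = []
        for t in timepoints:
            val = piv.loc[res].get(t, np.nan)
            is_det = bool(np.isfinite(val) and val > thr)
            if is_det:
                detected.append(t)
                counts_tp[t] += 1
        last = detected[-1] if detected else None
        cls = None
        for t in class_times:
            if t in detected:
                cls = t
                counts_cls[t] += 1
        rows.append((int(res), last, cls))
    per_residue = pd.DataFrame(
        rows, columns=["residue", "last_detected_time", "protection_class"]
    )
    return HdxResult(
        per_residue=per_residue, counts=counts_cls, counts_per_timepoint=counts_tp
    )
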