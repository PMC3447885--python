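"""Completion of partial metal-to-ligand connectivity maps by constraint satisfaction.

1H-113Cd correlation experiments identify which cysteine (or histidine) side
chains coordinate which metal ion, but weak three-bond couplings routinely
leave some metal-ligand edges unobserved.  Given the observed (confirmed)
edges, the coordination number of each metal, a per-ligand degree bound, the
total number of bridging ligands and -- when available -- metal-metal
scalar-coupling evidence (two metals coupled through a shared bridging
thiolate), the completions of the map are exactly enumerable.  Structure-based
violation scores supplied by the caller then rank the candidates, as done when
trial coordination restraints are checked against independently derived NOE
restraints in a refinement.

Edges are ``(metal_label, ligand_position)`` pairs; ligand positions are
1-based residue numbers in full-length numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import InfeasibleConnectivityError, MissingScoreError

Edge = tuple[str, int]

#: 113Cd chemical shifts (ppm, vs 1 M cadmium acetate) of the three metal
#: spins in the Cd-substituted MSL2 CXC domain.
MSL2_CD_SHIFTS = {"Cd-A": 734.2, "Cd-B": 740.2, "Cd-C": 746.6}


@dataclass(frozen=True)
class MetalSpin:
    """A metal ion observed as an NMR spin (e.g. one 113Cd resonance)."""

    label: str
    chemical_shift: float | None = None
    coordination_number: int = 4

    def __post_init__(self) -> None:
        if self.coordination_number < 2:
            raise ValueError(
                f"coordination_number must be >= 2, got {self.coordination_number}"
            )


@dataclass(frozen=True)
class CouplingPair:
    """Evidence that two metals share a bridging ligand (e.g. 2J Cd-Cd splitting)."""

    metal_a: str
    metal_b: str
    evidence: str = "2J_Cd-Cd"

    def as_set(self) -> frozenset[str]:
        return frozenset((self.metal_a, self.metal_b))


@dataclass(frozen=True)
class Assignment:
    """A complete metal-to-ligand map; bridging ligands have degree 2."""

    edges: frozenset[Edge]

    def metal_labels(self) -> tuple[str, ...]:
        return tuple(sorted({m for m, _ in self.edges}))

    def ligand_positions(self) -> tuple[int, ...]:
        return tuple(sorted({l for _, l in self.edges}))

    def metal_ligands(self, label: str) -> frozenset[int]:
        return frozenset(l for m, l in self.edges if m == label)

    def ligand_degree(self, position: int) -> int:
        return sum(1 for _, l in self.edges if l == position)

    @property
    def bridging_ligands(self) -> frozenset[int]:
        return frozenset(
            l for l in self.ligand_positions() if self.ligand_degree(l) >= 2
        )

    @property
    def terminal_ligands(self) -> frozenset[int]:
        return frozenset(
            l for l in self.ligand_positions() if self.ligand_degree(l) == 1
        )


#: The final MSL2 CXC Zn3Cys9 assignment: metals A/B/C each tetrahedral, with
#: Cys525, Cys539 and Cys553 bridging two metals each.
MSL2_ASSIGNMENT = Assignment(
    edges=frozenset(
        [("A", 525), ("A", 527), ("A", 539), ("A", 544),
         ("B", 525), ("B", 546), ("B", 553), ("B", 556),
         ("C", 539), ("C", 553), ("C", 558), ("C", 561)]
    )
)


@dataclass
class ConnectivityDataset:
    """Input to the completion solver.

    ``n_bridging="auto"`` resolves to ``sum(coordination numbers) - n_ligands``,
    i.e. every ligand is used and the surplus coordination is carried by
    degree-2 bridges.
    """

    metals: list[MetalSpin]
    ligands: list[int]
    confirmed_edges: set[Edge] = field(default_factory=set)
    coupling_pairs: list[CouplingPair] = field(default_factory=list)
    max_ligand_degree: int = 2
    n_bridging: int | str = "auto"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        labels = {m.label for m in self.metals}
        if len(labels) != len(self.metals):
            raise InfeasibleConnectivityError("duplicate metal labels")
        ligset = set(self.ligands)
        for m, l in self.confirmed_edges:
            if m not in labels or l not in ligset:
                raise InfeasibleConnectivityError(
                    f"confirmed edge ({m}, {l}) outside metals x ligands"
                )
        for spin in self.metals:
            deg = sum(1 for m, _ in self.confirmed_edges if m == spin.label)
            if deg > spin.coordination_number:
                raise InfeasibleConnectivityError(
                    f"metal {spin.label} has {deg} confirmed edges, "
                    f"exceeding coordination number {spin.coordination_number}"
                )
        for l in ligset:
            deg = sum(1 for _, lig in self.confirmed_edges if lig == l)
            if deg > self.max_ligand_degree:
                raise InfeasibleConnectivityError(
                    f"ligand {l} has {deg} confirmed edges, "
                    f"exceeding max degree {self.max_ligand_degree}"
                )
        for cp in self.coupling_pairs:
            if cp.metal_a not in labels or cp.metal_b not in labels:
                raise InfeasibleConnectivityError(
                    f"coupling pair ({cp.metal_a}, {cp.metal_b}) names unknown metal"
                )

    def resolved_n_bridging(self) -> int | None:
        if self.n_bridging == "auto":
            total = sum(m.coordination_number for m in self.metals)
            return total - len(self.ligands)
        if self.n_bridging is None:
            return None
        return int(self.n_bridging)


def enumerate_assignments(data: ConnectivityDataset) -> list[Assignment]:
    """All completions of the confirmed edges satisfying every constraint.

    Constraints: each metal reaches exactly its coordination number; each
    ligand has degree in [1, max_ligand_degree]; the number of degree-2
    (bridging) ligands equals ``n_bridging``; each coupled metal pair shares
    exactly one ligand.  Output order is lexicographic by the sorted tuple of
    added edges, so results are reproducible.
    """
    data.validate()
    metals = list(data.metals)
    ligands = sorted(data.ligands)
    n_bridging = data.resolved_n_bridging()
    if n_bridging is not None and n_bridging < 0:
        raise InfeasibleConnectivityError(
            "total coordination smaller than ligand count: no feasible assignment"
        )

    degrees = {l: 0 for l in ligands}
    for _, l in data.confirmed_edges:
        degrees[l] += 1

    need = {}
    for spin in metals:
        deg = sum(1 for m, _ in data.confirmed_edges if m == spin.label)
        need[spin.label] = spin.coordination_number - deg

    results: list[tuple[tuple[Edge, ...], Assignment]] = []

    def finish(edges: frozenset[Edge], added: tuple[Edge, ...]) -> None:
        degs = {l: 0 for l in ligands}
        for _, l in edges:
            degs[l] += 1
        if any(d == 0 for d in degs.values()):
            return
        n_bridge = sum(1 for d in degs.values() if d >= 2)
        if n_bridging is not None and n_bridge != n_bridging:
            return
        for cp in data.coupling_pairs:
            shared = {l for m, l in edges if m == cp.metal_a} & {
                l for m, l in edges if m == cp.metal_b
            }
            if len(shared) != 1:
                return
        results.append((tuple(sorted(added)), Assignment(edges=edges)))

    def recurse(i: int, degs: dict[int, int], edges: set[Edge], added: list[Edge]) -> None:
        if i == len(metals):
            finish(frozenset(edges), tuple(added))
            return
        label = metals[i].label
        want = need[label]
        avail = [
            l
            for l in ligands
            if degs[l] < data.max_ligand_degree and (label, l) not in edges
        ]
        for combo in combinations(avail, want):
            new_edges = [(label, l) for l in combo]
            for l in combo:
                degs[l] += 1
            edges.update(new_edges)
            added.extend(new_edges)
            recurse(i + 1, degs, edges, added)
            for l in combo:
                degs[l] -= 1
            edges.difference_update(new_edges)
            del added[-len(new_edges):]

    recurse(0, degrees, set(data.confirmed_edges), [])
    results.sort(key=lambda pair: pair[0])
    # distinct added-edge tuples can never give equal assignments, but dedupe
    # defensively by edge set
    seen: set[frozenset[Edge]] = set()
    out = []
    for _, a in results:
        if a.edges not in seen:
            seen.add(a.edges)
            out.append(a)
    return out


def classify_ligands(a: Assignment) -> tuple[frozenset[int], frozenset[int]]:
    """Partition ligands into (terminal, bridging) by coordination degree."""
    return a.terminal_ligands, a.bridging_ligands


@dataclass(frozen=True)
class RankedCandidate:
    assignment: Assignment
    violations: int
    selected: bool
    ambiguous: bool = False


def rank_by_violations(
    candidates: Iterable[Assignment], scores: Mapping[Assignment, int]
) -> list[RankedCandidate]:
    """Order candidates by externally supplied violation count (ascending).

    Ties keep input order.  A *unique* zero-violation candidate is flagged
    ``selected``; multiple zero-violation candidates are flagged ``ambiguous``
    and none is selected.
    """
    candidates = list(candidates)
    for c in candidates:
        if c not in scores:
            raise MissingScoreError(
                f"no violation score for candidate with edges {sorted(c.edges)}"
            )
    ordered = sorted(candidates, key=lambda c: scores[c])
    zero = [c for c in candidates if scores[c] == 0]
    unique_zero = zero[0] if len(zero) == 1 else None
    return [
        RankedCandidate(
            assignment=c,
            violations=scores[c],
            selected=c is unique_zero,
            ambiguous=scores[c] == 0 and len(zero) > 1,
        )
        for c in ordered
    ]


def score_against_structure(
    assignment: Assignment,
    metal_xyz: Mapping[str, "tuple[float, float, float]"],
    ligand_xyz: Mapping[int, "tuple[float, float, float]"],
    bond_length: float = 2.3,
    threshold: float = 0.5,
) -> int:
    """Synthetic violation scorer: count edges whose metal-donor distance in a
    reference coordinate set deviates from ``bond_length`` by more than
    ``threshold`` (Angstrom).  Stands in for a refinement run in tests and
    examples; it is not a refinement."""
    import math

    n = 0
    for m, l in assignment.edges:
        (x1, y1, z1), (x2, y2, z2) = metal_xyz[m], ligand_xyz[l]
        d = math.dist((x1, y1, z1), (x2, y2, z2))
        if abs(d - bond_length) > threshold:
            n += 1
    return n


def read_connectivity_csv(
    connectivity_path: str | Path,
    coupling_path: str | Path | None = None,
    coordination_number: int = 4,
    max_ligand_degree: int = 2,
    n_bridging: int | str = "auto",
) -> ConnectivityDataset:
    """Build a dataset from CSV tables.

    Connectivity columns: ``metal, ligand_position, status`` with status
    ``confirmed`` or ``candidate`` (candidate rows only contribute the ligand
    to the pool).  Optional column ``chemical_shift``.  Coupling columns:
    ``metal_a, metal_b[, evidence]``.
    """
    df = pd.read_csv(connectivity_path)
    required = {"metal", "ligand_position", "status"}
    if not required <= set(df.columns):
        raise ValueError(f"connectivity table needs columns {sorted(required)}")
    shifts: dict[str, float] = {}
    if "chemical_shift" in df.columns:
        for r in df.itertuples():
            if pd.notna(r.chemical_shift):
                shifts[str(r.metal)] = float(r.chemical_shift)
    labels = sorted(df["metal"].dropna().astype(str).unique())
    labels = [l for l in labels if l and l.lower() != "nan"]
    metals = [
        MetalSpin(lbl, chemical_shift=shifts.get(lbl), coordination_number=coordination_number)
        for lbl in labels
    ]
    ligands = sorted(df["ligand_position"].astype(int).unique())
    confirmed = {
        (str(r.metal), int(r.ligand_position))
        for r in df.itertuples()
        if str(r.status).strip().lower() == "confirmed"
    }
    couplings: list[CouplingPair] = []
    if coupling_path is not None:
        cdf = pd.read_csv(coupling_path)
        for r in cdf.itertuples():
            evidence = str(getattr(r, "evidence", "2J_Cd-Cd"))
            couplings.append(CouplingPair(str(r.metal_a), str(r.metal_b), evidence))
    return ConnectivityDataset(
        metals=metals,
        ligands=ligands,
        confirmed_edges=confirmed,
        coupling_pairs=couplings,
        max_ligand_degree=max_ligand_degree,
        n_bridging=n_bridging,
    )


def candidates_to_table(candidates: Iterable[Assignment]) -> pd.DataFrame:
    """Tabulate candidates with per-metal ligand sets and bridging/terminal split."""
    rows = []
    for i, a in enumerate(candidates):
        terminal, bridging = classify_ligands(a)
        row: dict[str, object] = {"candidate": i}
        for m in a.metal_labels():
            row[f"ligands_{m}"] = ",".join(str(l) for l in sorted(a.metal_ligands(m)))
        row["bridging"] = ",".join(str(l) for l in sorted(bridging))
        row["terminal"] = ",".join(str(l) for l in sorted(terminal))
        rows.append(row)
    return pd.DataFrame(rows)
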