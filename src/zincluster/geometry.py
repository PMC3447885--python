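"""Structure-side analysis of metal-thiolate clusters.

Detects metal sites in coordinates, classifies terminal vs bridging ligands,
reduces a site to a renumbering-invariant topology fingerprint that can be
compared across structures, superposes clusters by least squares, computes
ensemble RMSD to the mean structure, and checks hydrogen-bond geometry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AtomLookupError, DegenerateGeometryError
from .pdbio import Model, StructureEnsemble

#: The ideal tetrahedral angle, arccos(-1/3); 109.5 deg at printed precision.
TETRAHEDRAL_ANGLE = math.degrees(math.acos(-1.0 / 3.0))

#: Elements treated as cluster metals.
METAL_ELEMENTS = ("Zn", "Cd")

#: Default metal-donor distance cutoffs per donor element (Angstrom).  Wider
#: than the 2.3 A restraint target to tolerate refinement scatter.
DEFAULT_DONOR_CUTOFFS = {"S": 2.9, "N": 2.5}

#: Donor atoms considered per residue type.  His is off by default: in the
#: MSL2 CXC domain the two histidines are non-conserved and not ligands.
CYS_DONORS = {"CYS": ("SG",)}
HIS_DONORS = {"HIS": ("ND1", "NE2")}


@dataclass(frozen=True)
class MetalAtom:
    element: str
    res_seq: int
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class LigandAtom:
    res_seq: int
    res_name: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass
class MetalSite:
    """One connected metal-ligand site: metals, donor atoms and bonds."""

    metals: list[MetalAtom]
    ligands: list[LigandAtom]
    bonds: list[tuple[int, int]]  # (metal index, ligand index)

    @property
    def bond_lengths(self) -> list[float]:
        return [
            float(np.linalg.norm(np.subtract(self.metals[i].xyz, self.ligands[j].xyz)))
            for i, j in self.bonds
        ]

    def ligand_degree(self, j: int) -> int:
        return sum(1 for _, lj in self.bonds if lj == j)

    @property
    def bridging_residues(self) -> frozenset[int]:
        return frozenset(
            self.ligands[j].res_seq
            for j in range(len(self.ligands))
            if self.ligand_degree(j) >= 2
        )

    @property
    def terminal_residues(self) -> frozenset[int]:
        return frozenset(
            self.ligands[j].res_seq
            for j in range(len(self.ligands))
            if self.ligand_degree(j) == 1
        )

    def atom_coords(self) -> np.ndarray:
        """Stacked coordinates: metals first, then ligand donors."""
        pts = [m.xyz for m in self.metals] + [l.xyz for l in self.ligands]
        return np.asarray(pts, dtype=float)


def detect_metal_sites(
    model: Model,
    donor_cutoffs: Mapping[str, float] | None = None,
    include_histidine: bool = False,
) -> list[MetalSite]:
    """Find metal-thiolate sites in one coordinate set.

    Metals are Zn/Cd atoms; donors are Cys SG (plus His ND1/NE2 when
    ``include_histidine``) within the per-element distance cutoff.  Metals
    sharing a donor are merged into one site.  A model without metals yields
    an empty list.
    """
    cutoffs = dict(DEFAULT_DONOR_CUTOFFS if donor_cutoffs is None else donor_cutoffs)
    donors_by_res = dict(CYS_DONORS)
    if include_histidine:
        donors_by_res.update(HIS_DONORS)

    df = model.atoms
    metal_rows = df[df["element"].isin(METAL_ELEMENTS)]
    donor_mask = [
        r.name in donors_by_res.get(r.res_name, ())
        for r in df.itertuples()
    ]
    donor_rows = df[donor_mask]
    if metal_rows.empty:
        return []

    metals = [
        MetalAtom(str(r.element), int(r.res_seq), (float(r.x), float(r.y), float(r.z)))
        for r in metal_rows.itertuples()
    ]
    donors = [
        LigandAtom(
            int(r.res_seq), str(r.res_name), str(r.name), str(r.element),
            (float(r.x), float(r.y), float(r.z)),
        )
        for r in donor_rows.itertuples()
    ]
    if donors:
        dmat = cdist(
            np.asarray([m.xyz for m in metals]),
            np.asarray([d.xyz for d in donors]),
        )
    else:
        dmat = np.zeros((len(metals), 0))

    bonds = []
    for i in range(len(metals)):
        for j in range(len(donors)):
            cut = cutoffs.get(donors[j].element)
            if cut is not None and dmat[i, j] <= cut:
                bonds.append((i, j))

    # union-find over metals: merge metals bonded to the same donor atom
    parent = list(range(len(metals)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    donor_to_metals: dict[int, list[int]] = {}
    for i, j in bonds:
        donor_to_metals.setdefault(j, []).append(i)
    for ms in donor_to_metals.values():
        for other in ms[1:]:
            union(ms[0], other)

    sites: list[MetalSite] = []
    for root in sorted({find(i) for i in range(len(metals))}):
        midx = [i for i in range(len(metals)) if find(i) == root]
        jidx = sorted({j for i, j in bonds if i in midx})
        mmap = {i: k for k, i in enumerate(midx)}
        jmap = {j: k for k, j in enumerate(jidx)}
        sites.append(
            MetalSite(
                metals=[metals[i] for i in midx],
                ligands=[donors[j] for j in jidx],
                bonds=sorted((mmap[i], jmap[j]) for i, j in bonds if i in midx),
            )
        )
    return sites


@dataclass(frozen=True)
class ClusterTopology:
    """Renumbering-invariant fingerprint of a metal-thiolate cluster.

    Ligands are sorted by residue number and labeled 1..n; each metal is the
    set of ligand indices it binds, metals ordered by their smallest index.
    """

    n_ligands: int
    metal_ligand_indices: tuple[tuple[int, ...], ...]
    bridging_indices: tuple[int, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_ligands": self.n_ligands,
                "metals": [list(m) for m in self.metal_ligand_indices],
                "bridging": list(self.bridging_indices),
            },
            sort_keys=True,
        )


def cluster_topology(site: MetalSite) -> ClusterTopology:
    """Reduce a site to its ligand-order fingerprint."""
    if not site.metals:
        raise ValueError("site has no metals")
    order = sorted(
        range(len(site.ligands)),
        key=lambda j: (site.ligands[j].res_seq, site.ligands[j].atom_name),
    )
    index_of = {j: k + 1 for k, j in enumerate(order)}  # 1-based
    per_metal = []
    for i in range(len(site.metals)):
        idxs = tuple(sorted(index_of[j] for mi, j in site.bonds if mi == i))
        per_metal.append(idxs)
    per_metal.sort(key=lambda t: (t[0] if t else 0, t))
    degree: dict[int, int] = {}
    for _, j in site.bonds:
        degree[index_of[j]] = degree.get(index_of[j], 0) + 1
    bridging = tuple(sorted(k for k, d in degree.items() if d >= 2))
    return ClusterTopology(
        n_ligands=len(site.ligands),
        metal_ligand_indices=tuple(per_metal),
        bridging_indices=bridging,
    )


@dataclass
class MetalReport:
    metal: MetalAtom
    bond_lengths: list[float]
    angles: list[float]  # donor-metal-donor, degrees
    tetrahedrality: float | None  # RMS deviation from the ideal tetrahedral angle


@dataclass
class CoordinationReport:
    per_metal: list[MetalReport]

    @property
    def mean_bond_length(self) -> float:
        all_bonds = [b for m in self.per_metal for b in m.bond_lengths]
        return float(np.mean(all_bonds))

    @property
    def mean_angle(self) -> float:
        all_angles = [a for m in self.per_metal for a in m.angles]
        return float(np.mean(all_angles))

    @property
    def mean_tetrahedrality(self) -> float:
        vals = [m.tetrahedrality for m in self.per_metal if m.tetrahedrality is not None]
        return float(np.mean(vals))


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def coordination_report(
    site: MetalSite, reference_angle: float = TETRAHEDRAL_ANGLE
) -> CoordinationReport:
    """Per-metal bond lengths, inter-donor angles and tetrahedrality.

    Tetrahedrality is the RMS deviation of the donor-metal-donor angles from
    the ideal tetrahedral angle arccos(-1/3); metals with fewer than two
    donors report no angles.
    """
    per_metal = []
    for i, metal in enumerate(site.metals):
        js = [j for mi, j in site.bonds if mi == i]
        mpos = np.asarray(metal.xyz)
        bonds = [float(np.linalg.norm(np.asarray(site.ligands[j].xyz) - mpos)) for j in js]
        angles = []
        for a in range(len(js)):
            for b in range(a + 1, len(js)):
                angles.append(
                    _angle_deg(
                        np.asarray(site.ligands[js[a]].xyz),
                        mpos,
                        np.asarray(site.ligands[js[b]].xyz),
                    )
                )
        tet = (
            float(np.sqrt(np.mean((np.asarray(angles) - reference_angle) ** 2)))
            if angles
            else None
        )
        per_metal.append(MetalReport(metal, bonds, angles, tet))
    return CoordinationReport(per_metal=per_metal)


@dataclass
class SuperpositionResult:
    rmsd: float
    rotation: np.ndarray  # (3,3), proper rotation
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(moving: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``moving`` onto ``target`` (Kabsch).

    Reflections are excluded (proper rotation only).  Raises
    :class:`DegenerateGeometryError` for fewer than 3 points or collinear
    point sets.
    """
    X = np.asarray(moving, dtype=float)
    Y = np.asarray(target, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("point sets must be matched (n, 3) arrays")
    if len(X) < 3:
        raise DegenerateGeometryError("need at least 3 paired atoms")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    sx = np.linalg.svd(X0, compute_uv=False)
    if sx[1] < 1e-8 * max(sx[0], 1.0):
        raise DegenerateGeometryError("paired atoms are collinear or coincident")
    H = X0.T @ Y0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    moved = X @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Y) ** 2, axis=1))))
    return SuperpositionResult(rmsd=rmsd, rotation=R, translation=t)


def superpose_clusters(
    a: MetalSite, b: MetalSite, correspondence: Sequence[tuple[int, int]]
) -> SuperpositionResult:
    """Superpose site ``a`` onto site ``b`` over an ordered atom pairing.

    Pairing indices address each site's stacked atom list
    (:meth:`MetalSite.atom_coords`: metals first, then ligand donors).
    """
    pa, pb = a.atom_coords(), b.atom_coords()
    ia = [i for i, _ in correspondence]
    ib = [j for _, j in correspondence]
    return superpose(pa[ia], pb[ib])


@dataclass
class EnsembleRmsdResult:
    mean_rmsd: float
    sd_rmsd: float
    per_model: list[float]
    n_atoms: int
    excluded_atoms: list[tuple[str, int, str]]  # (chain, res_seq, name)


BACKBONE_ATOMS = ("N", "CA", "C")


def ensemble_rmsd(
    ens: StructureEnsemble,
    residue_ranges: Sequence[tuple[int, int]],
    atom_set: str = "backbone",
    include_O: bool = False,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> EnsembleRmsdResult:
    """RMSD of each model to the iteratively refined mean structure.

    Models are superposed onto the evolving mean until the mean shifts by
    less than ``tol`` Angstrom (RMS).  ``atom_set`` selects backbone
    (N, CA, C, optionally O) or all heavy atoms within the residue ranges.
    Atoms missing from any model are excluded consistently and reported.
    """
    if len(ens) < 2:
        raise ValueError("ensemble RMSD needs at least 2 models")
    residues: set[int] = set()
    for first, last in residue_ranges:
        residues.update(range(first, last + 1))

    def keys_of(model: Model) -> dict[tuple[str, int, str], np.ndarray]:
        df = model.atoms
        df = df[df["res_seq"].isin(residues)]
        if atom_set == "backbone":
            names = BACKBONE_ATOMS + (("O",) if include_O else ())
            df = df[df["name"].isin(names)]
        elif atom_set == "heavy":
            df = df[df["element"] != "H"]
        else:
            raise ValueError(f"unknown atom_set {atom_set!r}")
        return {
            (str(r.chain), int(r.res_seq), str(r.name)): np.array([r.x, r.y, r.z])
            for r in df.itertuples()
        }

    per_model_keys = [keys_of(m) for m in ens.models]
    common = set(per_model_keys[0])
    union: set[tuple[str, int, str]] = set()
    for keys in per_model_keys:
        common &= set(keys)
        union |= set(keys)
    excluded = sorted(union - common)
    common_sorted = sorted(common)
    if not common_sorted:
        raise ValueError("no atoms shared by all models in the selected ranges")

    coords = np.stack(
        [np.stack([keys[k] for k in common_sorted]) for keys in per_model_keys]
    )  # (n_models, n_atoms, 3)

    mean = coords[0].copy()
    for _ in range(max_iter):
        fitted = np.stack(
            [superpose(c, mean).apply(c) for c in coords]
        )
        new_mean = fitted.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        coords = fitted
        if shift < tol:
            break

    per_model = [
        float(np.sqrt(np.mean(np.sum((c - mean) ** 2, axis=1)))) for c in coords
    ]
    return EnsembleRmsdResult(
        mean_rmsd=float(np.mean(per_model)),
        sd_rmsd=float(np.std(per_model, ddof=1)),
        per_model=per_model,
        n_atoms=len(common_sorted),
        excluded_atoms=excluded,
    )


@dataclass
class HbondResult:
    present: bool
    distance: float
    angle: float | None  # D-H...A angle when a hydrogen was found


def _find_atom(model: Model, res_seq: int, name: str) -> np.ndarray:
    df = model.atoms
    hit = df[(df["res_seq"] == res_seq) & (df["name"] == name)]
    if hit.empty:
        raise AtomLookupError(f"atom {name} of residue {res_seq} not found")
    r = hit.iloc[0]
    return np.array([r.x, r.y, r.z], dtype=float)


def hbond_check(
    model: Model,
    donor: tuple[int, str],
    acceptor: tuple[int, str],
    dist_cutoff: float = 3.5,
    min_dha_angle: float = 120.0,
) -> HbondResult:
    """Heavy-atom distance hydrogen-bond test with optional angle criterion.

    True iff the donor-acceptor heavy-atom distance is within ``dist_cutoff``;
    when a hydrogen attached to the donor (within 1.2 A) is present, the
    D-H...A angle must additionally exceed ``min_dha_angle``.
    """
    d = _find_atom(model, *donor)
    a = _find_atom(model, *acceptor)
    dist = float(np.linalg.norm(d - a))
    # look for an attached hydrogen on the donor residue
    df = model.atoms
    hs = df[
        (df["res_seq"] == donor[0])
        & (df["element"] == "H")
    ]
    angle = None
    for r in hs.itertuples():
        hpos = np.array([r.x, r.y, r.z])
        if np.linalg.norm(hpos - d) <= 1.2:
            cand = _angle_deg(d, hpos, a)
            if angle is None or cand > angle:
                angle = cand
    present = dist <= dist_cutoff
    if present and angle is not None:
        present = angle > min_dha_angle
    return HbondResult(present=present, distance=dist, angle=angle)
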