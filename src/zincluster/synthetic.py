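"""Synthetic data generators with known ground truth for every pipeline stage.

Each generator emulates one experimental input class:

* idealized trinuclear metal-thiolate cluster coordinates (exact 2.3 A
  metal-S bonds, exact tetrahedral angles at zero noise) rendered as a
  multi-model ensemble;
* partial connectivity datasets derived from a ground-truth assignment by
  hiding edges, as when weak three-bond couplings leave correlations
  unobserved;
* amide-proton exchange decay tables engineered to hit given detection
  counts, and saturated/reference intensity pairs realizing a given
  heteronuclear NOE profile;
* protein sequences with consensus motif matches implanted in ligand-free
  random backgrounds.

Determinism: one integer seed per config; each artifact type consumes its
own explicitly constructed generator stream, so identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import (
    Assignment,
    ConnectivityDataset,
    CouplingPair,
    MetalSpin,
    MSL2_ASSIGNMENT,
    MSL2_CD_SHIFTS,
)
from .errors import GenerationError
from .geometry import TETRAHEDRAL_ANGLE
from .motifs import CXC_CONSENSUS, Ligand, MotifPattern
from .nmr import IntensityTable
from .pdbio import Model, StructureEnsemble

#: Background alphabet for motif implants: canonical residues minus the
#: ligand letters (C, H) and the signature letter (N).
BACKGROUND_ALPHABET = "ADEFGIKLMPQRSTVWY"

#: Default H/D-exchange timepoints (minutes).
DEFAULT_HDX_TIMEPOINTS = (0.0, 30.0, 75.0, 120.0, 160.0, 390.0, 1440.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs shared by the generators; identical configs give identical bytes."""

    seed: int = 0
    coordinate_noise: float = 0.0  # Angstrom, per-coordinate Gaussian sigma
    sidechain_noise_scale: float = 1.5  # side chains scatter more than backbone
    intensity_noise: float = 0.0  # fractional sigma for intensity tables
    n_models: int = 20
    bond_length: float = 2.3

    def rng(self, stream: str) -> np.random.Generator:
        """A named, reproducible random stream (stable across processes)."""
        stream_id = sum(ord(c) * 31**i for i, c in enumerate(stream)) % (2**31)
        ss = np.random.SeedSequence([self.seed, stream_id])
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Cluster coordinates


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _tetrahedral_completion(w1: np.ndarray, w2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The two directions completing an ideal tetrahedron given two of them."""
    c = _unit(w1 + w2)
    nrm = _unit(np.cross(w1, w2))
    alpha = math.radians(TETRAHEDRAL_ANGLE) / 2.0
    w3 = -c * math.cos(alpha) + nrm * math.sin(alpha)
    w4 = -c * math.cos(alpha) - nrm * math.sin(alpha)
    return w3, w4


def _trinuclear_site(template: Assignment, bond: float) -> tuple[dict[str, np.ndarray], dict[int, np.ndarray]]:
    """Exact coordinates for a three-metal ring cluster.

    Metals sit on an equilateral triangle; each bridging donor lies on the
    perpendicular bisector plane of its metal pair, lifted off the triangle
    plane so that every metal-donor bond is exactly ``bond`` and every
    donor-metal-donor angle is exactly tetrahedral.  With the bridge angle at
    the donor also tetrahedral, the closed form is: triangle circumradius
    R = d/sqrt(3) with d = 2 b sin(theta_t/2), bridge donors at radius R and
    height b/3.
    """
    labels = template.metal_labels()
    if len(labels) != 3:
        raise GenerationError("trinuclear construction requires exactly 3 metals")
    for l in template.ligand_positions():
        if template.ligand_degree(l) > 2:
            raise GenerationError(f"ligand {l} has degree > 2; infeasible template")
    # each pair must share exactly one bridging ligand
    shared = {}
    for i, a in enumerate(labels):
        for b_lbl in labels[i + 1 :]:
            common = template.metal_ligands(a) & template.metal_ligands(b_lbl)
            if len(common) != 1:
                raise GenerationError(
                    f"metals {a},{b_lbl} share {len(common)} ligands; ring "
                    "construction needs exactly one bridge per pair"
                )
            shared[frozenset((a, b_lbl))] = next(iter(common))

    theta_t = math.radians(TETRAHEDRAL_ANGLE)
    d = 2.0 * bond * math.sin(theta_t / 2.0)
    R = d / math.sqrt(3.0)
    angles = [math.pi / 2 + 2 * math.pi * k / 3 for k in range(3)]
    u = {lbl: np.array([math.cos(a), math.sin(a), 0.0]) for lbl, a in zip(labels, angles)}
    metal_xyz = {lbl: R * u[lbl] for lbl in labels}

    ligand_xyz: dict[int, np.ndarray] = {}
    for pair, lig in shared.items():
        a, b_lbl = sorted(pair)
        m = u[a] + u[b_lbl]  # |u_a + u_b| = 1 for 120 deg separation
        ligand_xyz[lig] = R * m + np.array([0.0, 0.0, bond / 3.0])

    for lbl in labels:
        bridges = sorted(
            l for l in template.metal_ligands(lbl) if template.ligand_degree(l) == 2
        )
        terminals = sorted(
            l for l in template.metal_ligands(lbl) if template.ligand_degree(l) == 1
        )
        if len(bridges) != 2 or len(terminals) != 2:
            raise GenerationError(
                f"metal {lbl} needs 2 bridging + 2 terminal ligands for the "
                "ring construction"
            )
        w1 = _unit(ligand_xyz[bridges[0]] - metal_xyz[lbl])
        w2 = _unit(ligand_xyz[bridges[1]] - metal_xyz[lbl])
        w3, w4 = _tetrahedral_completion(w1, w2)
        ligand_xyz[terminals[0]] = metal_xyz[lbl] + bond * w3
        ligand_xyz[terminals[1]] = metal_xyz[lbl] + bond * w4
    return metal_xyz, ligand_xyz


def _mononuclear_site(template: Assignment, bond: float) -> tuple[dict[str, np.ndarray], dict[int, np.ndarray]]:
    labels = template.metal_labels()
    (lbl,) = labels
    ligs = sorted(template.metal_ligands(lbl))
    if len(ligs) > 4:
        raise GenerationError("mononuclear construction supports up to 4 ligands")
    dirs = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / math.sqrt(3.0)
    metal_xyz = {lbl: np.zeros(3)}
    ligand_xyz = {l: bond * dirs[i] for i, l in enumerate(ligs)}
    return metal_xyz, ligand_xyz


_SIDECHAIN_ATOMS = ("CB", "SG")


def _cys_atoms(res_seq: int, sg: np.ndarray, outward: np.ndarray) -> list[dict]:
    """Idealized Cys heavy atoms built outward from the donor Sgamma.

    Bond lengths are standard (SG-CB 1.81, CB-CA 1.53, CA-N 1.46, CA-C 1.52,
    C-O 1.23 A); the local frame is deterministic.  Not stereochemically
    refined -- sufficient for site detection, selection and RMSD code paths.
    """
    u = _unit(outward)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    p = _unit(np.cross(u, ref))
    q = np.cross(u, p)
    cb = sg + 1.81 * u
    ca = cb + 1.53 * _unit(0.94 * u + 0.34 * p)
    n = ca + 1.46 * _unit(0.45 * u + 0.72 * p + 0.53 * q)
    c = ca + 1.52 * _unit(0.45 * u - 0.72 * p + 0.53 * q)
    o = c + 1.23 * _unit(q)
    names = [("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o),
             ("CB", "C", cb), ("SG", "S", sg)]
    return [
        {
            "serial": 0,
            "name": nm,
            "element": el,
            "res_name": "CYS",
            "res_seq": res_seq,
            "chain": "A",
            "x": float(pos[0]),
            "y": float(pos[1]),
            "z": float(pos[2]),
        }
        for nm, el, pos in names
    ]


def make_cluster_coordinates(
    config: GeneratorConfig = GeneratorConfig(),
    template: Assignment = MSL2_ASSIGNMENT,
    metal_element: str = "Zn",
) -> StructureEnsemble:
    """Render a metal-thiolate cluster template as a coordinate ensemble.

    At zero noise every metal-donor bond is exactly ``config.bond_length``
    and every donor-metal-donor angle exactly tetrahedral.  Gaussian noise of
    ``config.coordinate_noise`` (scaled by ``sidechain_noise_scale`` for CB
    and SG) is added per model.  Metals get residue numbers 601, 602, ...
    """
    n_metals = len(template.metal_labels())
    if n_metals == 3:
        metal_xyz, ligand_xyz = _trinuclear_site(template, config.bond_length)
    elif n_metals == 1:
        metal_xyz, ligand_xyz = _mononuclear_site(template, config.bond_length)
    else:
        raise GenerationError(
            f"no construction for {n_metals} metals (supported: 1, 3)"
        )

    center = np.mean(list(metal_xyz.values()), axis=0)
    records: list[dict] = []
    for res_seq in sorted(ligand_xyz):
        sg = ligand_xyz[res_seq]
        bonded = [
            metal_xyz[m] for m, l in template.edges if l == res_seq
        ]
        outward = sg - np.mean(bonded, axis=0)
        if np.linalg.norm(outward) < 1e-9:
            outward = sg - center
        records.extend(_cys_atoms(res_seq, sg, outward))
    for k, lbl in enumerate(sorted(metal_xyz), start=1):
        pos = metal_xyz[lbl]
        records.append(
            {
                "serial": 0,
                "name": metal_element.upper(),
                "element": metal_element.capitalize(),
                "res_name": metal_element.upper(),
                "res_seq": 600 + k,
                "chain": "A",
                "x": float(pos[0]),
                "y": float(pos[1]),
                "z": float(pos[2]),
            }
        )
    for i, r in enumerate(records, start=1):
        r["serial"] = i
    ideal = Model(pd.DataFrame(records))

    rng = config.rng("cluster")
    models = []
    for _ in range(config.n_models):
        if config.coordinate_noise > 0:
            noise = rng.normal(0.0, config.coordinate_noise, size=(len(ideal), 3))
            scale = np.array(
                [
                    config.sidechain_noise_scale if nm in _SIDECHAIN_ATOMS else 1.0
                    for nm in ideal.atoms["name"]
                ]
            )[:, None]
            models.append(ideal.with_xyz(ideal.xyz + noise * scale))
        else:
            models.append(ideal.with_xyz(ideal.xyz))
    return StructureEnsemble(models=models, label="synthetic-cluster")


# ---------------------------------------------------------------------------
# Connectivity datasets


def make_connectivity_dataset(
    truth: Assignment = MSL2_ASSIGNMENT,
    hidden_edges: Sequence[tuple[str, int]] = (),
    config: GeneratorConfig = GeneratorConfig(),
    chemical_shifts: dict[str, float] | None = None,
    with_couplings: bool = True,
) -> ConnectivityDataset:
    """Derive a solver input from a ground-truth assignment by hiding edges.

    Coupling pairs are derived from the truth's bridging structure (each
    shared ligand couples its two metals).  Hiding every edge of a metal is
    allowed; the dataset simply carries no confirmed edge for it.
    """
    hidden = set(hidden_edges)
    if not hidden <= truth.edges:
        raise ValueError("hidden_edges must be a subset of the truth's edges")
    labels = truth.metal_labels()
    shift_map = chemical_shifts if chemical_shifts is not None else {}
    metals = []
    for lbl in labels:
        metals.append(
            MetalSpin(
                label=lbl,
                chemical_shift=shift_map.get(lbl),
                coordination_number=len(truth.metal_ligands(lbl)),
            )
        )
    couplings: list[CouplingPair] = []
    if with_couplings:
        seen = set()
        for lig in sorted(truth.bridging_ligands):
            pair = tuple(sorted(m for m, l in truth.edges if l == lig))
            if pair not in seen:
                seen.add(pair)
                couplings.append(CouplingPair(pair[0], pair[1]))
    return ConnectivityDataset(
        metals=metals,
        ligands=sorted(truth.ligand_positions()),
        confirmed_edges=set(truth.edges) - hidden,
        coupling_pairs=couplings,
        max_ligand_degree=2,
        n_bridging="auto",
    )


def msl2_connectivity_input() -> ConnectivityDataset:
    """The solver input as observed experimentally: metal C's two unseen
    ligand correlations hidden, all three coupling pairs present, and the
    reported 113Cd shifts attached."""
    return make_connectivity_dataset(
        truth=MSL2_ASSIGNMENT,
        hidden_edges=[("C", 539), ("C", 553)],
        chemical_shifts={
            lbl.replace("Cd-", ""): v for lbl, v in MSL2_CD_SHIFTS.items()
        },
    )


# ---------------------------------------------------------------------------
# Intensity tables


def make_hdx_table(
    targets: tuple[int, int, int] = (17, 10, 4),
    config: GeneratorConfig = GeneratorConfig(),
    timepoints: Sequence[float] = DEFAULT_HDX_TIMEPOINTS,
    class_times: tuple[float, float, float] = (0.0, 120.0, 1440.0),
    noise_level: float = 1.0,
    threshold_multiple: float = 3.0,
    first_residue: int = 520,
) -> IntensityTable:
    """Exponential amide-proton decays hitting given detection counts.

    ``targets`` are the numbers of residues detected at the three class
    boundary times (first spectrum, 2 h, 24 h) and must be non-increasing.
    Decay rates are chosen per protection class so intensity crosses the
    detection threshold between the right boundaries.
    """
    if not (targets[0] >= targets[1] >= targets[2]):
        raise ValueError(f"hdx target counts must be non-increasing: {targets}")
    thr = threshold_multiple * noise_level
    i0 = 100.0 * noise_level
    t1, t2, t3 = class_times
    rng = config.rng("hdx")
    rows = []
    n_total = targets[0]
    for k in range(n_total):
        res = first_residue + k
        if k < targets[2]:
            # persists beyond the last boundary
            rate = math.log(i0 / (10.0 * thr)) / (2.0 * t3)
        elif k < targets[1]:
            # detected at t2, gone by t3
            rate = math.log(i0 / (0.5 * thr)) / ((t2 + t3) / 2.0)
        else:
            # detected at t1 only
            rate = math.log(i0 / (0.5 * thr)) / max((t1 + t2) / 2.0, t2 / 2.0)
        for t in timepoints:
            intensity = i0 * math.exp(-rate * t)
            if config.intensity_noise > 0:
                intensity += rng.normal(0.0, config.intensity_noise * i0)
            rows.append((res, float(t), intensity))
    df = pd.DataFrame(rows, columns=["residue", "time", "intensity"])
    return IntensityTable(df, noise_level=noise_level)


def make_hetnoe_tables(
    noe_profile: Sequence[tuple[int, float]],
    config: GeneratorConfig = GeneratorConfig(),
    reference_intensity: float = 100.0,
    noise_level: float = 1.0,
) -> tuple[IntensityTable, IntensityTable]:
    """Saturated/reference intensity pairs realizing a per-residue NOE profile."""
    rng = config.rng("hetnoe")
    sat_rows, ref_rows = [], []
    for res, noe in noe_profile:
        ref = reference_intensity
        sat = noe * reference_intensity
        if config.intensity_noise > 0:
            sat += rng.normal(0.0, config.intensity_noise * reference_intensity)
            ref += rng.normal(0.0, config.intensity_noise * reference_intensity)
        sat_rows.append((res, sat))
        ref_rows.append((res, ref))
    sat_df = pd.DataFrame(sat_rows, columns=["residue", "intensity"])
    ref_df = pd.DataFrame(ref_rows, columns=["residue", "intensity"])
    return (
        IntensityTable(sat_df, noise_level=noise_level),
        IntensityTable(ref_df, noise_level=noise_level),
    )


# ---------------------------------------------------------------------------
# Motif-bearing sequences


def _implant_from_pattern(
    pattern: MotifPattern, rng: np.random.Generator, his_at_ligand2: bool = False
) -> tuple[str, list[int]]:
    """One realization of the pattern: text and 0-based constrained offsets."""
    chars: list[str] = []
    constrained: list[int] = []
    ligand_idx = 0
    for tok in pattern.tokens:
        if isinstance(tok, Ligand):
            ligand_idx += 1
            if len(tok.allowed) > 1:
                letter = "H" if (his_at_ligand2 and "H" in tok.allowed) else tok.allowed[0]
            else:
                letter = tok.allowed[0]
            constrained.append(len(chars))
            chars.append(letter)
        else:
            gap = int(rng.integers(tok.min, tok.max + 1))
            for _ in range(gap):
                chars.append(BACKGROUND_ALPHABET[int(rng.integers(len(BACKGROUND_ALPHABET)))])
    return "".join(chars), constrained


def _background(rng: np.random.Generator, length: int) -> str:
    return "".join(
        BACKGROUND_ALPHABET[int(rng.integers(len(BACKGROUND_ALPHABET)))]
        for _ in range(length)
    )


def make_motif_sequences(
    n: int,
    config: GeneratorConfig = GeneratorConfig(),
    pattern: MotifPattern = CXC_CONSENSUS,
    pad_range: tuple[int, int] = (20, 60),
) -> tuple[str, list[dict]]:
    """FASTA text with one implanted consensus match per record, plus ground truth.

    Gap lengths are drawn uniformly within the pattern bounds; backgrounds
    contain no ligand-capable letters, so the implanted registration is the
    only one.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = config.rng("motif")
    fasta_lines = []
    truth = []
    for i in range(n):
        left = int(rng.integers(pad_range[0], pad_range[1] + 1))
        right = int(rng.integers(pad_range[0], pad_range[1] + 1))
        implant, offsets = _implant_from_pattern(pattern, rng)
        seq = _background(rng, left) + implant + _background(rng, right)
        seq_id = f"syn{i:03d}"
        positions = [left + off + 1 for off in offsets]  # 1-based
        if pattern.has_signature:
            lig_positions, sig = positions[:-1], positions[-1]
        else:
            lig_positions, sig = positions, None
        fasta_lines.append(f">{seq_id}")
        fasta_lines.append(seq)
        truth.append(
            {
                "seq_id": seq_id,
                "ligand_positions": lig_positions,
                "signature_position": sig,
                "span": [left + 1, left + len(implant)],
            }
        )
    return "\n".join(fasta_lines) + "\n", truth


def make_ez_tandem_sequence(
    config: GeneratorConfig = GeneratorConfig(),
    pattern: MotifPattern = CXC_CONSENSUS,
    pad: int = 30,
) -> tuple[str, list[dict]]:
    """An EZ-pre-SET-style sequence: two immediately adjacent consensus units,
    the first with His at ligand-2 (17 Cys among the 18 ligand slots)."""
    rng = config.rng("ez")
    d1, off1 = _implant_from_pattern(pattern, rng, his_at_ligand2=True)
    d2, off2 = _implant_from_pattern(pattern, rng, his_at_ligand2=False)
    left = _background(rng, pad)
    right = _background(rng, pad)
    seq = left + d1 + d2 + right
    truth = []
    for base, (dom, offs) in zip(
        (len(left), len(left) + len(d1)), ((d1, off1), (d2, off2))
    ):
        positions = [base + off + 1 for off in offs]
        truth.append(
            {
                "seq_id": "ez_tandem",
                "ligand_positions": positions[:-1] if pattern.has_signature else positions,
                "signature_position": positions[-1] if pattern.has_signature else None,
                "span": [base + 1, base + len(dom)],
            }
        )
    return seq, truth


#: Canonical MSL2 CXC landmark positions in full-length numbering.
MSL2_CYS_POSITIONS = (525, 527, 539, 544, 546, 553, 556, 558, 561)
MSL2_ASN_POSITION = 563
MSL2_HIS_POSITIONS = (557, 565)


def make_msl2_like_sequence(
    config: GeneratorConfig = GeneratorConfig(), length: int = 570
) -> str:
    """A synthetic stand-in for the MSL2 C-terminal region.

    Carries the nine printed Cys ligand positions, the signature Asn563 and
    the two non-conserved histidines in an otherwise ligand-free random
    background.  The real MSL2 sequence is not reproduced; only the printed
    landmark positions are.
    """
    rng = config.rng("msl2")
    chars = list(_background(rng, length))
    for pos in MSL2_CYS_POSITIONS:
        chars[pos - 1] = "C"
    chars[MSL2_ASN_POSITION - 1] = "N"
    for pos in MSL2_HIS_POSITIONS:
        chars[pos - 1] = "H"
    return "".join(chars)


def ground_truth_json(truth: object) -> str:
    """Canonical JSON for a generator's ground-truth record."""
    return json.dumps(truth, sort_keys=True, indent=1)
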