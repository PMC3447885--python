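"""Independent reference implementations used only to cross-check the package.

Each oracle deliberately takes a different algorithmic route from the code it
validates: exhaustive set enumeration for the connectivity solver, Horn's
quaternion method for Kabsch superposition, itertools-product gap expansion
for the backtracking motif scanner, and plain loops for vectorized geometry.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np


def brute_force_assignments(data):
    """Enumerate ALL per-metal ligand subsets of the right size containing the
    confirmed edges, then filter every constraint. Returns a set of edge
    frozensets."""
    metals = data.metals
    ligands = sorted(data.ligands)
    n_bridging = data.resolved_n_bridging()
    confirmed_by_metal = {
        m.label: {l for lbl, l in data.confirmed_edges if lbl == m.label}
        for m in metals
    }
    per_metal_choices = []
    for m in metals:
        choices = [
            frozenset(c)
            for c in combinations(ligands, m.coordination_number)
            if confirmed_by_metal[m.label] <= set(c)
        ]
        per_metal_choices.append(choices)
    valid = set()
    for combo in product(*per_metal_choices):
        edges = frozenset(
            (m.label, l) for m, ligs in zip(metals, combo) for l in ligs
        )
        degree = {l: sum(1 for _, ll in edges if ll == l) for l in ligands}
        if any(d < 1 or d > data.max_ligand_degree for d in degree.values()):
            continue
        if n_bridging is not None:
            if sum(1 for d in degree.values() if d >= 2) != n_bridging:
                continue
        ok = True
        for cp in data.coupling_pairs:
            sa = {l for lbl, l in edges if lbl == cp.metal_a}
            sb = {l for lbl, l in edges if lbl == cp.metal_b}
            if len(sa & sb) != 1:
                ok = False
                break
        if ok:
            valid.add(edges)
    return valid


def horn_superpose_rmsd(moving: np.ndarray, target: np.ndarray) -> float:
    """RMSD after optimal proper rotation via Horn's quaternion method."""
    X = np.asarray(moving, float) - np.mean(moving, axis=0)
    Y = np.asarray(target, float) - np.mean(target, axis=0)
    Sxx, Sxy, Sxz = (X[:, 0] * Y[:, 0]).sum(), (X[:, 0] * Y[:, 1]).sum(), (X[:, 0] * Y[:, 2]).sum()
    Syx, Syy, Syz = (X[:, 1] * Y[:, 0]).sum(), (X[:, 1] * Y[:, 1]).sum(), (X[:, 1] * Y[:, 2]).sum()
    Szx, Szy, Szz = (X[:, 2] * Y[:, 0]).sum(), (X[:, 2] * Y[:, 1]).sum(), (X[:, 2] * Y[:, 2]).sum()
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    n = len(X)
    msd = max(0.0, ((X**2).sum() + (Y**2).sum() - 2.0 * lam) / n)
    return math.sqrt(msd)


def naive_scan_tuples(seq: str, pattern) -> set:
    """All constrained-position tuples satisfying the pattern, by expanding
    every gap-length combination at every start."""
    from zincluster.motifs import Gap, Ligand

    seq = seq.upper()
    tokens = pattern.tokens
    gaps = [t for t in tokens if isinstance(t, Gap)]
    results = set()
    for start in range(len(seq)):
        for lens in product(*[range(g.min, g.max + 1) for g in gaps]):
            gi = 0
            pos = start
            positions = []
            ok = True
            for tok in tokens:
                if isinstance(tok, Ligand):
                    if pos >= len(seq) or seq[pos] not in tok.allowed:
                        ok = False
                        break
                    positions.append(pos + 1)
                    pos += 1
                else:
                    pos += lens[gi]
                    gi += 1
                    if pos > len(seq):
                        ok = False
                        break
            if ok:
                results.add(tuple(positions))
    return results


def naive_bond_angles(metal_xyz, donor_xyzs):
    """Bond lengths and all pairwise donor-metal-donor angles by plain loops."""
    bonds = []
    for d in donor_xyzs:
        bonds.append(
            math.sqrt(sum((a - b) ** 2 for a, b in zip(metal_xyz, d)))
        )
    angles = []
    for i in range(len(donor_xyzs)):
        for j in range(i + 1, len(donor_xyzs)):
            v1 = [a - b for a, b in zip(donor_xyzs[i], metal_xyz)]
            v2 = [a - b for a, b in zip(donor_xyzs[j], metal_xyz)]
            dot = sum(a * b for a, b in zip(v1, v2))
            n1 = math.sqrt(sum(a * a for a in v1))
            n2 = math.sqrt(sum(a * a for a in v2))
            angles.append(math.degrees(math.acos(max(-1.0, min(1.0, dot / (n1 * n2))))))
    return bonds, angles
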