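# zincluster

A Python toolkit for the inference chain behind trinuclear zinc–cysteine
(Zn₃Cys₉) cluster determinations in cysteine-rich DNA-binding domains of the
CXC superfamily (MSL2/tesmin/TSO1 CXC domains and the pre-SET motifs of
histone lysine methyltransferases). It is written for structural biologists
and bioinformaticians who need to reproduce or extend each quantitative step
of such a study without rerunning spectrometers or refinement engines:

1. **Metal stoichiometry from native ESI-MS** (`zincluster.mass`) — neutral
   monoisotopic mass from a charge-state peak, *M* = (m/z)·z − z·m_carrier,
   and the adduct arithmetic for divalent metals, e.g. each bound Zn²⁺
   contributing M(⁶⁴Zn) − 2 = 61.929 Da; a search over n = 0…n_max picks the
   metal count minimizing |M_obs − M_pred|.
2. **Metal-to-ligand connectivity completion** (`zincluster.connectivity`) —
   ¹H–¹¹³Cd correlation experiments typically leave some metal–ligand edges
   unobserved. Given confirmed edges, per-metal coordination numbers, a
   ligand degree bound, the bridging-ligand count and metal–metal coupling
   evidence (²J through a shared thiolate), the solver enumerates *every*
   consistent completion and ranks candidates by externally supplied
   restraint-violation counts.
3. **Per-residue NMR observables** (`zincluster.nmr`) — chemical-shift
   perturbation Δδ = δ_b − δ_a per nucleus; steady-state heteronuclear NOE
   I_sat/I_ref with noise-propagated errors; H/D-exchange protection classes
   from intensity decays.
4. **Restraint tools** (`zincluster.restraints`) — NOE range classification
   (|i−j| = 0 / 1 / ≤4 / ≥5, ambiguous), restraints-per-residue density,
   volume-to-distance calibration d = d_ref (V_ref/V)^{1/6} clamped to
   [2.2, 6.0] Å, and tetrahedral coordination restraints (M–S 2.3 Å,
   S–M–S 109.5°).
5. **Cluster geometry** (`zincluster.geometry`) — metal-site detection in
   coordinates, terminal/bridging classification, a renumbering-invariant
   topology fingerprint for cross-structure comparison, Kabsch superposition
   (proper rotations only), iterative ensemble RMSD-to-mean, hydrogen-bond
   checks.
6. **Consensus motif scanning** (`zincluster.motifs`) — the CXC-superfamily
   pattern `CX[C/H]X2-13CX4-7CXCX5-60CX2-4CX1-2CX2-15CXN` parsed into
   ligand/gap tokens and scanned with bounded backtracking; tandem-domain
   detection for EZ-type (adjacent) and tesmin/TSO1-type (40–60 residue
   spacer) arrangements.
7. **Synthetic data with ground truth** (`zincluster.synthetic`) — idealized
   cluster ensembles, partial connectivity datasets, intensity tables and
   motif-bearing sequences, so the full pipeline is testable offline.

## Worked example

```python
from zincluster import (
    MassPeak, ZN64, neutral_mass_from_peak, infer_stoichiometry,
    enumerate_assignments, classify_ligands,
)
from zincluster.synthetic import msl2_connectivity_input

# Native MS: +5 monoisotopic peak of a 51-residue Cys-rich domain
observed = neutral_mass_from_peak(MassPeak(mz=1165.8361, z=5), charge_carrier_mass=1.0)
print(observed)                    # 5824.1805
res = infer_stoichiometry(observed, apo_mass=5638.48, metal=ZN64, n_max=6, tolerance=0.5)
print(res.n_metals, round(res.predicted_mass, 3), round(res.residual, 4))
# 3 5824.267 0.0865  -> the mass matches the apo protein plus three Zn2+

# Connectivity: metal C has two unobserved ligands
data = msl2_connectivity_input()
candidates = enumerate_assignments(data)
print(len(candidates))             # 9 completions consistent with coupling evidence

# the completion confirmed downstream (zero restraint violations)
final = next(a for a in candidates
             if a.metal_ligands("C") == frozenset({539, 553, 558, 561}))
terminal, bridging = classify_ligands(final)
print(sorted(bridging))            # [525, 539, 553]  (degree-2, metal-bridging Cys)
```

The mass 5824.1805 Da deconvolved from the peak sits 0.0865 Da from the
theoretical three-zinc adduct mass 5824.267 Da — inside a 0.5 Da window, and
no other metal count comes close. The nine candidate completions are exactly
{one terminal ligand of metal A} × {one terminal ligand of metal B}, the only
choices that give each coupled metal pair exactly one shared thiolate.

The same operations are available from a shell:

```sh
zincluster mass --mz 1165.8361 --z 5 --apo 5638.48 --metal Zn
zincluster synth cluster --seed 0 --out scratch/demo
zincluster site --pdb scratch/demo/cluster.pdb
# site 0: 3 metals, 9 ligands, 12 bonds; bridging [525, 539, 553]
```

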