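# Methods

This note records the models, conventions and design choices behind each
module, what the synthetic generators do and do not emulate, and the known
limitations.

## Mass arithmetic (`zincluster.mass`)

Charge deconvolution of a native ESI-MS peak uses
*M* = (m/z)·z − z·m_carrier. Two charge-carrier conventions are supported:

* **nominal mode** (default): m_carrier = 1.0 Da and each bound divalent metal
  adds its neutral monoisotopic atom mass minus its integer charge
  (⁶⁴Zn²⁺: 63.929 − 2 = 61.929 Da). This integer-subtraction convention is
  widespread in manual Q-TOF deconvolution and is the one under which the
  package's worked example is internally consistent.
* **accurate mode**: m_carrier = 1.007276 Da (proton) and metal adducts
  subtract only the displaced electron masses (2·m_e per M²⁺). The two modes
  differ by exactly n·z·(1 − m_e) Da for n metals, which the test suite
  asserts.

A caution for users comparing against published numbers: the two conventions
differ by ~7 mDa per charge, and published values for the same species
sometimes disagree at that scale (for the worked example's +5 peak, values
of 5824.1805 and 5824.0875 Da are both in circulation; the former follows
from the peak's own m/z by the stated rule and is the one this package
reproduces).

The stoichiometry search scans n = 0…n_max and returns the count minimizing
the residual; ties break toward smaller n (parsimony — and for metal masses
far above twice the tolerance, ties cannot occur). A best match outside the
tolerance is returned flagged rather than raised, since a failed match is a
scientific result, not a program error. Sequence masses come from
Biopython's monoisotopic residue table (residues + one water).

## Connectivity completion (`zincluster.connectivity`)

The solver input is a bipartite multigraph-completion problem: metals with
fixed coordination numbers (default 4, tetrahedral), a ligand pool with a
degree bound (default 2 — a thiolate can bridge at most two metals), a
bridging count (default "auto": Σ coordination − n_ligands, i.e. all ligands
used), and optional metal–metal coupling evidence. Coupling through a shared
thiolate is interpreted as *exactly one* shared ligand per coupled pair:
zero shared ligands would give no two-bond coupling path, and two shared
ligands between one pair is incompatible with the observed triplet
splittings once all three pairs couple (it would force some ligand above
degree 2 elsewhere in the triangle).

Enumeration is exhaustive over per-metal completions with early degree
pruning, then filtered by the global constraints; output order is
lexicographic in the added edges so runs are reproducible. The test suite
checks equivalence against an independent brute-force enumerator (all
coordination-number subsets per metal, product, filter) on every dataset
with ≤ 12 ligands.

Violation scores used for ranking are injected, never computed here: the
package does not run structure refinement. For tests and examples a
synthetic scorer counts metal–donor distances in a reference coordinate set
deviating more than 0.5 Å from the 2.3 Å target. A unique zero-violation
candidate is flagged selected; multiple zero-violation candidates are
flagged ambiguous and none is selected.

## NMR observables (`zincluster.nmr`)

* **CSP** is reported per nucleus and signed (Δδ = δ_b − δ_a), matching how
  metal-substitution perturbations are usually displayed; a composite
  ¹H/¹⁵N distance with w_N = 0.154 is available but off by default.
  Residues present in only one table are reported missing, never imputed as
  zero (prolines and unassigned residues simply drop out).
* **Heteronuclear NOE** is I_sat/I_ref with the error
  |NOE|·sqrt((σ/I_sat)² + (σ/I_ref)²), σ being the spectrum background
  noise. Zero reference intensity yields a per-residue undefined flag.
* **H/D exchange**: detection at a timepoint means intensity above
  threshold_multiple × noise (default 3×, the conventional signal-to-noise
  floor; configurable since no universal standard exists). Protection
  classes are assigned at three boundary times — first spectrum, 2 h, 24 h —
  while intermediate timepoints (30, 75, 160, 390 min in the default
  schedule) are retained in per-timepoint counts but do not define classes.

## Restraint tools (`zincluster.restraints`)

Range classes partition unambiguous restraints by |i−j| (0, 1, 2–4, ≥5);
ambiguous restraints (multiple assignment options, taken from input) are
counted only in their own class. "Exponential calibration" of peak volumes
is implemented as the isolated spin-pair relation V ∝ d⁻⁶, i.e.
d = d_ref·(V_ref/V)^{1/6}, clamped to [2.2, 6.0] Å — the standard reading of
that calibration mode; the sixth-root form is documented here as an
interpretation since calibration software rarely prints its formula.

Restraint density divides by the construct span (last − first + 1 residues,
e.g. 51 for a 520–570 construct) rather than the count of assigned residues,
and rounds half-to-even. Coordination restraints are one bond per edge and
C(k,2) donor–metal–donor angles per metal, defaults 2.3 Å and 109.5°.

## Cluster geometry (`zincluster.geometry`)

Metal-site detection uses distance cutoffs per donor element: M–S 2.9 Å,
M–N 2.5 Å. These are deliberately wider than the 2.3 Å restraint target to
tolerate refinement scatter. Histidine donors are off by default (in the
motivating system the two histidines are non-conserved and not ligands);
they can be enabled for EZ-family cases. Metals sharing a donor are merged
into one site by union-find.

The topology fingerprint sorts ligands by residue number, labels them 1…n,
and records each metal's ligand-index set (metals ordered by smallest
index) plus the degree-2 (bridging) indices. It is invariant under rigid
motion and uniform renumbering, making fingerprints directly comparable
across structures; canonical JSON serialization supports diffing.

Angles are referenced to the exact tetrahedral angle arccos(−1/3) =
109.4712°, not the rounded 109.5°: all six ligand-pair angles at a
4-coordinate center can simultaneously equal only the former. The
tetrahedrality score is the RMS deviation of a metal's angles from that
reference, so the ideal generator cluster reports exactly zero.

Superposition is Kabsch via SVD with the determinant correction, proper
rotations only; collinear or < 3-point pairings raise a conditioning error.
The implementation is cross-checked in tests against an independent
quaternion (Horn) method to 1e-6 Å. Ensemble RMSD iterates superposition to
the evolving mean until the mean shifts < 1e-6 Å (RMS), then reports each
model's RMSD to the final mean. "Backbone" means N, CA, C (O optional); the
convention matters at the ~0.1 Å level when comparing to published ensemble
RMSDs, so comparisons against deposited ensembles should carry a ±0.1 Å
tolerance. Hydrogen-bond checks are heavy-atom distance tests (default
3.5 Å) with a D-H···A > 120° criterion applied only when an explicit
hydrogen is present.

## Motif scanning (`zincluster.motifs`)

The pattern grammar covers residue letters, `[A/B]` alternatives, `X`
(exactly one arbitrary residue) and `Xa-b` or `X_a-b_` bounded gaps (hyphen
or en dash). Parsing the CXC consensus yields 10 constrained tokens (nine
ligand slots plus the signature Asn) separated by 9 gap tokens; the `[C/H]`
alternative exists only at ligand-2, exactly as the consensus is written.
Adjacent gaps merge, and patterns round-trip through their text form.

The scanner enumerates *all* distinct ligand registrations by backtracking
over gap lengths — variable gaps can register the same region in several
ways and downstream analyses need every option. Deduplication is by ligand
tuple, not span; output order is (start, ligand tuple). Non-canonical
letters (B, J, O, U, X, Z) never satisfy constrained tokens but do fill gap
positions. Equivalence with a naive try-every-gap-combination matcher is
asserted in tests for short sequences. Tandem detection pairs
non-overlapping matches with spacer ≤ max_spacer; spacer 0 is the
immediately-adjacent (EZ pre-SET) arrangement, and domain junctions are
assumed non-overlapping.

## Synthetic data (`zincluster.synthetic`)

* **Cluster coordinates.** The three metals sit on an equilateral triangle
  and each bridging Sγ on the perpendicular-bisector plane of its metal
  pair, lifted off the triangle plane. Requiring every bond to equal b =
  2.3 Å, every donor–metal–donor angle to be exactly tetrahedral, and the
  metal–S–metal bridge angle also tetrahedral gives a closed form: triangle
  edge d = 2b·sin(θ_t/2), circumradius R = d/√3, bridging donors at radius R
  and height b/3. Terminal donors complete each metal's exact tetrahedron.
  The construction satisfies the coordination restraints exactly; it is an
  idealization, not an energy-minimized structure, and carries an idealized
  (non-Ramachandran) local backbone per Cys purely so that selection and
  RMSD code paths have N/CA/C/O/CB atoms to work on. Per-model Gaussian
  coordinate noise emulates ensemble scatter; side-chain atoms (CB, SG) get
  1.5× the backbone noise by default, reflecting the generically higher
  side-chain variability of NMR ensembles (and making backbone ≤ heavy RMSD
  hold by construction). What passing tests on these ensembles shows is
  that the detection/fingerprint/RMSD machinery is correct — not that real
  refinement ensembles are this well-behaved.
* **Connectivity datasets** are derived from a ground-truth assignment by
  hiding chosen edges; coupling pairs follow from the truth's bridging
  structure. The default truth is the Zn₃Cys₉ map with bridging Cys 525,
  539, 553.
* **Intensity tables.** H/D decays are single exponentials with rates chosen
  per protection class so that detection counts at the three boundary times
  hit the requested targets (default 17/10/4) at the default 3× threshold;
  heteronuclear NOE tables realize a requested per-residue profile exactly
  at zero noise. Real exchange kinetics (EX1/EX2 regimes, baseline drift)
  are not modeled.
* **Sequences.** Implants draw each gap uniformly within the pattern bounds
  and embed in backgrounds drawn from the 17 letters that can serve neither
  as ligand (C, H) nor signature (N), which guarantees the implanted
  registration is unique — hence 100% recall with zero spurious tuples is
  the *expected* outcome, a correctness check rather than a benchmark. A
  570-residue "landmark" sequence carries the nine canonical Cys positions
  (525…561), Asn563 and His557/565 of the MSL2 CXC region in such a
  background; it is a synthetic stand-in, not the real MSL2 sequence.
* **Determinism.** Every generator draws from a named stream seeded by
  (seed, stable hash of the stream name), so artifact types are independent
  and reruns are byte-identical; golden-byte tests enforce this.

## Problem sizes and numerical choices

The test suite and the acceptance script run on desk-scale problems: 20-model
ensembles of ~60 atoms, connectivity problems with ≤ 12 ligands, 100 implant
sequences of a few hundred residues. Enumeration problems at these sizes are
exact, so no stochastic tolerance is involved; geometric comparisons use
1e-6–1e-9 Å tolerances, and the closed-form ensemble-RMSD expectation
√3·σ·√(1−1/N) is checked at 10% to absorb sampling noise and the small
variance absorbed by superposition.

## Known limitations

* No spectral processing, peak picking or resonance assignment; observables
  start from tabulated shifts/intensities.
* No structure refinement: violation scores are inputs, and the coordination
  restraints are emitted, not applied.
* The connectivity solver assumes fixed coordination numbers; mixed 4/5/6
  coordination requires per-metal settings and has not been exercised beyond
  the degree bounds the tests cover.
* The trinuclear coordinate construction covers the symmetric three-metal
  ring and mononuclear sites; other nuclearities (e.g. Zn₄Cys₁₁) are not
  generated.
* The scanner's backtracking is exponential in pathological inputs (long
  poly-Cys tracts with wide gaps); it is intended for natural sequences
  where ligand letters are sparse.
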