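# Methods

This note documents the models, parameter choices and limitations behind
`pepdyn`.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and units

Coordinates are stored in nanometres everywhere; conversion happens only at
format boundaries (PDB and DCD are in Ångström, GRO and XTC natively nm).
Atom indices are 0-based; residue numbers are 1-based and contiguous within
each chain, matching the conventional amyloid-beta residue naming (K28,
V40, …).  Chain species (ABETA42, ABETA40, SST14, AVP) are inferred by exact
sequence match; unknown sequences become OTHER and are excluded from
species-classified censuses with a logged warning.  When a periodic box is
present, each chain is made whole by minimum-image shifting relative to its
first atom before any distance computation; no re-imaging across frames is
attempted beyond that.

GRO files carry no chain identifiers; chains are split wherever the residue
numbering restarts, and receive positional labels A, B, C, …

## Synthetic trajectories

The generator emulates the study design the analyses target — eight
disordered Aβ chains (42- or 40-residue sequence) mixed with eight 14- or
9-residue cyclic peptides at approximately 4 mM — while staying cheap enough
that ground-truth recovery experiments run in seconds.

**Resolution.** Peptides are built at backbone resolution (N, CA, C, O, CB
for non-Gly, plus idealised aromatic ring atoms for F/Y/W/H).  This is
sufficient for every downstream consumer: the secondary-structure rules need
N/CA/C/O; hydrogen-bond detection uses backbone donors/acceptors with amide
hydrogens constructed geometrically (1.0 Å from N, anti to the preceding
carbonyl O); SASA is atom-sphere based; π–π tests need ring centroids.
Nothing in the package assumes an all-atom model.

**Geometry.** Chains are extended by NeRF placement with standard bond
lengths (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å), trans
peptide bonds, and motif torsions helix (−57°, −47°) and strand
(−139°, 135°); coil residues draw φ ~ U(−150°, −50°) and ψ ~ U(−60°, 160°),
the broad upper-left Ramachandran region populated by disordered chains.
The test suite recomputes φ/ψ from the built coordinates and checks them to
0.5°.  Hairpins use type-II β-turn torsions, which make the flanking
strands' end-to-end vectors antiparallel.  Cyclic peptides (SST14, AVP) are
approximated as linear chains whose conformation is chosen, among a small
set of canonical candidates, to minimise the distance of the disulfide pair
(C3–C14 for SST14, C1–C6 for AVP); the restraint shapes the builder only and
is not enforced during dynamics.

**Mixture placement.** Chains are placed with uniformly random positions and
orientations in a cubic box, rejecting placements whose minimum inter-chain
heavy-atom distance is ≤ 0.4 nm (the sparse-placement rule of the emulated
setup).  The default box edge is derived from the ~4 mM figure
(8 chains → 14.9 nm); since that concentration is approximate, the box is a
config value.

**Dynamics.** Frame coordinates are

    x(t) = rigid-group motion ∘ ( reference + Σ_k a_k(t) u_k + ε(t) )

with unit-norm mode shapes u_k over participant atom sets,
Ornstein–Uhlenbeck amplitudes a_k (stationary SD σ, correlation time τ,
update a(t+Δ) = a e^{−Δ/τ} + N(0, σ²(1−e^{−2Δ/τ}))), and isotropic Gaussian
per-atom noise ε.  Mode shapes come in two flavours: *incoherent* (an
independent random 3-vector per atom) and *coherent* (every participant
moves along one direction).  Coherent modes are what a quasi-rigid domain of
correlated motion looks like; they are the appropriate ground truth for
domain-recovery experiments, whereas incoherent modes exercise covariance
estimation.  Rigid groups undergo an optional random walk and rotation, and
a scripted schedule of merge events pulls group pairs together at a constant
drift rate.

**Ground truth and stickiness.** Contact between any two rigid groups
(minimum atom distance ≤ `contact_dist`, default 0.35–0.4 nm) fuses them
permanently, whether the contact was scheduled or incidental, and the frame
of first contact is recorded.  The per-frame chain partition in the
GroundTruth object is therefore exactly the partition a contact-graph
analysis of the frames should find — the property the aggregation-recovery
tests assert.  One master seed feeds separate substreams for mode
amplitudes, noise and rigid motion, so trajectories are bit-reproducible.

**What the generator does not emulate.** No force field, no solvent, no
realistic conformational ensembles or interface packing, no transient
un-binding (contacts are sticky), and no secondary-structure conversion
during aggregation.  Passing recovery tests therefore demonstrates that the
analysis stack measures what it claims on data with known structure; it
does not certify behaviour on real MD ensembles, where conformational
heterogeneity and marginal contacts add noise the generator lacks.

## Hydrogen bonds

A bond is recorded when donor–acceptor distance ≤ 0.35 nm and the
H–donor–acceptor angle ≤ 30°, the convention of the GROMACS analysis
ecosystem; both values are config keys.  Donors are N/O/S with an explicit
hydrogen (attached by proximity ≤ 0.12 nm) or, absent explicit hydrogens,
backbone amides with the constructed H; acceptors are N and O.  Pairs within
one residue and the covalently adjacent N(i)⋯O(i−1) amide pair are excluded.
Intra-molecular bonds are included in class totals by default (early-stage
mixtures are dominated by them) and also reported separately.  On rigid
ideal-geometry fixtures the constructed amide H can sit ~40° off the N→O
axis even where the Kabsch–Sander energy criterion accepts the bond; tests
that bridge the two definitions widen the geometric angle cutoff
accordingly.

## Secondary structure

Kabsch–Sander rules, implemented from the hydrogen-bond energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with bond iff
E < −0.5: n-turns (n = 3, 4, 5) yield G/H/I helices from two consecutive
turns; parallel/antiparallel bridge patterns yield B, laddered bridges E;
remaining turn spans T; bends (Cα angle > 70°) S; everything else C.
Overlap priority is H, E, B, G, I, T, S.  Residues missing backbone atoms
are forced to C with a warning.

"Stable β-sheet content" is the time average over the analysis window of the
per-frame percentage of Aβ residues assigned E — the only reading that needs
no extra parameter.  An alternative persistence definition (residue counted
when E in ≥ 50 % of window frames) sits behind a flag.  Occupancy statistics
default to Aβ residues only, with an all-chain option.  For the four-colour
occupancy scheme, S is merged into coil.

**Limitation — parallel sheets.**  Rigid ideal-geometry strands can be
placed to hydrogen-bond only in the mutual i↔j register, which the
Kabsch–Sander rules classify antiparallel; a cleanly registered parallel
ladder requires backbone relaxation the ideal builder deliberately lacks.
Parallel-sense detection is therefore verified at hydrogen-bond-topology
level (hand-enumerated ladder patterns), while antiparallel sheets and
hairpins are verified geometrically end to end.

## Solvent-accessible surface area

Shrake–Rupley with a deterministic Fibonacci sphere lattice (default 960
points), probe 0.14 nm, Bondi radii (C 0.170, N 0.155, O 0.152, S 0.180 nm);
all overridable.  Per-atom area is 4π(r+probe)² × (accessible points /
n_points).  The hydrophobic/hydrophilic split is element-based by default
(C, S hydrophobic; N, O hydrophilic), with a residue-set policy available;
the acceptance arithmetic on window means is policy-independent.  The
point-sampling error scales with the atom's sphere area, so convergence is
asserted as |Δarea| < 1 % of 4π(r+probe)² per atom when doubling the point
count.  Terminus exposure uses relative SASA of the terminal residue against
the Tien et al. (2013) theoretical maxima, threshold 0.25; in the reduced
atom representation absolute SASA is smaller than all-atom values, so the
threshold is a config key and the classification is exercised by constructed
cages and threshold sweeps rather than by literature values.

## Aggregates

Two chains are in contact when their minimum heavy-atom distance is
≤ 0.45 nm; aggregation status over a reporting window keeps an edge present
in ≥ 50 % of window frames (both config keys, logged in run metadata), which
suppresses transient detachment/re-adsorption flicker.  Components are
formatted as canonical composition strings, Aβ species first (`3Ab42+2SST14`);
ASCII species tags are used in all machine-readable output.  Contact
classification marks a residue pair hydrophobic when two side-chain C/S
atoms are within 0.45 nm, hydrogen-bonded via the hbonds module, and π–π
when aromatic ring centroids are within 0.55 nm.  π–π uses centroid distance
only — ring orientation in the reduced representation is stub-based, so no
plane-angle criterion is applied.

## Essential collective dynamics

Trajectory windows are cut into non-overlapping 0.2 ns segments (trailing
partial segments dropped).  Per segment, frames are optionally superposed
onto the segment mean (recomputed once after a first alignment pass) and the
3N×3N positional covariance C = ⟨Δr Δrᵀ⟩ is diagonalised; the top d = 10
eigenpairs define the essential coordinates, with a logged warning when they
capture < 95 % of the trace.  Atom images are

    χ_i = (√λ_1 e^(1)_i, …, √λ_d e^(d)_i) / √(Σ_{k≤d} λ_k),

dimensionless and segment-comparable; the mapping lives behind a small
strategy surface so an alternative normalisation can be swapped in.  Pair
correlation is the segment-mean image distance, flexibility the segment-mean
distance from the main-chain image centroid (the per-residue value is the
Cα image — the simplest definition consistent with a main-chain profile),
and domains are single-linkage clusters of images cut at a distance
threshold, with clusters under 20 atoms (config) off-domain and ranks by
size.

Covariance is not mass-weighted (uniform weights; a flag enables
mass-weighting).  Alignment before covariance defaults ON — otherwise
rigid-body motion dominates λ₁ — with OFF giving a lab-frame variant that
the recovery experiments use, since their ground-truth modes are themselves
translation-like.

**Threshold units.**  The clustering threshold is dimensionless in the image
normalisation above, and its numeric value transfers between pipelines only
if the image normalisation is identical.  The default (0.008) is exposed in
config, and `detect_threshold` provides a data-driven alternative: the
midpoint of the largest multiplicative gap in the single-linkage merge
distances.  Tests and the acceptance script calibrate from the detected gap,
never from the literature constant.

**Recovery experiment conditions** (fixed once, used by tests and the
acceptance script): 2–4 chain groups of 8-residue chains, two coherent
Cα-modes per group with σ_mode = 0.1 nm and τ = 10 ps, per-atom noise
σ_noise = 0.004 nm (σ_mode/σ_noise = 25), 10⁴ frames at dt = 1 ps.  The
flexibility-recovery experiment uses a single 6-residue chain with per-Cα
noise SDs log-spaced over a 5× range (0.01–0.05 nm) and d = 18 so the
retained modes span the per-atom noise space being ranked.

## Summary statistics

Replicate trajectories are summarised by the arithmetic mean and the sample
(n−1) standard deviation, rounded half-up at the printed precision — the
combination that reproduces the published footer rows this layer is tested
against.  Window percent decrease is round(100·(first−last)/first) half-up
to integer.  Windows are specified as `first:Xns` / `last:Xns`.

## Problem sizes

Tests and the acceptance script run the recovery experiments at 2–4 chains
of 6–8 residues and 2×10³–10⁴ frames, and mixture scenarios at 2+2 chains
and 300 frames — sizes where every ground-truth check is exact and the whole
suite completes in minutes on one core.  All analyses scale to full 16-chain
systems (the pipeline demo config runs one); SASA is the only stage where a
stride over frames is advisable.
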