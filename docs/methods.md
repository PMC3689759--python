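# Methods

## Scope and data model

`oligotraj` analyses multi-frame coordinate trajectories of small protein
systems — typically a dimer of 6–7-residue peptides, or a two-chain
protein like insulin — together with side tables produced by external
tools (per-snapshot MM-PBSA component energies; per-frame STRIDE
secondary-structure letters). It does not run molecular dynamics, solve
the Poisson–Boltzmann equation, compute normal-mode entropies or assign
secondary structure; those are upstream engines whose *outputs* are the
package's inputs.

Internally everything is angstroms and nanoseconds. GRO files (nm) are
scaled by exactly 10 on read; RMSD values are reported in nm because that
is the unit practitioners use at protein scale. Residue numbering is kept
1-based as printed in the input file, and chain identifiers follow the
file (for two-chain insulin, chain A = residues A1–A21 and chain B =
B1–B30). Backbone atoms are N, CA, C, O plus amide H/HN and terminal OXT;
side-chain heavy atoms are all other non-hydrogens, with glycine's CA
doubling as its side-chain center so per-residue side-chain centers of
mass are always defined. Box vectors are carried but minimum-image
wrapping is *not* applied: analysis frames are assumed whole.

## Nematic order and fibril state

For molecular unit vectors ẑᵢ (by default one end-to-end Cα vector per
chain) the order parameter is the largest eigenvalue of
Q = (1/2N) Σᵢ (3 ẑᵢẑᵢᵀ − I). It is invariant under global rotation and
under flipping any vector's sign, and lies in [0, 1]. For N = 2 the
closed form P₂ = (1 + 3|cos θ|)/4 holds exactly; the test suite uses it
as an oracle, which is the main reason the end-to-end vector is the
default (a per-residue backbone-segment mode is also provided, since the
order parameter is equally well defined on segment vectors).

A frame counts as fibril (two-strand β-sheet) when P₂ ≥ `p2_threshold`
*and* the number of inter-chain backbone–backbone hydrogen bonds is
≥ `min_backbone_hb`. Defaults: threshold 0.9 (the conventional value in
the order-parameter literature; configurable because reasonable studies
use 0.8–0.95), minimum 2 H-bonds (the standard β-sheet definition), and a
persistence of 1 frame (first occurrence). The fibril-formation time τ is
the time of the first frame starting a run of `persistence` consecutive
fibril-positive frames; means over repeat runs are plain arithmetic
means.

## Hydrogen bonds, contacts and pair energies

Hydrogen bonds are geometric: donor–acceptor distance ≤ 3.5 Å and D–H–A
angle ≥ 135°, both boundary-inclusive and configurable. The 3.5 Å cutoff
is the common heavy-atom criterion; the 135° angle is a convention, and
nothing downstream is sensitive to ±10° at the default geometries.
Donor/acceptor roles come from atom-name tables (backbone N–H and C=O
plus standard side-chain groups); donor hydrogens are attached
geometrically (any H within 1.4 Å of the donor heavy atom), which avoids
a hydrogen-naming table and tolerates moderate coordinate noise. A donor
with no attached hydrogen is skipped with a logged warning rather than an
error, since terminal residues in reduced topologies legitimately lack
one.

Side-chain contacts use the mass-weighted center of the side-chain heavy
atoms, cutoff 6.5 Å, boundary inclusive; a `whole_residue` switch uses
the all-heavy-atom center instead, because "center of mass of a residue"
is genuinely ambiguous in the field. Contact-probability maps are the
fraction of retained frames (time ≥ equilibration cut) in contact.

Residue-pair interaction energies are unscreened Coulomb
(332.0636·qᵢqⱼ/r kcal/mol with charges in e, r in Å) plus Lennard-Jones
4ε[(σ/r)¹² − (σ/r)⁶] with Lorentz–Berthelot combination (arithmetic σ,
geometric ε), summed over inter-residue atom pairs. There is no PME, no
exclusion or 1–4 scaling: this reproduces residue–residue interaction
maps, not an MD engine's total non-bonded energy. Parameters come from a
TSV sidecar; a missing parameter raises an error naming the atom.

## Free-energy landscapes

ΔG(V) = −RT ln[P(V)/P_max] over 1-D or 2-D histograms, R =
1.987×10⁻³ kcal mol⁻¹ K⁻¹, default T = 300 K so RT ln 2 = 0.413 kcal/mol.
Defaults: 50 bins per axis spanning the observed range padded by 1%
(binning is not a physical parameter and is always configurable). Empty
bins are masked, never set to a large finite value; the modal bin is
exactly 0 by construction. Minima are local minima of the masked grid
under 4-neighborhood comparison (2 in 1-D), with masked neighbors
treated as infinitely high, reported sorted by depth. No reweighting,
KDE or WHAM.

## Superposition and clustering

Kabsch superposition uses the weighted SVD construction with the
determinant correction, so reflections are excluded even for
near-degenerate inputs; collinear point sets are rejected. Pairwise
trajectory RMSDs use each pair's own optimal superposition, as the gromos
clustering method prescribes; fitted RMSD is symmetric and non-negative
but not a metric, and nothing here assumes the triangle inequality.

Clustering is the greedy gromos/Daura scheme: the frame with the most
neighbors within the cutoff becomes a center, it and its neighbors are
removed, repeat. Ties in neighbor count break toward the lowest frame
index, making the result deterministic; cluster ids are assigned in
extraction order so populations are non-increasing. The cluster
representative is the center frame (not an average structure).
Equilibration cuts are always explicit parameters, never inferred.

## MM-PBSA aggregation and inhibition constants

ΔG_bind = ΔE_elec + ΔE_vdW + ΔG_sur + ΔG_PB − TΔS per snapshot or per
trajectory mean, with the TΔS column stored as tabulated (typically
negative) and subtracted. Cross-trajectory spreads are *population*
standard deviations (divisor N): with only four repeat trajectories this
is the convention that matches how such tables quote their ± values, and
the package applies it to components and to ΔG_bind alike (the ± on
ΔG_bind is the spread of per-trajectory ΔG values, not a propagation of
component spreads — the two differ). K_I = exp(ΔG_bind/RT) in mol/L,
equal to IC50 under the Cheng–Prusoff noncompetitive (or K_m ≪ [S])
assumption; the summary object records that assumption explicitly.

`oligotraj.datasets` bundles the published four-trajectory component
table for LVEALYL and RGFFYT binding to insulin as worked-example input;
`scripts/acceptance.py` recomputes the per-row combinations from it at
run time.

## Synthetic data: what it emulates and what it does not

The dimer generator scripts the phenomenology an MD run of an
amyloidogenic peptide dimer exhibits — a disordered phase followed by an
antiparallel (or parallel) two-strand β-sheet — with exact ground truth:

* Ordered phase: idealized extended strands, Cα–Cα 3.5 Å along the
  strand, 4.8 Å between backbone lines, N/C carbonyl groups protruding
  0.335 Å toward the facing strand so that N···O distances are 2.9 Å and
  N–H···O angles ≈ 180°, giving up to 8 (antiparallel) or ≥ 3 (parallel)
  inter-chain backbone H-bonds under the default criterion. Side chains
  are a single Cβ pseudo-atom carrying the residue mass minus the
  backbone mass — enough for center-of-mass contacts, not for rotamers.
* Disordered phase: each chain rigidly rotated by a uniform SO(3)
  rotation about its centroid, centroids 40 Å apart, so no inter-chain
  H-bond can occur and the two-vector order parameter samples its
  disordered distribution (mean P₂ = 0.625 for N = 2, which is why the
  fibril criterion also requires H-bonds).
* Isotropic Gaussian noise of `noise_sigma` (default 0.1 Å, up to 0.3 Å
  in tests) on every coordinate; everything is reproducible bit-for-bit
  from one `numpy` Generator seeded per scenario.

Defaults (sequence LVEALYL, 7 residues, 100 frames at 0.1 ns, transition
at frame 50, antiparallel) mirror the study conditions the package is
aimed at. What the generator does *not* emulate: solvent, a force field,
emergent kinetics, intermediate/partially ordered states, β-register
defects, or chain flexibility. Passing tests therefore demonstrate that
the detectors recover a known signal under coordinate noise — not that
they would segment the messier order-parameter traces of real MD, where
threshold choice matters more.

Component and secondary-structure streams are i.i.d. Gaussian /
categorical draws; they validate aggregation statistics at the
central-limit rate, not autocorrelated MD time series.

## Numerical choices and degenerate inputs

* P₂ eigenvalues are clipped to [0, 1] against 1e-15 round-off.
* All cutoff comparisons are boundary-inclusive (≤, ≥).
* Zero-length molecular vectors, <2 vectors, ≠2 chains, empty component
  streams, empty histogram streams, all-zero probability grids, empty
  selections (for RMSD), collinear Kabsch inputs and out-of-range
  transition frames raise `ValueError` with a specific message.
* Histogram probabilities are bin masses (sum to 1), not densities.
* The Daura implementation and an independent brute-force enumeration are
  compared exhaustively on random ≤8-frame distance matrices in the tests.

## Problem sizes

The test suite and the acceptance script run on synthetic systems of two
7-residue chains (84 atoms), 20–200 frames per trajectory and 20
scenarios for the kinetics recovery check; these sizes give the detectors
thousands of frame-level decisions while keeping the whole suite in the
seconds range. The analysis code itself is O(n²) in atoms per frame for
H-bonds and in frames for clustering, which is adequate at desk scale; a
neighbor-list optimization hook was deliberately left out.

## Known limitations

* PDB/GRO carry no time axis; frame times come from a user-supplied `dt`.
* GRO I/O is single-frame and drops chain identity (the format has none);
  multi-frame output uses multi-MODEL PDB.
* No binary trajectory formats (XTC/TRR) in the core reader.
* The residue-pair energy model is deliberately naive (no screening);
  compare patterns between residues, not absolute values, against
  engine-computed energies.
* β-sheet registry is characterized only by the sign of cos θ; no
  per-strand twist or register assignment.
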