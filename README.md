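# oligotraj

Trajectory analysis for short-peptide oligomerization and peptide–protein
binding energetics, aimed at the workflow used to study amyloidogenic
insulin fragments such as LVEALYL (chain-B residues 11–17) and RGFFYT
(B22–27): deciding when a peptide dimer has formed a two-strand β-sheet,
mapping which residues hold it together, and turning end-point MM-PBSA
component tables into binding free energies and inhibition constants.

It is a library first (NumPy/pandas containers, MDAnalysis-backed PDB/GRO
I/O) with a thin `oligotraj` CLI on top.

## What it computes

**Fibril detection.** For each frame the nematic order parameter

P₂ = largest eigenvalue of Q = (1/2N) Σᵢ (3 ẑᵢẑᵢᵀ − I)

is computed from the chains' end-to-end Cα unit vectors ẑᵢ (P₂ = 1 for
perfect parallel *or* antiparallel alignment), together with cos θ between
the two end-to-end vectors and the number of inter-chain backbone–backbone
hydrogen bonds (geometric criterion: d(D···A) ≤ 3.5 Å, D–H–A angle ≥ 135°).
A frame is in the fibril state when P₂ ≥ 0.9 and ≥ 2 backbone H-bonds are
present — the standard two-strand β-sheet definition — and the
fibril-formation time τ is the first passage of that criterion.

**Free-energy landscapes.** ΔG(V) = −k_BT ln[P(V)/P_max] from the sampling
histogram over one or two reaction coordinates (typically P₂ and cos θ),
with empty bins masked and the mode at exactly 0.

**Contacts.** Side-chain contact maps (side-chain center-of-mass distance
≤ 6.5 Å), hydrogen-bond probability maps, and residue-pair Coulomb + LJ
interaction-energy maps.

**Conformations.** Kabsch superposition, Cα-RMSD series (nm), and greedy
RMSD-cutoff (gromos/Daura) clustering at tolerances such as 0.18–0.2 nm.

**Binding energetics.** MM-PBSA aggregation
ΔG_bind = ΔE_elec + ΔE_vdW + ΔG_sur + ΔG_PB − TΔS over per-snapshot
component tables, cross-trajectory means with population-SD spreads, and
K_I = exp(ΔG_bind/RT) = IC50 under the Cheng–Prusoff noncompetitive
assumption (R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹).

A synthetic-data module generates dimer trajectories with a scripted
disorder→β-sheet transition, Gaussian MM-PBSA component streams, and
STRIDE-letter secondary-structure streams, all with known ground truth, so
the whole pipeline is testable without MD runs.

## Worked example

```python
import oligotraj as ot
from oligotraj.datasets import MMPBSA_COMPONENTS

# binding energetics of LVEALYL against insulin (bundled literature table)
s = ot.summarize_trajectories(MMPBSA_COMPONENTS["LVEALYL"])
print(f"dG_bind = {s.delta_g_bind:.1f} +/- {s.delta_g_sd:.1f} kcal/mol")
print(f"K_I = IC50 = {s.k_i:.2e} M")

# fibril kinetics on a synthetic dimer with a transition scripted at 5 ns
sc = ot.DimerScenario(n_frames=100, transition_frame=50, noise_sigma=0.1, seed=7)
series = ot.order_series(ot.generate_dimer_trajectory(sc))
print(f"fibril first-passage time: {ot.first_passage(series):.1f} ns")
```

prints

```
dG_bind = -14.3 +/- 6.1 kcal/mol
K_I = IC50 = 3.82e-11 M
fibril first-passage time: 5.0 ns
```

i.e. averaging the four trajectory means gives a strongly favorable
binding free energy of −14.3 kcal/mol (spread 6.1 over repeats), a
sub-nanomolar predicted inhibition constant, and the first-passage
detector recovers the scripted 5.0 ns transition exactly.

The same analyses are available from the shell, e.g.

```sh
oligotraj simulate dimer --config scenario.yaml --out traj.pdb
oligotraj order --traj traj.pdb --dt 0.1 --criterion p2=0.9,hb=2 --out order.tsv
oligotraj cluster --traj traj.pdb --select "name CA" --cutoff 0.2 --out clusters.tsv
oligotraj mmpbsa --components traj1.tsv --components traj2.tsv --out summary.tsv
oligotraj run --config pipeline.yaml   # multi-stage run with a JSON report
```

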