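# ecdyn

Essential collective dynamics (ECD) analysis of molecular-dynamics
trajectories, aimed at intrinsically disordered proteins and their oligomers
(the packaged reference sequence is the 140-residue human α-synuclein).

## What it computes

Given a short, equilibrated trajectory segment of N atoms, the Cartesian
coordinate time series X(t) = (X₁(t), …, X₃ₙ(t)) is reduced by principal
component analysis of the covariance matrix

    C_ij = ⟨(X_i(t) − ⟨X_i⟩)(X_j(t) − ⟨X_j⟩)⟩ ,   i, j = 1 … 3N ,

with eigenvectors E⃗ᵏ sorted by decreasing eigenvalue.  Each atom i is mapped
to an **image** r⃗ᵢ — the concatenation over the leading k_max components of
the triplets (Eᵏ_{i,x}, Eᵏ_{i,y}, Eᵏ_{i,z}).  Distances in image space are
dimensionless measures of dynamic coupling:

* **pair correlations**  d_ij = |r⃗ᵢ − r⃗ⱼ| — small d_ij means atoms i and j
  move coherently;
* **main-chain flexibility**  F_Cα(i) = |r⃗ᵢ^Cα − ε⃗| with
  ε⃗ = (1/N_Cα) Σ r⃗ᵢ^Cα — low F means strong coupling to the collective
  main-chain motion.

Descriptors are averaged over consecutive sub-nanosecond segments (the
standard protocol: fifty 0.2-ns segments from the trailing 10 ns, 20
principal components, all heavy atoms, Cα descriptors).

Around the core the package provides

* deterministic extended-chain constructs: monomer, parallel (HH1/HH2) and
  antiparallel (HT1/HT2) dimers at a 14 Å axis separation, and a 2×2 stacked
  tetramer whose six chain pairs carry HH/HT labels;
* a harmonic-network Langevin generator whose stationary covariance is known
  in closed form (kT·L⁺ per axis, L the weighted spring-graph Laplacian), so
  every descriptor can be validated against planted correlation structure;
* supporting metrics: mean shortest-distance maps, RMSD traces, and
  secondary-structure occupancy/stability tables from external DSSP-style
  assignments (stable β: E occupancy > 80 %; stable helix: H/G/I > 50 %);
* readers/writers for multi-model PDB (biotite) and XTC/DCD (MDAnalysis), and
  a `ecdyn` command line (`build`, `simulate`, `ecd`, `dmap`, `rmsd`,
  `ss-occ`, `run`, `info`).

## Worked example

```python
import numpy as np
from ecdyn import (assemble_construct, model_from_construct, simulate,
                   SimulationConfig, default_two_chain_plan, select,
                   slice_segments, average_descriptors, superpose_frames,
                   compute_covariance, variance_captured)

spec, plan = default_two_chain_plan()          # two 40-residue chains,
construct = assemble_construct(spec)           # rigid blocks + linker,
net = model_from_construct(construct, plan)    # inter-chain coupling
traj = simulate(net, SimulationConfig(n_frames=2000, frame_interval=0.1,
                                      seed=1))

(segment,) = slice_segments(traj, window=200.0, take_last=200.0)
heavy = select(segment, "heavy")
model = compute_covariance(
    superpose_frames(segment, "segment-mean", heavy), heavy)
print(f"20 PCs capture {100 * variance_captured(model, 20):.1f}% "
      "of the variance")

segments = slice_segments(traj, window=100.0, take_last=200.0)
flex = average_descriptors(segments, heavy, 20, "flexibility")
res = np.array([a.residue_index for a in flex.atoms])
linker = (res >= 17) & (res <= 24)
print(f"mean F: linker {flex.values[linker].mean():.3f}  "
      f"blocks {flex.values[~linker].mean():.3f}")
```

prints

```
20 PCs capture 92.1% of the variance
mean F: linker 0.347  blocks 0.112
```

The first line shows the expected behaviour of an equilibrated fluctuation
segment — a small number of collective components carries 90–95 % of the
total displacement variance.  The second line is the parameter-recovery
readout: residues planted as a flexible linker (17–24) have roughly three
times the flexibility descriptor of the rigid blocks.

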