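# thermotraj

Trajectory descriptors for protein thermostability studies: hydrogen-bond
persistence statistics, RMSF/B-factors, solvent-accessible surface area, ion
radial distributions, group electrostatics, and multi-condition response
aggregation — exercised end-to-end on synthetic trajectories with planted
ground truth.

## The problem

Molecular-dynamics studies of enzyme thermostability (the motivating system
is a fungal laccase, a three-domain multicopper oxidase) probe how structure
responds to temperature, ionic strength, salt species and N-glycosylation by
running many short, independently seeded simulations and comparing
descriptors across conditions. The most sensitive proxy of
secondary-structure integrity in such panels is the **backbone hydrogen-bond
count** and, more stringently, the number of ***persistent*** backbone
hydrogen bonds — pairs whose geometric criteria hold for more than half of
the analysed frames. This package implements that analysis layer (it does
**not** run molecular dynamics): given a reference structure, coordinate
trajectories and a condition manifest, it computes per-trajectory
descriptors and the cross-condition response statistics, and it ships a
synthetic-data generator that plants known effect sizes so every stage is
testable without external data.

## The statistics

* **Hydrogen bond** (donor N–H, acceptor carbonyl O): counted in a frame iff
  d(D, A) < 3.5 Å and the angle between the D→H and D→A vectors is < 30°
  (both strict; the angular deviation at the donor, not the internal D–H–A
  angle). The per-simulation **average count** is the mean per-frame number
  of such interactions; the **persistence** of a pair is the fraction of
  window frames in which it holds, and a pair is *persistent* iff that
  fraction exceeds 0.5 strictly. The sum of per-pair persistences equals the
  average count exactly.
* **Salt bridges**: an Asp/Glu–Lys/Arg pair passes a pre-screen if any
  carboxylate O is < 3.2 Å from any basic side-chain N in at least one
  frame, and is retained iff the carboxylate-O/basic-N centre-of-mass
  distance is < 3.5 Å for more than 50 % of the frames.
* **Positional disorder**: frames are Kabsch-superposed onto the first frame
  over the backbone; RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩ converts to an isotropic
  B-factor via B = (8π²/3)⟨Δr²⟩, averaged per residue over non-hydrogen
  backbone atoms.
* **SASA**: Shrake–Rupley point sampling with a 1.4 Å probe on a
  deterministic Fibonacci sphere lattice (960 points by default).
* **Ion environment**: g(r) between amide hydrogens and halide anions under
  cubic periodic boundaries, and first-shell coordination numbers
  N(r) = ρ Σ g(r) 4πr² dr.
* **Electrostatics**: direct Coulomb sums E = k_e Σ q_i q_j / r_ij
  (k_e = 332.0636 kcal·Å·mol⁻¹·e⁻²) between atom groups, window-averaged,
  and the Pearson correlation between hydrogen-bond persistence and
  interaction energy.
* **Response aggregation**: per-condition descriptor table; OLS slope of
  counts vs temperature scaled to "per 50 K"; paired glycosylation and
  salt-type deltas with sign-consistency counts; ionic-concentration
  bookkeeping c = n_pairs/(N_A·L³).

## Worked example

Plant a persistence schedule on an ideal 12-residue α-helix and measure it
back:

```python
from thermotraj.synthetic import generate_peptide, generate_trajectory
from thermotraj.io import perceive_topology
from thermotraj.interactions import (
    hbond_persistence, persistent_count, average_hbond_count,
)

peptide = generate_peptide(12, "helix")          # 8 i -> i-4 amide pairs
schedule = {(5, 1): 0.73, (6, 2): 1.00, (7, 3): 0.40, (8, 4): 0.0}
traj, truth = generate_trajectory(peptide, 100, schedule=schedule, seed=1)
topology, peptide = perceive_topology(peptide)
table = hbond_persistence(traj, topology, peptide)
print(table.to_frame().to_string(index=False))
print("average per-frame count:", average_hbond_count(traj, topology, peptide))
print("persistent (>50%):", persistent_count(table))
```

prints

```
donor_res acceptor_res  donor_n  donor_h  acceptor_o  fraction
     ALA5         ALA1       19       20           3      0.73
     ALA6         ALA2       24       25           8      1.00
     ALA7         ALA3       29       30          13      0.40
     ALA9         ALA5       39       40          23      1.00
    ALA10         ALA6       44       45          28      1.00
    ALA11         ALA7       49       50          33      1.00
    ALA12         ALA8       54       55          38      1.00
average per-frame count: 6.13
persistent (>50%): 6
```

The four scheduled pairs show exactly their planted fractions (the pair
scheduled at 0 is absent), the four unscheduled helix pairs persist in every
frame, the average count 6.13 equals the sum of the fractions, and six pairs
exceed the 50 % threshold.

The same workflow scales to full condition panels from the shell:

```sh
thermotraj simulate --out-dir run/data --seed 0
thermotraj analyze  --manifest run/data/manifest.yaml --out-dir run/bundles \
                    --sasa-stride 10 --n-sphere-points 120
thermotraj compare  --manifest run/data/manifest.yaml --bundles run/bundles \
                    --out-dir run/response
thermotraj report   --response run/response
```

which generates 30 conditions (5 salt backgrounds × glycosylated/not × 300,
350, 400 K), analyses each trajectory, and reports the per-condition table
plus the derived temperature slope, glycosylation delta and sign
consistency, and salt-type delta.

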