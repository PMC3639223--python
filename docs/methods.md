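# Methods

This note documents the models, conventions and numerical choices behind
`thermotraj`, and what the synthetic-data generator does and does not
emulate.

## Analysis window

All persistence statistics (hydrogen bonds, salt bridges, window-averaged
energies) share one trailing analysis window. The default is the stretch of
frames covering the last 2 ns at the declared frame interval — 100 frames at
the 20 ps saving interval typical of the panels analysed here — capped at
the trajectory length. Descriptor means (RMSD, R_gyr, SASA) use the same
window.

## Hydrogen bonds

A donor–hydrogen–acceptor interaction counts as a hydrogen bond iff
d(D, A) < 3.5 Å **and** angle(D→H, D→A) < 30°, both strict; ties are
excluded. The angle is the deviation of the acceptor direction from the N–H
bond direction at the donor — deliberately *not* the internal D–H–A angle,
which is a different (stricter at equal numbers) criterion. Donors are
backbone amide N–H pairs; proline and each chain's N-terminal residue
contribute none. Acceptors are backbone carbonyl O atoms; the C-terminal
carboxylate (O and OXT) is excluded, so an n-residue, proline-free single
chain has n−1 donors and n−1 acceptors. Donor and acceptor within the same
residue are excluded; sequence-adjacent pairs are allowed since the
geometric criteria alone decide. Glycan (e.g. NAG) atoms are not part of the
backbone donor/acceptor sets, so backbone totals never mix in
carbohydrate–protein bonds.

Two counts are reported per trajectory: the **average** number of bonds per
frame, and the **persistent** count — pairs whose presence fraction strictly
exceeds 0.5. Because pairs never present are omitted from the persistence
table, the identity Σ fractions = average count holds to exact frame
arithmetic (asserted at 1e-12 in the tests).

## Salt bridges

Two-stage filter. Stage 1 (pre-screen): an (Asp/Glu, Lys/Arg) residue pair
is a candidate iff *any* carboxylate O to *any* side-chain N distance is
< 3.2 Å in at least one window frame. Stage 2: per frame, the mass-weighted
centre of mass of the carboxylate oxygens and of the basic nitrogens is
computed; the pair is retained iff the COM–COM distance is < 3.5 Å in
strictly more than 50 % of frames. Mass weighting is moot for the equal-mass
O and N sets (it reduces to the centroid) but is kept because the criterion
is stated as a centre of mass.

## Superposition and disorder

Superposition is a least-squares proper rotation (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) over a backbone selection;
the reference is the trajectory's first frame, matching the convention of
superposing all frames onto the initial frame before averaging. Selections
with fewer than three non-collinear atoms raise a degenerate-selection
error. RMSF is measured about the window-mean position after superposition
and converts to an isotropic B-factor via B = (8π²/3)⟨Δr²⟩; per-residue B is
the unweighted mean over that residue's non-hydrogen backbone atoms.
Hydrogens are included in the radius of gyration (standard atomic masses)
but excluded from residue B-factors.

For planted isotropic per-coordinate noise σ the closed forms are
RMSF → √3·σ and residue B → 8π²σ²; the tests recover both within 5 % at
2000 frames. The rigid fit absorbs six degrees of freedom, so the per-frame
RMSD of noisy frames against a clean reference has mean
√3·σ·√((3N−6)/(3N)); this is the linearized (small-σ) result and is what the
RMSD sanity test asserts at 2 %.

## Solvent-accessible surface area

Shrake–Rupley point sampling: each atom's sphere is inflated by the probe
radius (default 1.4 Å, water-sized) and covered with a Fibonacci
(golden-angle) lattice — deterministic, so results are bit-stable. A point
is buried iff strictly inside a neighbour's inflated sphere; the accessible
fraction times 4π(r+p)² is the atom's area, and residue areas are exact sums
of member-atom areas. Radii are the Bondi set by element (H 1.20, C 1.70,
N 1.55, O 1.52, S 1.80 Å), configurable. Coincident atoms are tolerated but
warned about: each copy counts its full surface. The default 960 points give
the isolated-sphere closed form within 1 % and < 2 % change on doubling.
Because the lattice is fixed in the laboratory frame, rotation invariance
holds only to sampling resolution (≈0.5 % on totals at 960 points); absolute
SASA values are implementation-dependent across packages, so only relative
and Δ quantities should be compared. Per-residue ΔSASA(t) subtracts the
frame-0 profile, which localises exposure gains such as a detaching terminal
segment.

## Ion radial distributions

g(r) uses minimum-image distances in a cubic box (edge per frame, supporting
fluctuating boxes), histogrammed in shells of width dr = 0.1 Å up to
r_max = min(10 Å, box/2), and normalised by shell volume, per-frame partner
density, reference-atom count and frame count — so a uniform partner field
gives g ≈ 1 in the bulk. Normalisation is *per reference (amide-H) atom*;
the coordination number N(r) = ρ Σ_{bins≤r} g·4πr²·dr is therefore the mean
number of partners within r per amide H per frame. The physically relevant
shells are ~2 Å for N–H···F⁻ and ~2.5 Å for N–H···Cl⁻ contacts. No
unwrapping is attempted; generator and readers supply consistently wrapped
coordinates.

## Electrostatics

Group–group energies are direct Coulomb sums over input partial charges,
E = k_e Σ q_i q_j / r_ij with k_e = 332.0636 kcal·Å·mol⁻¹·e⁻², no cutoff and
no periodicity. This is a deliberate simplification: the production
alternative is an Ewald-decomposed engine energy, but the analysis logic
under test (trailing-window averaging and the persistence–energy
correlation) is agnostic to the electrostatic backend, and the synthetic
systems the package ships are self-consistent under the direct sum. Charges
are always inputs (from the generator or a manifest), never derived from a
force field. Correlations are standard Pearson r with r² reported; constant
inputs raise rather than returning NaN.

## Response aggregation

The per-condition table keys on (temperature, salt, concentration,
glycosylation). Derived statistics:

* **Temperature slope**: within each (glycosylation, salt, concentration)
  family with ≥ 2 temperatures, the OLS slope of the count vs T, scaled to
  "per 50 K" (loss negative); the reported slope is the mean over families.
  OLS is the reproducible formalisation of an eyeballed per-step loss and
  reduces to the finite difference for two temperatures.
* **Glycosylation delta**: mean(on − off) over pairs matched on (salt,
  concentration, temperature), plus the count of pairs with on > off
  (sign consistency).
* **Salt-type delta**: KF − NaCl matched on (glycosylation, concentration,
  temperature).
* **Ionic concentration**: c = n_pairs/(N_A·L³) with the full cubic cell
  volume in litres, reported to two decimals. A water-volume variant
  c = n_pairs/(N_A·n_w·v_w) with configurable molecular volume (default
  30 Å³) is provided for completeness; only the cell-volume form is
  validated by the test suite, since the water-volume form depends on an
  assumed molecular volume.

## The synthetic-data generator

The generator produces data the *analysis* can be tested against, not
physical dynamics. What it emulates:

* **Ideal poly-alanine backbones** (N, H, CA, C, O per residue) built from
  standard internal coordinates by chain extension; φ/ψ = −57°/−47° yields
  an α-helix whose i→i−4 amide ladder satisfies the detection criteria
  (d = 3.09 Å, deviation 10.1° in the ideal frame), and 180°/180° a fully
  extended strand with none. Amide H sits on the C(prev)–N–CA external-angle
  bisector at 1.01 Å — also the construction used when an input structure
  lacks hydrogens.
* **Scheduled persistence**: each scheduled donor/acceptor pair is bonded in
  a deterministic frame prefix (first k of n frames) and broken afterwards,
  by placing the acceptor O on the donor's N→H axis at 2.9 Å (bonded) or
  4.2 Å (broken). Fractions are therefore exact rationals k/n, and the
  guard band around the 3.5 Å cutoff means Gaussian jitter with σ ≤ 0.05 Å
  cannot flip a state (> 7σ margin). In noise-free mode the generator
  re-detects the finished trajectory and raises unless the measured table
  equals the schedule exactly — recovery tests need no tolerance. Larger σ
  is allowed but drops the exactness guarantee.
* **Ion boxes**: ions are redrawn uniformly per frame (an ideal-gas partner
  field; it interpenetrates the peptide, which is intended — bulk g(r) ≈ 1
  everywhere). A sticky fraction of anions is pinned 2.0 Å beyond chosen
  amide hydrogens along the outward N→H axis — the N–H···F⁻ contact
  geometry — which keeps each pinned ion in the 2.5 Å first shell of exactly
  one site, so the planted coordination is n_sticky/n_sites. Shielding
  replaces the pinned anions with neutral glycan-like blocker particles at
  those positions and releases the anions to the bulk.
* **Condition panels**: 5 salt backgrounds × {glycosylated, not} × {300,
  350, 400 K}. The planted persistent count is linear:
  base − 9·(T−300)/50 + 3·[any salt] + KF deficit (−2 at 0.3 M, −6 at
  1.2 M) + glycosylation delta. The glycosylation delta is +5 per pairing
  except one adversarial pairing (1.2 M NaCl at 350 K) overridden to −4, so
  the paired mean is exactly 66/15 = 4.4 with 14-of-15 sign consistency —
  the headline effect sizes with a realistic outlier. The KF deficit is
  planted for both glycosylation states to keep the pairing arithmetic
  factorized. Defaults (180 residues → 176 realisable pairs, base 155,
  counts spanning 134–163, 100 frames at 20 ps, noise-free) are the panel
  conditions used by the reproduction script; the test suite runs a
  structurally identical panel scaled to 50 residues/base 30/20 frames,
  which exercises identical code paths — the recovery identities are exact
  at any size.

What it does **not** emulate: force-field energetics, water, correlated
backbone motion, diffusive ion kinetics, real glycan chemistry, or
temperature dependence beyond σ(T) = σ₃₀₀·√(T/300) jitter scaling. Passing
recovery tests therefore demonstrate the correctness of the measurement
machinery, not the realism of any simulation.

## Degenerate inputs and tie-breaks

Strict inequalities at every cutoff (3.5 Å, 30°, 3.2 Å, 3.5 Å COM, 50 %
threshold): a pair at exactly 50 % persistence is not persistent. Empty
detection results are valid (empty tables, zero counts); empty manifests
parse but aggregation refuses them. Superposition of < 3 or collinear points
raises; coincident atoms raise in Coulomb sums (singularity) and warn in
SASA (double counting). Thresholds outside [0, 1) and unrealisable schedule
fractions raise. Single-frame trajectories are accepted (persistence then 0
or 1 only).

## Problem sizes

Default test and reproduction sizes were chosen so the whole suite and the
reproduction script each run in minutes on one CPU: oracle equivalence on
100 random frames of a 50-residue peptide (exhaustive all-pairs loops),
disorder recovery at 2000 frames, RDFs at 10⁴–10⁵ pair samples, panels of 30
conditions. The SASA stage of panel analysis subsamples frames (stride 10)
and uses a 120-point lattice; SASA enters no planted-recovery identity, so
only its own closed-form and convergence tests use the full 960-point
default.

## Known limitations

* Only cubic boxes; no triclinic minimum image, no unwrapping.
* PDB and XYZ trajectories only (text formats); binary formats are out of
  scope.
* Absolute SASA values are not comparable across implementations (radii and
  sampling differ); use relative quantities.
* The direct Coulomb sum is not an Ewald energy; absolute energies of
  periodic ionic systems are not meaningful, only the correlation/averaging
  analyses built on them.
* Donor/acceptor perception covers backbone amides plus Asp/Glu/Lys/Arg
  side-chain groups; histidine, side-chain hydroxyls and water are not
  perceived.
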