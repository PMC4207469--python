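# Methods

This note documents the models, conventions and parameter choices behind
`membranekit`, and what its synthetic benchmarks do and do not
demonstrate about real coarse-grained (CG) membrane trajectories.

## Units and geometry

Internal lengths are Angstrom and times nanoseconds; GRO files (nm, ps)
are converted at the I/O boundary. All boxes are orthorhombic — the
systems this package targets are built and simulated in rectangular
boxes — and triclinic input is rejected. Every distance uses the
minimum-image convention; `mode="xy"` wraps and measures only the
lateral components, which is what all in-leaflet statistics use. The
cutoffs that define the analyses (11 Å lipid–lipid contacts, 15 Å
cluster neighbourhoods, 8 Å protein connectivity, 6 Å protein–lipid
contacts) are expressed in Å, which is why Å is the internal unit.

## Species registry

Ten CG lipid types are registered: POPC, POPE, POPS, DOPC, DOPE, DOPS,
PPCS (palmitoyl sphingomyelin, alias "Sph"), GM3, PIP2 and CHOL. Each
species declares three functional bead subsets used by the analyses:

* `head_beads` — the polar head group; its centroid is the per-lipid
  point for clustering, grid binning and leaflet assignment;
* `linker_beads` — glycerol esters (GL1/GL2) or amide alcohols
  (AM1/AM2); lipid–lipid contacts are defined between linker beads;
* `interface_bead` — first tail bead under the head group; its z
  coordinate defines the local bilayer surface height.

PPCS and GM3 carry two 4-bead ceramide tails; PIP2 carries a 4- and a
5-bead unsaturated tail and a net charge of −4; POPS/DOPS and GM3 carry
−1. Cholesterol is special-cased: ROH serves as head, linker and leaflet
reference, because the molecule has no glycerol backbone and exchanges
between leaflets.

## Leaflet assignment

Lipids are tagged `outer` / `inner` / `core` against a *local* midplane:
the mean z of lipid linker beads per lateral grid cell (4×4 by default),
so assignment stays correct in undulating membranes where a single
global plane would misclassify lipids on large-amplitude bumps.
Cholesterol is excluded from the midplane estimate — its reference bead
is the quantity being classified, and including molecules that sit in
the core or hop between leaflets would bias the plane they are judged
against. A lipid is `core` when its reference z is within
`core_half_width` (default 10 Å, a value on the order of one monolayer
thickness; the three-state bookkeeping needs *some* boundary and results
are insensitive to ±3 Å) of the local midplane.

## Membrane construction

The builder follows the "edit a template" strategy: a flat all-POPC
bilayer on a jittered square lattice (lateral edge `sqrt(n_per_leaflet
× apl)`, default 53.3 Å² per lipid so that 750 lipids per leaflet give a
~20×20 nm patch), then per leaflet a seeded uniform draw of POPC
molecules is converted to the target species. Integer targets come from
largest-remainder rounding of the fractions (ties broken by species name
order), so every count is within one lipid of `fraction × leaflet size`
and the same recipe always yields the same composition. The exchange is
one-for-one: leaflet totals never change, which realises the equal
per-leaflet lipid percentage that keeps the two monolayer areas matched.
Cholesterol's per-leaflet fractions produce its initial equal split
between leaflets.

Conversion rules: POPE/POPS/PPCS (same bead count as POPC) inherit the
POPC bead coordinates positionally; DOPC/DOPE/DOPS/PIP2/GM3 are
rigid-superimposed (Kabsch on anchor beads) onto the POPC's first two
tail beads; cholesterol is superimposed onto the head group (PO4) plus
the first three tail beads. Idealized straight-chain conformers stand in
for coordinates transferred from a simulated bilayer: no MD snapshot is
required, and every analysis in this package operates on configurations,
not energies, so the idealized geometry is sufficient. Collinear anchors
leave the rotational roll undefined; any optimum is accepted, and runs
remain bit-reproducible under a fixed seed.

Transmembrane proteins are idealized single-helix backbones (one bead
per residue, 1.5 Å rise, 100° twist, 24 residues by default, spanning
~36 Å) placed on a centred rectangular grid whose nearest-neighbour
spacing equals the requested value exactly; a grid that cannot keep that
spacing under the periodic wrap is rejected. Lipids with any bead within
the exclusion radius (default 3 Å) of any protein bead are deleted —
all clashing lipids are removed and the per-species removals are
reported rather than forced to a preset total. Replication tiles the
frame laterally and renumbers molecules, scaling every species count by
`nx × ny`.

## Synthetic benchmarks

The generators plant exactly the statistical structure each analysis is
supposed to measure and return it in a manifest:

* **Random mixing** — uniform positions with a 7 Å periodic hard core
  (batch random sequential addition) and species labels assigned by a
  uniform random permutation of the integer composition counts. The
  label permutation, not the positional process, carries the mixing
  null, so residual structure in the point pattern cannot leak into the
  species statistics. The default synthetic area per lipid is 90 Å²:
  comfortably below the ~54.7 % jamming coverage of random sequential
  disc packing (7 Å core at 90 Å² is ~43 %), while still giving every
  lipid ~3 neighbours inside the 11 Å contact shell.
* **Planted clusters** — the target species sits in sunflower-spiral
  discs (neighbour spacing ~8 Å, well under the 15 Å DBSCAN cutoff)
  whose centres are separated by at least 45 Å plus the disc radii;
  singletons are isolated by the same margin. Under these margins the
  density clustering must recover the planted partition exactly, so the
  size-bin time series is scored against the manifest with equality.
* **Curvature coupling** — the surface is a sum of sine modes scaled to
  a given amplitude, both leaflets displaced congruently (constant
  thickness). Species positions are drawn by thinning a uniform proposal
  with intensity 1 + c·ẑ, where ẑ is the surface scaled to unit
  maximum; |c| ≤ 1 keeps the intensity non-negative, and negative c
  enriches the species in the troughs, producing a negative
  R<sub>L,z</sub> whose magnitude grows with the per-box expected count
  (Poisson counting noise attenuates it below |c|).
* **Diffusion** — independent lateral Gaussian walks with per-axis step
  variance 2·D·dt (so the lateral MSD slope is 4D); frames store wrapped
  coordinates, the manifest the exact unwrapped walk.
* **Flip-flop** — cholesterol z follows a discrete-time three-state
  Markov chain (outer/core/inner) satisfying detailed balance with the
  requested stationary occupancy; the core exit rates are split in
  proportion to the leaflet occupancies and scaled so the expected
  full-crossing rate summed over molecules equals the requested
  events/ns. The manifest logs every true crossing of the simulated
  chain. Static phospholipid filler on a jittered lattice in both
  leaflets keeps the local midplane estimate unbiased in every grid
  cell.

What passing these benchmarks shows: the estimators recover known
parameters from data with the assumed statistical structure, at the
sample sizes used. What it does not show: correctness on real MARTINI
ensembles, where lipids interact, diffusion is neither Gaussian nor
independent at short times, membrane undulations are not stationary sine
modes, and leaflet exchange kinetics need not be Markovian. The
generators validate the measurement pipeline, not the physics.

## Contact analysis

A lipid pair is in contact when the minimum-image distance between any
of their linker beads is strictly below 11 Å; however many bead pairs
qualify, the pair counts once. Cholesterol is excluded from leaflet
contact statistics since it cannot be assigned to one leaflet over time.
Pair counts are summed over the analysis window (sum-then-normalise,
rather than averaging per-frame fractions) and converted to ordered
rates r(A→B) = C(A,B)/Σ<sub>t</sub> N<sub>A</sub>Ñ<sub>B</sub> with
Ñ<sub>B</sub> = N<sub>B</sub> off-diagonal and N<sub>A</sub>−1 on the
diagonal, then row-normalised. This abundance correction is what makes
the fully mixed expectation exactly 1/k for k species independent of
composition (0.5 and 0.25 for two and four species), because under
random mixing every unordered pair is a contact with the same
probability and the rate cancels out of the row normalisation. The
matrix need not be symmetric: f(A→B) is A's contact budget spent on B,
which differs from B's budget spent on A whenever neighbourhood sizes
differ.

Lateral RDFs are two-dimensional: shell counts normalised by annulus
area and the target's planar density, with g(r) → 1 for random
placement; protein-centred curves use each protein's lateral centre of
geometry and average over proteins. Per-residue protein–lipid contacts
count selected lipid beads within 6 Å of a residue's beads; a residue is
flagged persistent when at least one contact is present in more than
50 % of frames.

## Cluster analysis

DBSCAN runs on lateral head-centroid positions with periodic distances.
A point is core when its eps-neighbourhood *including itself* holds at
least `min_elements` points (the common minPts convention); clusters are
the connected components of the core points; border points join the
cluster of their lowest-index core neighbour — a deterministic,
order-stable tie-break — and each noise point becomes its own singleton,
so the size bins partition all lipids. Clustering is purely lateral
(xy): nano-domains are in-leaflet structures and the analysis is run per
leaflet. Protein clusters use single-linkage connectivity (any
inter-protein bead pair within 8 Å) and are reported per frame with the
largest-component series.

## Flip-flop analysis

States are assigned geometrically per frame; an event is a completed
crossing outer→inner or inner→outer, with core passages permitted in
between. A crossing is only recorded once the molecule persists in the
new leaflet for `min_dwell` consecutive stored frames (default 5):
without a debounce, boundary noise at the core threshold inflates rates,
and the detected count is then stable under stride refinement as long as
the dwell time in ns is held fixed. The rate is events/ns summed over
molecules (a whole-system rate), and occupancy is the raw time-averaged
state fraction.

## Diffusion analysis

Wrapped trajectories are unwrapped by the minimum-image step rule (valid
while per-frame displacements stay below half the box; violations raise
with guidance), the per-leaflet lateral centre of motion is subtracted
(leaflets can drift antisymmetrically, so a global correction would
under-remove), and the MSD is averaged over all molecules and time
origins via the standard FFT decomposition, which is verified against a
direct O(T²) reference to 10⁻⁹ relative. D is the least-squares slope
over lags in 10–50 % of the maximum lag, divided by 4 (two lateral
dimensions), with 1 Å²/ns = 10⁻⁷ cm²/s. Short lags are excluded for
crossover effects and long lags for origin starvation. The reported
standard error is the OLS slope error; MSD values at neighbouring lags
are strongly correlated, so it understates the true estimator spread —
windowed estimates (1 µs windows by default) are the honest way to see
run-to-run variability.

## Curvature analysis

Lipids are binned by head-centroid into half-open periodic grid boxes
(8×8 default; the grid dimension, not a physical box size, is the
controlling parameter). The surface height z<sub>n</sub> of a box is the
mean interface-bead z of its lipids excluding the species being
correlated, so a species cannot correlate with itself through the
surface definition. R<sub>L,z</sub> is the Pearson correlation over
non-empty boxes — Pearson is the natural normalisation that bounds the
statistic in [−1, 1] — computed per frame with z̄ taken per frame, and
reported as mean ± SD over frames. Zero-variance frames (flat surface or
constant counts) contribute R = 0 and are counted separately. Empty
boxes are excluded from the sums. The interleaflet map correlates outer
and inner per-box species counts pooled over frames; local thickness is
the per-box outer-minus-inner interface separation, and its correlation
with the mid-height is reported so constant-thickness (congruent
displacement) can be asserted.

## I/O and reproducibility

GRO reading and writing is implemented against the fixed-column dialect
with molecule grouping inferred from residue-number runs, precise
line-numbered errors for malformed files, velocity preservation, and
nm↔Å conversion; round-trips preserve coordinates to the format's
0.001 nm. The writer is cross-checked against MDAnalysis in the test
suite. Proteins are written as a single `PROT` residue (residue-level
labels are not preserved across a GRO round trip; analyses needing
per-residue labels should run before writing). Multi-frame GRO files are
parsed block-wise for trajectories; frame times come from `t=` title
fields (ps in file, ns internally).

Every randomised operation takes an explicit seed and is bit-reproducible
under it; CLI runs write a provenance record (command, parameters, seed,
version, input checksums).

## Problem sizes used in the validation suite

The test suite and acceptance script run at desk scale: mixing
calibration on 50 frames × 1000 lipids per condition; diffusion recovery
on 5000 frames × 1500 lipids (three species at D = 1.5, 2.0 and
2.6×10⁻⁷ cm²/s, the plasma-membrane scale); flip-flop recovery on 100
cholesterol over 1000 ns at 0.14 events/ns; curvature recovery on
20–50 frames of 2560-lipid bilayers. These sizes give the estimators
enough statistics that the planted parameters are recovered within the
stated tolerances while keeping the whole suite to a few minutes.

## Known limitations

* The builder's idealized conformers produce a sterically sane but
  unequilibrated configuration; it is a starting structure, not an
  ensemble member.
* Leaflet assignment assumes an intact bilayer; it is undefined for
  micelles, pores or single-leaflet systems (synthetic single-leaflet
  frames carry their tags from the generator instead).
* The flip-flop rate depends on the dwell debounce for noisy
  trajectories; the default 5 frames is conservative at 1 ns output
  spacing.
* No energetics anywhere: contacts are geometric, and the package makes
  no claim about interaction strengths or free energies.
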