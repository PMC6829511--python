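# Methods

This note documents the models, estimators and numerical conventions behind
`mempsn`, the design choices made where several definitions were defensible,
and what the bundled synthetic fixtures do and do not establish about real
trajectories.

## Units and geometry

Lengths are Å, times ns, charges elementary charges throughout; sources in
nm (GRO/XTC) or ps are converted at the I/O boundary, because interaction
cutoffs in the residue-network literature are quoted in Å. All inter-atomic
distances use the minimum-image convention for **orthorhombic** boxes (the
box lengths of each frame). Nearly rectangular triclinic membrane boxes are
handled as orthorhombic; strongly skewed cells are outside scope.

## Chemical roles and node granularity

Roles (H-bond donor/acceptor, charged positive/negative, hydrophobic) are a
pure function of `(residue_name, atom_name)` via an editable YAML lookup
(`data/role_map.yaml`) covering the 20 amino acids, PS/PE/PC lipids and the
myristoyl group; backbone N/O roles are applied uniformly to protein
residues. Unknown residues are reported — raised by default, or labelled
`unknown` under `on_unknown="warn"` — never dropped silently.

Network nodes are one per protein residue, one per lipid molecule and one
for the myristoyl group. Water and ions are not nodes. Protein keys are
one-letter code + residue number (`R43`), lipids `PS_17`-style, the acyl
anchor `MYR`.

Because coarse topologies carry no bond table, a hydrogen belongs to a donor
when it is an H atom of the same residue within 1.3 Å of the donor in the
analysed frame. This geometric rule matches covalent N–H/O–H distances
(~1.0 Å) with a safety margin and needs no connectivity input.

## Contact criteria and persistence

Defaults (all overridable through `Cutoffs` or the YAML config, and echoed
into output headers):

| class | criterion |
|---|---|
| hydrogen bond | donor–acceptor ≤ 3.5 Å and donor–H–acceptor ≥ 120° |
| salt bridge | any-atom ≤ 4.5 Å between oppositely charged groups |
| hydrophobic | group centre-of-mass ≤ 5.0 Å |

The hydrophobic set comprises Ala, Val, Leu, Ile, Met, Phe, Trp, Pro side
chains plus lipid acyl carbons and the myristoyl chain. Intra-protein pairs
i, i±1 on one chain are excluded (covalently forced); protein–lipid pairs
have no such exclusion and are restricted to lipids whose head-group
centroid lies in the upper leaflet. Leaflet membership is recomputed per
frame by default (`initial` mode freezes it at the first frame); the
midplane is the mean head-group z, ties go to `upper`.

Persistence of a (pair, class) is the fraction of analysed frames in which
the criterion holds; classes are tracked independently until the network
merge, and a pair satisfying both salt-bridge and H-bond geometry in one
frame is counted once in each class (the merge de-duplicates edges while
keeping per-class persistences as attributes). Persistence is invariant
under frame reordering and additive over concatenated replicas:
(k₁+k₂)/(n₁+n₂).

Leaflet separation is diagnosed by the between-class fraction of the
head-group z-variance explained by the midplane split: ~1 for a bilayer,
≈0.75 for a uniform (micelle-like) z distribution, ≈0.64 for a unimodal
Gaussian; assignments below 0.85 are flagged poorly separated but still
returned.

## Threshold selection and the structure network

The persistence threshold p_T (percent scale) is selected by the largest
hydrophobic-cluster criterion: the hydrophobic graph is filtered at cutoffs
c = 0…100 in steps of 0.2 percentage points, the largest
connected-component size is recorded at each c (isolated nodes do not count
as clusters), and a four-parameter logistic
`bottom + amplitude / (1 + exp((c − c0)/width))` is fitted to size-vs-c;
p_T = c0. Constant or single-step curves raise an explicit
threshold-undefined error suggesting a manual p_T. The sweep step and the
logistic form are fixed defaults, overridable.

p_T lives on the percent scale (e.g. 20.2); persistences are fractions
(e.g. 0.13); every interface converts explicitly. Class graphs keep edges
with persistence ≥ p_T/100 and are unioned into one undirected graph whose
edges carry per-class persistences, the contributing class list and
`max_persistence`. Filtering is monotone in p_T by construction.

Hubs are nodes of degree ≥ 3 (configurable); the degree-colour labels
blue/yellow/orange for degrees 7/8/9 are exported for rendering parity with
the conventional depiction of major hubs. Degree deltas between states are
restricted to nodes that are hubs (degree ≥ 7 by default) in at least one
state; a node missing from one network carries degree 0 there and is
flagged.

The per-residue lipid-contact profile aggregates a residue's persistences
over its lipid partners within each class by the **maximum** (the bar answers
"how persistently is this residue lipid-engaged", not "with which specific
molecule"); summation over partners is available via `aggregate="sum"`.
Rows with all classes ≤ 0.13 are omitted from the report.

## Communication robustness

For nodes A, B the census computes the BFS distance l and the exact number
σ of distinct shortest paths by accumulating path counts over the BFS
predecessor DAG; explicit path listing is capped at 10 000 (the count stays
exact beyond the cap, and the score uses only the count). The CR index is

    CR_AB = σ_AB · p_T / l,

zero for disconnected pairs and equal to p_T for adjacent pairs with a
unique path. CR is symmetric, linear in p_T (so rankings are p_T-free) and
increases with redundancy while decreasing with distance; the alternative
reading σ·p_T·l is exposed behind `form="product"` for sensitivity checks
only, since it would rank long detours above direct routes. EF-hand
representative residues default to E85 (EF2) and E121 (EF3), configurable.

## SASA and insertion events

SASA uses Shrake–Rupley with golden-spiral test points (default 960) on each
atom's solvent-accessible sphere (van der Waals radius + 1.4 Å probe);
neighbours are found with a k-d tree. Radii come from per-atom values when
present, else from the Bondi set in `data/vdw_radii.yaml`; a missing radius
is an explicit error naming the atom. By default every non-water, non-ion
atom occludes — lipids must occlude the myristoyl chain or the burial signal
does not exist — with a protein-only mode available. An isolated atom
reproduces 4π(r+probe)² to well under 1%, doubling the sphere points changes
it by < 0.5%, and disjoint atoms are exactly additive.

Insertion detection is an operational definition with every constant
exposed: smooth with a 5-frame moving median; baseline = median over the
baseline window (default the first quarter of the trace); **end** = first
time the smoothed series falls below `low_fraction`·baseline (default 0.25)
and stays below for `stable_span` ns (default 10); **start** = last time
before the end still above (1 − `low_fraction`)·baseline; **completed** when
the low state persists to the end of the series. All thresholds are
baseline-relative, so calls are invariant to uniform scaling. Flat traces
and dip-and-recover excursions return no event. Real insertion traces drop
steeply at onset (first contact with the head-group region buries a large
area fraction at once), which is why the start call lands at the departure
from the plateau; the synthetic descent reproduces exactly this shape.

## Macrodipole

μ_z(t) = Σᵢ qᵢ·(zᵢ − z̄(t)) in e·Å, converted at 4.8032 D per e·Å. The
reference z̄ is the selection centroid, making the reported value
origin-independent for net-charged proteins (bead fixtures carry no masses;
for all-atom systems the geometric and mass-weighted centroids differ
negligibly on the z-projection's sign structure, which is the observable of
interest). Missing partial charges raise an error; an explicit opt-in
fallback substitutes formal charges (±1 on charged side-chain atoms per the
role map). The sign-reversal count of μ_z(t) is reported.

## Density maps and lateral MSD

The 2D number density is atoms per cell volume (cell edge² × slab height),
averaged over frames, with optional per-frame lateral re-centering on an
anchor selection (e.g. the myristoyl group) so the map is drawn in the
anchor's co-moving frame. Conservation holds exactly:
Σ(density × cell volume) × n_frames equals the number of atom-in-slab
observations.

Lateral MSD unwraps head-group positions by accumulating minimum-image
frame-to-frame displacements, then averages squared xy-displacements over
all head groups of a lipid type and all time origins, for lags up to half
the run. D = slope/4 by least squares over the fit window, default 10–50% of
the covered lags: shorter lags are dominated by discrete-hop noise and
longer lags by the few, strongly correlated origins, so the middle of the
curve carries the reliable slope (1 Å²/ns = 10⁻⁷ cm²/s). A log-log slope
over the same window is reported as the anomalous exponent; values above 1.5
flag super-diffusive (e.g. ballistic, MSD = v²t²) motion.

## Essential dynamics

Frames are least-squares superposed (Kabsch, equal weights) onto a reference
— the first frame by default; any fixed reference yields equivalent
subspaces for these checks — before the 3N×3N covariance of Cα positions is
diagonalised. The top S = 20 eigenvectors span the essential subspace;
`superpose=False` skips the fit for pre-aligned or analytic inputs, since
least-squares fitting necessarily redistributes part of any single-atom
motion into the rigid-body modes. RMSIP is computed exactly from the S×S
inner-product matrix: 1 for identical subspaces, 0 for orthogonal ones, and
≈√(S/n) on average for random S-subspaces of an n-dimensional space.
Projections onto PC1/PC2 support a bounding-box intersection-over-union
overlap between replicas — reported as a coarse homogeneity indicator, not
tested against any reference value.

## Synthetic fixtures: what they emulate, and what they do not

All generators are pure functions of their configuration, seed included.

**Membrane patch.** 260 lipids, 20% PS / 40% PE / 40% PC (exact counts by
largest-remainder apportionment, split evenly between leaflets), in a
90 × 90 × 160 Å box; head-group planes sit ±18.5 Å from the bilayer centre.
Each lipid is a bead column — phosphate (negative), ester oxygen (acceptor),
ammonium/choline (positive; with a donor hydrogen for PS/PE), a PS
carboxylate, two acyl beads — whose head beads perform independent 2D
Brownian motion at a configurable lateral diffusion coefficient (default
5×10⁻⁷ cm²/s for every type, chosen so displacements are resolvable within
the 50 ns fixture runs; fixture defaults are 500 frames at 0.1 ns).

**Contact schedules.** A protein-like chain of single-function bead residues
sits 16.5 Å above the upper head-group plane, residues 15 Å apart so a
scheduled contact cannot accidentally engage a neighbour. For each scheduled
(pair, class, p), the relevant lipid bead is placed inside the class
criterion in exactly round(p·n_frames) seeded-random frames and at its
membrane position (≥ 10 Å margin) otherwise. Scheduled lipid nodes must name
upper-leaflet lipids; the generator retypes lipids by swapping within the
leaflet so composition counts are preserved. Conflicting entries for one
(pair, class) are a configuration error.

**Myristoyl descent.** A 14-bead chain above the patch descends through the
head-group plane between the configured start and end times. Beads below
the plane are enclosed by 12-bead icosahedral cages of acyl beads hosted by
the four nearest upper-leaflet lipids — a scripted stand-in for the dense
acyl packing around an inserted chain — so buried beads have exactly zero
SASA. The buried-bead count jumps to 4/14 just after the start (the SASA
drops well below the 75%-of-baseline start criterion, making the configured
start the last plateau time), climbs to 9/14 through the window (safely
above the 25% end criterion) and reaches 11/14 at the end (safely below),
then ramps to full burial. Under the detection rule above, the true event
times of the fixture are therefore the configured window; the `dip` mode
buries briefly and recovers, which the stability clause rejects.

**Toy graphs and threshold fixtures.** Named topologies (cycle, path, star)
and seeded Erdős–Rényi graphs carry persistence attributes for path tests.
The threshold fixture builds a chain whose edge persistences lie on the
inverse logistic, so the largest-component-size curve follows a logistic
with a prescribed inflection; small seeded jitter (σ = 0.05 percentage
points) makes fixtures distinct without moving the inflection.

**Limitations.** The fixtures exercise the detectors' geometry, counting and
estimation logic, not membrane physics: there are no energetics, no lipid
tail entanglement, no water, no protein internal dynamics, and bead
geometries are far simpler than all-atom force-field structures. Passing
tests therefore establish correctness of the analysis chain — that
persistences, thresholds, path counts, SASA, event calls, D and RMSIP are
computed right — not that any biological conclusion transfers to a specific
real system.

## Problem sizes

The test suite and acceptance script use desk-scale fixtures chosen as the
smallest systems that leave each estimator's statistics meaningful: ≤ 500
atoms and ≤ 200 frames for oracle recounts, 200 lipids × 500 frames × 20
seeds for diffusion recovery, 50 random 30-node graphs for path censuses,
20 logistic fixtures for threshold recovery. With these sizes the whole
suite runs in well under a minute.

## Known limitations

* Orthorhombic minimum image only; no π-stacking, cation-π or
  water-mediated-bridge detection; no suboptimal-path ensembles or
  centralities beyond degree; no curvature/order-parameter/thickness
  analyses.
* SASA ignores periodic images (selections are assumed whole and inside the
  box).
* The H-to-donor association is geometric; exotic naming schemes whose
  hydrogens sit > 1.3 Å from their donor would need an adapted role map.
* Leaflet assignment assumes a planar bilayer normal to z; strongly curved
  or vesicular geometries will be flagged poorly separated rather than
  handled.
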