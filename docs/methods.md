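# Methods

`fibronet` maps where a fibrous tissue geometry can structurally support
micro-anatomical reentry — continuous electrical activation circulating
around a fibrotically insulated fibre tract.  The model is purely
structural: tissue is reduced to a spatial network whose edges represent
electrical coupling, interstitial fibrosis is modelled as the progressive
loss of transverse edges (a percolation-style process), and a region is a
reentry substrate when the network contains a closed pathway at least one
refractory wavelength long.  No membrane kinetics, conduction velocities
or source–sink effects enter anywhere; what passes or fails below says
nothing about electrophysiological dynamics, only about network
structure.

## Model

**Geometry and fibre field.** The input is a 3-d voxel occupancy mask and
a per-voxel *axial* unit vector (fibre orientation; `v` and `-v` are the
same orientation).  All lengths in the package are in voxel units; the
physical voxel pitch (e.g. 300 µm) is metadata only.  Orientation
averaging — coarse-graining included — goes through the structure tensor
(mean outer product, principal eigenvector), because the vector mean of
antiparallel axial data cancels.  Coarse-graining marks an aggregated
voxel occupied when at least half of its children are occupied (ties
occupied), a deliberately conservative rule that preserves thin walls;
degenerate structure tensors break ties to the lexicographically
smallest canonical eigenvector and log a warning.

**Tractography.** Global fibre tracts come from an evenly-spaced-
streamlines scheme: seed points with a hard-core separation
`d_sep = 0.7`, fixed-step bidirectional integration (step 0.5, nearest-
voxel orientation lookup with sign continuity), termination on mask
exit, on a per-step turn above 60°, on approaching an accepted tract
closer than `d_sep`, or at a length bound.  Candidates are traced in
rounds and accepted longest-first, each round discarding candidates that
collide with already-accepted tracts; rounds repeat until the node
budget — one node per occupied voxel, placed at unit arc-length
intervals from a random phase along each tract — is reached.  This keeps
the node density approximately uniform (about 1.00–1.01 nodes per voxel
on slab fixtures).  Nearest-voxel lookup rather than interpolation
matches the discrete resolution of the data; the per-step turn cap and
round size are configurable.

**Network.** Consecutive nodes of a tract couple longitudinally with
probability 1.  Nodes of different tracts within a cutoff distance of 2
couple transversely with the logistic probability
`p(x; r, c) = 1 / (exp(r (x - c)) + 1)` (steepness `r = 7`); `c` is the
characteristic coupling distance and is the fibrosis dial: lowering `c`
removes transverse edges.  Non-adjacent pairs on the *same* tract get no
edge — the conservative reading, since a same-fibre shortcut would
fabricate loops inside a single tract; a config flag can re-enable them.
Each candidate pair carries one fixed uniform variate (a hash of the
pair identity and the seed), so for a fixed seed the edge set at a
smaller `c` is a subset of the edge set at any larger `c`; coupling
sweeps are therefore exactly nested, never confounded by re-randomised
draws.  The fibre-less null model keeps the geometry but drops fibre
information: nodes are placed uniformly with the same `d_sep` hard core
at ~1 per voxel, every candidate pair couples through `p(x; r, c)`, and
no longitudinal edges exist — comparable edge densities need a larger
`c` than the fibre model.

**Reentry criterion and the discrete diffusion model.**  With the
refractory wavelength expressed as `tau` node steps (node spacing is one
voxel), unidirectional block across edge `(b, n)` yields reentry exactly
when the *shortest return length* `L` — one plus the shortest `b`–`n`
path avoiding that edge — satisfies `tau <= L < inf`.  The discrete
diffusion model (synchronous excitation, one-step excited state,
`tau`-step refractoriness, transient block on first arrival) reproduces
this criterion when the paced wavefront is delivered at the blocked
fibre itself, which is the package default: the dynamics are observed
from the moment the wave reaches the block, so the outcome does not
depend on where in the tissue the beat originated.  With a far-field
pacing source the two wavefronts meet as in normal rhythm and the
retrograde timing depends on the source position; that mode is available
for exploration but is not used for substrate detection.  `L` is
symmetric in the block direction, so the full scan evaluates each
undirected edge once (compiled BFS over CSR adjacency) and reports both
(node, direction) pairs.  A search horizon (`max_steps`) bounds the
detectable loop length; the desk-scale default below is 60 steps.

**Risk.**  Global risk is the per-beat induction probability under a
uniform block rule, `lambda = N / (2 E)` with `N` the number of inducing
(node, direction) pairs and `2 E` the number of block opportunities;
`lambda` is in [0, 1] and directly proportional to the substrate count.
Any fixed rescaling of this normalisation would leave all local-risk
ratios and every qualitative result unchanged.  Local risk apportions
`lambda` to voxels by their share of identified circuits,
`R_v = lambda N_v / sum(N_v)`, so the voxel sums return `lambda`
exactly.  Risk maps pool a fixed number of circuits (default 1000),
sampled uniformly with replacement among inducing pairs, across an
ensemble of independently drawn networks (fresh edge randomness; tracts
and null-model node placement held fixed by default, regenerable by
flag).  Gaussian smoothing (sigma 5 voxels, reflective boundaries, total
preserved) is cosmetic and never precedes `lambda` or cluster
statistics.

## Structural metrics

*Occupied voxel fraction* (OVF): the occupied fraction of the lattice
sphere of radius `r_tilde = 5` around a voxel, with a position-
independent denominator and out-of-grid voxels counted empty, so
boundary and convex regions genuinely read low.  A bulk-defined proxy
for wall thickness and convexity.

*Longitudinal connection fraction* (LCF): per node, longitudinal degree
over total degree; per voxel, the mean over resident nodes.  High LCF
means well-aligned fibres.  Undefined for the null model (it has no
longitudinal edges); null-model voxels are labelled with the paired
fibre-model LCF when compared.  Note the documented asymmetry: removing
transverse edges raises the LCF without adding a single longitudinal
connection.

*Cluster counts*: DBSCAN at range `eps = 10` with minimum cluster size 1
(equivalently, connected components of the eps-neighbourhood graph) on a
fixed-size sample of substrate voxels.  Sampling is without replacement
when the substrate holds at least the sample size (so a fully dispersed
substrate counts one cluster per sample) and with replacement otherwise
(keeping the sample size fixed for small substrates).  Confinement is a
per-realisation property, so ensemble statistics sample and cluster each
member separately and average; pooling members first would blur isolated
pockets into uniform coverage.

## Synthetic fixtures and what they do (not) show

No real atrial data ships with the package.  Seeded generators produce
slabs (uniform thin/thick walls), wedges (a linear thickness gradient,
hence a built-in OVF gradient), plate-plus-ridge (pectinate-muscle-like)
and plate-plus-hollow-sleeve (pulmonary-vein-like, circumferential tube
fibres) geometries, with optional spherical holes and fibre-disarray
patches drawn from a von Mises–Fisher distribution of concentration
`kappa` about the base direction (small `kappa` = strong disarray).
These reproduce the *structural motifs* the method responds to — thin
convex walls, ridges, tubes, holes, misalignment — but none of the
smoothed-image artefacts, spatially varying fibrosis, or anatomical
complexity of real fibre maps.  Passing tests demonstrate that the
machinery behaves as designed on those motifs, not that its predictions
hold in real atria.

## Desk-scale study conditions

The slow checks run on a 80×50×10 wedge (20 000 occupied voxels, one
node each) with `tau = 20`, horizon 60, 50-network ensembles, fibre
coupling grid {0, 0.2, 0.35, 0.5, 0.65, 0.8, 1.0, 1.2} and null grid
{0.7, 0.9, 1.1}.  `tau = 20` node steps keeps the refractory wavelength
a small multiple of the fixture extent, the same regime as a
centimetre-scale wavelength in a decimetre-scale organ; there is no
single canonical value and it is configurable everywhere.  For cluster
statistics at this extent the dispersed regime is only resolvable if
samples can sit farther apart than `eps`, so the per-member sample size
is set to occupied-volume/eps³ ≈ 20 (the production default of 1000
presumes a geometry orders of magnitude larger than `eps`).  Observed
behaviour under these conditions: `lambda(c)` vanishes at both grid ends
with a maximum near `c = 0.5`; along the high-coupling branch the
substrate starts in the thin (low-OVF) end, well below the geometry-mean
OVF, and the bias erodes as `lambda` grows; per-network cluster counts
grow with `lambda` in both models; a `kappa = 3` disarray patch
concentrates the fibre-model substrate at high coupling (density ratio
well above 2) while the null model on the same geometry shows no patch
preference.

## Numerical and degenerate-input choices

- Candidate pairs use a strict `x < cutoff` inequality (k-d tree result
  filtered), identical to brute-force enumeration.
- `connection_probability` is evaluated through the logistic sigmoid for
  overflow-free behaviour at large `|r (x - c)|`; the midpoint value at
  `x = c` is exactly 0.5.
- Zero-length orientation vectors at occupied voxels are a hard error
  with voxel indices; missing orientations are NaN and are never
  fabricated during coarse-graining.
- Streamlines shorter than two points are discarded; a tract's node
  phase is uniform per tract; nodes falling outside the mask after
  interpolation (corner-cutting) are dropped.
- RSA node placement stops after a bounded run of consecutive
  rejections; the hard core `d_sep = 0.7` leaves the target density of 1
  node per voxel well below the jamming density (~2.1 per voxel).
- `lambda > 0` with an all-zero count map raises rather than silently
  producing an empty risk map.
- Smoothing with `sigma = 0` is the identity; negative `sigma` is an
  error.

## Known limitations

- Uniform coupling: `c` is constant across the geometry; region-
  dependent coupling (patient-specific fibrosis maps) is out of scope.
- Uniform block susceptibility; no functional block or repolarisation
  heterogeneity.
- The detection horizon hides loops longer than `max_steps`; raise it
  (at quadratic-ish cost in dense regions) when long circuits matter.
- Tract realism is unvalidated by construction — only robustness to the
  seed-point draw is tested (the ensemble-mean risk shifts by less than
  the ensemble spread across independent tract regenerations).
- The sleeve/ridge fixtures are geometric caricatures; their value is in
  exercising curvature and tube topology, not anatomy.
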