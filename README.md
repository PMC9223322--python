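# fibronet

Structural mapping of micro-anatomical reentry risk on fibre spatial
networks.

Micro-anatomical reentry — electrical activation circulating
continuously around a fibrotically insulated fibre tract — is a
candidate driver of atrial fibrillation.  Whether a tissue region can
*structurally* host such a circuit depends on its geometry, its fibre
architecture, and how much electrically insulating interstitial fibrosis
has accumulated between fibres.  `fibronet` implements a spatial-network
method for locating those regions in a voxel geometry with a fibre
orientation field, aimed at computational electrophysiologists and
network scientists studying arrhythmia substrates.

## Method in brief

1. **Tractography** — global fibre tracts are reconstructed from the
   local orientation field with an evenly-spaced-streamlines scheme
   (seed separation d_sep = 0.7 voxels), and nodes are placed along
   tracts at unit spacing, ~1 node per voxel.
2. **Spatial network** — nodes on the same tract couple longitudinally
   with probability 1; nodes on different tracts within x < 2 voxels
   couple transversely with probability

       p(x; r, c) = 1 / (e^{r (x − c)} + 1),   r = 7,

   where the characteristic distance c is the fibrosis dial: lowering c
   strips transverse edges, mimicking interstitial fibrosis.  A
   fibre-less null model (same geometry, no fibre information, no
   longitudinal edges) isolates the role of fibre structure.
3. **Reentry detection** — with the refractory wavelength τ in node
   steps, unidirectional conduction block across an edge induces reentry
   iff the shortest return loop through that edge has length ℓ ≥ τ.  A
   discrete diffusion model (synchronous excitation, τ-step
   refractoriness, transient block) realises this criterion dynamically;
   a compiled graph scan applies it to every edge.
4. **Risk and structure** — global risk λ = N / (block opportunities),
   local risk R̃_v = λ·N_v / Σ N_v (summing back to λ), plus structural
   metrics: occupied voxel fraction (OVF, a bulk wall-thickness proxy),
   longitudinal connection fraction (LCF, a fibre-alignment proxy), and
   DBSCAN cluster counts of the substrate (eps = 10, min size 1).

No real atrial data is required: a fixtures module generates slab,
wedge, ridge and sleeve geometries with controlled fibre fields,
disarray patches and holes.

## Worked example

```python
import numpy as np
import fibronet as fn

# a wedge: thickness grows 1 -> 9 voxels along y, fibres along x
geom, field = fn.make_fixture(
    fn.FixtureSpec("wedge", (80, 50, 10), thickness=9, thickness_min=1, seed=0)
)
tracts = fn.generate_tract_set(geom, field, fn.TractographyParams(seed=1))
print(f"{tracts.n_nodes / geom.n_occupied:.3f} nodes per voxel")

rm = fn.ensemble_risk(
    geom, field, "fibre",
    fn.CouplingConfig(c=1.0, seed=0),
    fn.DDMConfig(tau=20, max_steps=60),
    n_networks=20, n_circuits_sampled=1000,
    rng=np.random.default_rng(42), tracts=tracts,
)
ovf = fn.occupied_voxel_fraction(geom, 5.0)
detected = rm.per_voxel_counts > 0
print(f"lambda = {rm.lambda_:.5f}")
print(f"substrate mean OVF = {np.nanmean(ovf[detected]):.3f}"
      f" vs geometry mean {np.nanmean(ovf):.3f}")
```

prints

```
1.002 nodes per voxel
lambda = 0.00264
substrate mean OVF = 0.506 vs geometry mean 0.612
```

At this high coupling (low fibrosis) reentry is rare (λ ≈ 0.003 per
paced beat) and the substrate sits in tissue whose neighbourhood is only
~51% occupied — the thin end of the wedge — well below the geometry-wide
mean of 61%: thin, convex walls are the first regions able to host
micro-reentry.  Lowering `c` raises λ and erodes that thin-wall bias
while the substrate disperses spatially; sweeping `c` (see
`fibronet.calibration_sweep`) shows λ vanishing at both extremes with a
maximum at intermediate coupling — too few transverse edges leave no
loops, too many make every loop shorter than τ.

A command-line interface mirrors the library
(`fibronet synth|trace|build|detect|risk|metrics|sweep|run`); see
`fibronet --help`.  `docs/methods.md` documents the model, parameters
and limitations.

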