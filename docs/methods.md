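# Methods and numerical notes

This document records the models behind each analysis stage, the default
parameters and why they were chosen, and the known limitations of the
synthetic generators.

## Coordinate model

A nanotube frame is a set of CG beads, each belonging to a lipid
(`species`, `lipid_id`, `bead` role, `xyz` in Å), plus protein anchor
points on a helical lattice. All surface analyses work in cylindrical
coordinates about a vertical axis: the axis position is fitted per frame by
a least-squares circle through the anchors (Gauss–Newton on the residuals
`|a_i − c| − r̄(c)`, started from the anchor centroid). With 34 anchors and
1 Å anchor jitter the fitted center is accurate to ~0.3 Å, and it agrees
with an iteratively refined brute-force grid search of the same objective
to better than 10⁻³ Å (checked in the acceptance suite).

Degenerate inputs (fewer than 3 anchors, collinear anchors) raise
`DegenerateGeometryError` rather than returning an arbitrary center.

## Leaflet assignment

Phosphate beads of phospholipids are clustered by single linkage cut at two
clusters; the cluster with larger mean radius is the outer leaflet.
Cholesterol, which has no phosphate, inherits the leaflet of its nearest
phosphate bead. A cluster-size ratio above 50:1 triggers a warning, since
it usually means the geometry is not a bilayer (or the surface is too
sparse for single linkage, see *Generator scope* below).

## Zones

The protein contact site is a helical wedge of half-width 15° (30° total)
that follows the anchor helix (the centerline rotates by
`(360/subunits_per_turn)/rise` degrees per Å of z, 7.06°/Å at the
defaults); the *gap* wedge sits 180° across; everything else is *other*.
Points outside the anchors' z span fall in *other*.

## Radial density profiles

Per-selection Gaussian KDE of bead radii (default bandwidth 0.5 Å,
grid 0–80 Å with 0.2 Å spacing), normalized by 2πrΔr per frame so that
`∫ρ(r)·2πr dr` returns the mean selected bead count. Conservation to
better than 1% is asserted in the test suites; in practice it is exact to
rounding because the kernel mass lies inside the grid.

## Headgroup surface maps

Headgroup bead positions are mapped to (θ in degrees, z in Å) and
density-estimated on a grid with 1° × 0.835 Å spacing. θ is periodic
(points are replicated ±360°); z edges are mirror-padded with 15% of the
range so the KDE does not sag at the tube ends — with padding the edge rows
of a uniform lattice of points deviate from the interior by <0.1%, without
it by >10%. The default bandwidth is tied to the output grid
(2× the θ spacing, 1.5× the z spacing): the structure of interest is a
helical stripe whose z-thickness at fixed θ is only ~2.7 Å (wedge width
divided by the 7.06°/Å helix slope), so a sample-size–driven bandwidth
(e.g. Silverman's rule, ~5× wider here) would smear the stripe and halve
its contrast. Maps are min–max normalized to [0, 1] by default
(`normalize=False` returns raw densities).

## Tail tilt

Each tail's orientation vector runs from the phosphate bead to the last
tail bead; the tilt angle is measured against the signed radial normal
(+r̂ inner, −r̂ outer), so 0° means membrane-normal in both leaflets and the
convention is exactly mirror-symmetric (asserted bitwise in the tests).
Distributions are Gaussian KDEs with an absolute 0.05° bandwidth on a
0–180° grid with 0.9° steps, renormalized to integrate to 1 on the grid
(the raw KDE integral deviates because the bandwidth is far below the grid
spacing). Note the practical consequence: with a 0.05° bandwidth the
density is a micro-binned histogram, and its argmax resolves the
distribution mode reliably only when the underlying spread is comparable
to the grid step; for broad distributions the per-group `mean_angle` is
the stable location estimate.

## Zone compositions

Compositions gather *all non-headgroup beads* at the bead level — each
bead's own position decides its zone — then divide by the species'
non-headgroup bead count to get lipid equivalents and normalize to
100 mol% per (leaflet, zone). Lipids straddling a wedge boundary therefore
split between zones; this is a convention, not an error, and differs from
per-lipid counting by several mol% in the narrow wedges.

## Leaflet thickness (simulation)

Glycerol planes are the peak radii of the per-leaflet glycerol-bead
profiles; the bilayer midplane is where the *unit-normalized* per-leaflet
terminal-tail densities cross. Normalization matters: the outer leaflet
holds ~1.8× more lipids, so raw densities never cross even for a perfectly
symmetric bilayer.

## Lateral diffusion

Each lipid's reference bead is tracked as the surface displacement
(R̄·Δθ with θ unwrapped over time, Δz unwrapped with the box z period).
MSD(τ) is averaged over lipids and all time origins and fitted by a
straight line over lags of 2–20% of the trajectory, weighted by 1/τ
(overlapping-origin MSD variance grows roughly linearly with lag);
D = slope/4. At 500 lipids and 2,000 frames the recovery error is below
7% across seeds; a trajectory whose lipids are frozen yields exactly 0.

## EM map analysis

Maps are normalized by mean density in a protein radial shell after
subtracting the solvent baseline (outermost 10% of radii), which removes
any gain/offset; inverted contrast is rejected. Helical slices are rotated
into register using the map's twist/rise metadata. The membrane radial
profile is fitted by three Gaussians (inner peak, aliphatic trough, outer
peak) over a window of 28–60 Å: centers are bounded by the observed
peak–trough–peak structure and widths capped at 8 Å (membrane scale), which
keeps the trough center from drifting when the protein shell's tail leaks
into the window. Leaflet thicknesses are the trough-to-peak distances;
asymmetry = outer − inner.

Bromine-difference composition subtracts the unbrominated reference
profile from each brominated variant, integrates the positive excess per
leaflet (split at the trough), divides by Br atoms per molecule, and closes
each leaflet to 100 mol%. Negative excess areas are clamped to zero and
logged. Half-map pairs give a √2-scaled standard deviation per quantity.

## Synthetic generators: scope and limitations

- **Tubule snapshots.** Two concentric cylindrical leaflets with exact
  per-leaflet species counts (largest-remainder rounding). Within a
  leaflet, lipids occupy a near-square (θ, z) lattice filled in random
  order and jittered by `noise_sigma`; fully random (Poisson) placement is
  deliberately *not* used because its density voids can exceed the
  inter-leaflet gap, which no packed membrane exhibits, and which breaks
  single-linkage clustering on otherwise valid geometry. Tails realize the
  sampled von Mises tilt exactly as the phosphate→terminal chord. The
  optional furrow displaces outer-leaflet headgroups out of a helical
  wedge, spreading them over a 1–16° band beyond the wedge edge (piling
  them at the rim would leak density back into the stripe), and backflips
  a fraction of sn-2 terminals beyond the anchor radius.
- **Trajectories.** Rigid-lipid Brownian motion on each leaflet cylinder;
  θ and z are both periodic (z wraps per lipid so molecules stay whole, and
  the box z length carries the period). Reflecting walls were rejected
  because reflected Brownian motion saturates the z-MSD at long lags and
  biases D low by ~10%. Lipids with D = 0 keep bitwise frame-0 coordinates.
- **Map families.** Radial Gaussian shells (two leaflet peaks at
  36.8/56.8 Å, a −0.35-amplitude trough at 45 Å, a protein shell at 68 Å
  with σ = 2.5 Å — kept narrow so it does not bleed into the membrane
  window), optional helical contact hot-spots, per-species bromine
  enhancement proportional to leaflet fraction × Br count, and white voxel
  noise. The grid half-extent must exceed the outermost shell radius plus
  3σ plus a 5 Å solvent margin, or the solvent baseline used for
  normalization would be contaminated (validated at construction).
- Not modeled: protein sterics/elasticity, lipid flip-flop, curvature
  softening of the tilt field, CTF or alignment errors in maps, non-white
  map noise.

## File formats

GRO-dialect coordinates are read/written via MDAnalysis (fixed-format,
0.001 nm precision → round trips are exact to 0.005 Å); MRC/CCP4 maps via
gemmi (voxel size and helical metadata preserved); an internal tabular
CSV round-trips snapshots exactly. Unknown species at parse time raise
`ParseError` (or are ignored with `on_unknown="ignore"`).

## Determinism

Every generator takes a seed or `numpy.random.Generator`; stage outputs
are pure functions of (inputs, config, seed). Result CSV/JSON files embed
a config hash so replicates can be matched to their configuration.
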