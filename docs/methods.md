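# Methods

This note documents the models and conventions behind channelhydra's
analyses, the design choices made where the field has no single convention,
what the synthetic generator does and does not emulate, and the numerical
details a careful user should know.

## Distance criteria and periodic boundaries

All distance criteria are heavy-atom, minimum-image distances in an
orthorhombic box; triclinic cells are rejected. Cutoffs are **closed
intervals** — a pair at exactly the cutoff counts — and the defaults are:

| criterion | default | meaning |
|---|---|---|
| H-bond / contact | 3.0 Å | heavy-atom donor–acceptor distance at which direct proton transfer is plausible |
| hydration shell | 5.0 Å | water-counting shell around residue sets |
| cavity linkage | 3.5 Å | O–O first-hydration-shell distance joining waters into one cavity |
| lipid contact | 3.0 Å | headgroup-phosphate to residue atom distance |

The H-bond criterion is distance-only (no donor–H–acceptor angle): the
analyses operate on heavy atoms, and the synthetic fixtures carry no
hydrogens. Neighbor queries use a periodic k-d tree
(`scipy.spatial.cKDTree(boxsize=...)`) with exact distance re-checks; the
result is contractually identical to a brute-force all-pairs scan and is
tested against one. Trajectory coordinates are stored in single precision
(the DCD norm), so distances derived from stored frames are reproducible to
about 1e-5 Å; all pure-geometry functions are float64.

## Superposition, RMSF, helix axis, χ

Rigid superposition uses the Kabsch algorithm (SVD with determinant
correction, so reflections are excluded); the RMSD agrees with an
independent quaternion-method implementation to 1e-8 and is symmetric in its
arguments. RMSF is the per-atom root-mean-square displacement about the
time-mean position, optionally after superposing each frame onto frame 0 by
a reference selection. RMSD/RMSF are unweighted (no masses).

The helix axis is the leading principal component of the centered Cα cloud
of a residue range, sign-fixed toward the C-terminal end; χ is the arccos
angle (degrees, [0°, 180°]) between that axis and the side-chain vector
Cα → terminal polar heavy atom (Asn: ND2, Gln: NE2; the map is
configurable). Neither construction is standardized in the literature; both
are package decisions, and the axis is re-fit every frame so helix drift
does not masquerade as side-chain motion.

## Stable spatial positions

A stable spatial position (SP) is an angular state of χ(t) whose fluctuation
amplitude is comparable to thermal fluctuations. Operationally:

1. Candidate states are local maxima of the χ histogram (2° bins, Gaussian
   smoothing σ = 1.5 bins).
2. For each candidate, the member set is every frame within
   ±(2 × `sp_amplitude_ratio` × baseline) of the mode — the widest window a
   qualifying state could claim. The candidate's center is the member mean,
   its amplitude the member RMS deviation. This window convention is what
   lets a structureless (uniform) series reject itself: its "amplitude" is
   the window RMS, window/√3, which always exceeds the qualification bound.
3. Candidates closer than `merge_separation_deg` (default 15°) merge into
   the more occupied one.
4. A candidate qualifies as an SP iff amplitude ≤ `sp_amplitude_ratio`
   (default 1.5) × baseline **and** occupancy ≥ `min_occupancy`
   (default 0.05).
5. Frames within 2×amplitude of an SP center are assigned to it (nearest
   center wins); the rest are transient. Occupancies are recomputed from
   this final assignment, so SP occupancies plus the transient fraction sum
   to one. Transitions are counted between consecutive assigned frames.

The thermal baseline is supplied by the caller (default 5°); when backbone
RMSF is available it can be converted through the side-chain lever arm, but
the package does not guess it. Angles are treated as plain values on
[0, 180], not circular, because χ is defined through an arccos. SPs are
labelled SP1, SP2, … by descending occupancy; labels are per-run, not
anchored to fixed angle ranges. Because assignment truncates at 2×amplitude
(≈ 2σ for a Gaussian state), measured occupancies run ~5% below the
generative state probabilities; recovery tests therefore compare against the
realized planted schedule, with a ±0.05 band.

## Density grids and structural-water sites

Waters are tracked by their oxygen. The residence grid covers the frame-0
box at `grid_spacing` (default 1 Å), origin snapped to a 0.5 Å lattice;
points are wrapped into the box and binned by floor division. Raw-count
grids conserve the point tally exactly; probability mode divides by the
number of contributing frames, so the grid total equals the mean number of
tracked points per frame. Grids can be restricted to points within a radius
of a selection (the maps near key residues) and are written in OpenDX.

A structural-water site is a 26-connected component of voxels with
probability ≥ `site_prob_threshold` (default 0.4 — the literature says only
"high probability", so this is exposed in config). Per site the package
reports the probability-weighted centroid, peak probability, the **mean
simultaneous water count** (average number of distinct waters inside the
site per frame — distinguishing a single structural water from a 2–3-water
exchanging cluster), and the **mean residence time**: the mean over all
contiguous per-water occupancy intervals, times the frame spacing. Note the
pooling convention: short visits by exchanging waters weigh individually,
not per-water-averaged.

Cavity analysis builds, per frame, the graph of region waters (within
`cavity_region_radius` of the region selection) with edges at the 3.5 Å
linkage distance and reports connected-component counts and sizes; a
merged entrance lacuna is one component where a dry entrance shows several.

## Water wires

The per-frame hydrogen-bond graph has water oxygens plus the side-chain N/O
atoms of the configured relay residues (and the target atoms) as nodes, and
edges at the H-bond cutoff, so a wire may pass through residues as well as
waters. Sources are the waters within `source_radius` (default 6 Å) of the
entrance selection. Path optimality is **fewest edges**, not geometric
length — the relevant quantity for hop-by-hop proton relay — found by
breadth-first search with deterministic tie-breaks (neighbors expanded in
ascending index order; among equally near targets the smallest atom index
wins). Continuity is the fraction of frames with a wire. For a broken
frame, the breakpoint is attributed to the relay residue nearest the
midpoint of the largest gap: the closest approach between the
source-connected and target-connected components. The attribution rule is a
package decision; nothing in the underlying physics singles out one
convention.

## Lipid binding sites and residence

Contacts are evaluated per (protein residue, lipid molecule) pair — one
lipid touching two residues yields two event streams. The "phosphatidic
acid moiety" is operationalized as an atom-name selection (phosphorus plus
phosphate/ester oxygens; force-field naming differs, so this lives in
config). Residence events are maximal contact intervals with interruptions
of at most `gap_tolerance_frames` (default 2) merged; mean retention is
monotone non-decreasing in that tolerance, and occupancy always equals the
un-merged total contact time divided by the frame count. Binding sites are
single-linkage clusters (connected components at ≤ `adjacency` = 8 Å
between first-frame Cα positions) of residues with occupancy ≥ 0.1; site
occupancy is the fraction of frames in which any member residue touches any
lipid, and site retention pools the members' events.

## The synthetic generator

`SyntheticSpec.paper_like()` builds a desk-scale solvated-channel caricature
in a 40 × 40 × 60 Å box: an ideal α-helix carrying an Asn-214 analogue, the
relay residues of the inlet half-channel (Glu219, Asp119, His245, Asn214,
Gln252 analogues, plus off-path Asn116/Ser144 and entrance Arg24/His132, and
a chain-C Asp61 target), a 13-water wire along the channel axis, a W1-like
cluster of three sub-sites maintained by 2–3 exchanging waters from a
5-water pool, a 30-water hydration-shell pool with Bernoulli per-frame
presence, two entrance lacunae with a switchable bridge, bulk waters, and
ten surface Lys sites visited by cardiolipin-headgroup beads.

Planted dynamics and their defaults (the validated study conditions):

| plant | default | mechanism |
|---|---|---|
| wire continuity | 0.75 | Bernoulli per-frame break; the wire water nearest the Asn214 analogue is parked, opening a 5.3 Å gap |
| contact fraction (Asp119–His245) | 0.90 | exactly ⌊0.9 n⌋ frames at 2.6 Å, the rest at 5.5 Å |
| Asn214 χ states | 60°/120° at 0.6/0.4 | geometric dwells (mean 200 frames), Gaussian noise σ = 3° |
| W1 cluster | 2–3 waters (mean 2.5) | two slots always occupied, a third at probability 0.5; holders exchange on geometric dwells (mean 50 frames) |
| shell hydration | mean 15 waters (8 low / 18 high) | per-frame Bernoulli presence of pool waters at fixed in-shell positions |
| lipid sites | 10, occupancies 0.25–0.9 | alternating exponential on/off dwells, on-mean 150 ps |
| frame spacing | 2 ps | matches a typical recording interval |
| thermal jitter | σ = 0.05 Å, truncated at 3σ | added to every atom every frame |

Truncating the jitter keeps every planted distance on the intended side of
its criterion, so recoveries are exact rather than statistical where the
plant is exact. At generation time a worst-case static connectivity check
verifies that shell and bulk waters cannot accidentally bridge the broken
wire (offending waters are resampled), so measured wire existence equals the
planted schedule frame by frame. Every realized quantity — per-frame wire
existence, contact flags, χ states, W1 occupancy, lipid intervals — is
written to a ground-truth manifest, and recovery tests compare against
realized (not just nominal) values.

What the generator does **not** emulate: real force-field dynamics,
diffusion (off-duty waters teleport to a parking lattice), hydrogens,
water-water correlations, protein flexibility beyond the planted motions,
and realistic lipid geometry (headgroups are single beads). Passing
recovery tests therefore demonstrates that the analysis code measures what
it claims to measure under controlled conditions — not that any particular
biological conclusion holds.

The low/high hydration pair (`hydration="low"|"high"`) differs only in
shell count (8 vs 18), wire continuity (0.60 vs 0.90), and entrance-lacuna
bridging (off vs on), mimicking the direction of the plain-PC vs
cardiolipin-membrane contrast. In the low condition the entrance region
resolves into three components (two lacunae plus the channel-mouth water
column); bridging merges all of them into one.

## Pipeline and comparison

`run_analysis` executes all stages from one config and writes a bundle with
SHA-256 checksums; reruns on identical inputs are byte-identical.
`compare_conditions` refuses bundles whose selections or cutoffs differ and
reports per-metric deltas with 95% moving-block bootstrap confidence
intervals (block = 50 frames, 200 replicates, seeded) to respect temporal
autocorrelation; SP occupancies are compared as plain deltas. Frame stride
is a config option (default 1, all frames).

## Problem sizes

The validation suite generates its own data: recovery tests use five seeds
of 5,000 frames (~170 atoms) per condition, the condition contrast 2,000
frames per condition, and unit fixtures tens to hundreds of frames. The
acceptance script uses 5,000 frames for the main run and 2,000 per contrast
condition. These sizes put Monte-Carlo error well inside the stated
tolerances (e.g. a Bernoulli 0.75 continuity at 5,000 frames has a standard
error of 0.006 against a ±0.03 band).

## Known limitations

- Orthorhombic boxes only; no triclinic minimum image.
- H-bond criterion is distance-only by default; no angle term.
- Selection grammar covers name/resname/resid/chain/element/water with
  booleans — not the full MDAnalysis language (though well-formed
  MDAnalysis expressions in that subset pass through unchanged).
- Site residence times are biased short when a water leaves a site's voxel
  set for a single frame (no gap tolerance at the voxel level).
- The SP classifier treats χ as non-circular, which is correct for the
  arccos definition but unsuitable for dihedral-type angles.
- `compare_conditions` bootstraps frames within each bundle; it does not
  model between-replica variance from multiple independent runs. Running
  replicas as separate bundles and comparing per-run, then pooled, is the
  recommended pattern.
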