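# Methods

## Data model

Coordinates are nanometres everywhere inside the library. Skeletons are
rooted trees (`SkeletonGraph`): node ids, parent pointers (−1 at the
root), positions and radii; the root is the soma side. The SWC reader
accepts a units declaration (`nm`/`um`) or an explicit voxel size so
8 nm-voxel connectome exports convert on ingest. Synapse tables carry
one row per contact — `pre_neuron`, `post_neuron`, a `kind` marking
whether the recorded position is the presynaptic T-bar or the
postsynaptic density, a compartment label, and an integer `weight`
(≥ 1; aggregated rows count fully in every statistic). A neuron's
"T-bars + PSDs" in a region therefore counts rows where it is
presynaptic plus rows where it is postsynaptic there. Autapses are
flagged, not dropped.

Compartments are ordered lists of analytic primitives (sphere, box,
finite slab, torus sector). Membership is boundary-inclusive and
resolved by list order, so every point maps deterministically to exactly
one region or `unassigned`, and overlap ties are decided by the declared
priority (e.g. adjacent FB layer slabs give their shared boundary to the
lower layer index; the broad FB slabs are listed after the lateral
territories they brush). Hemisphere is the sign of the coordinate normal
to a declared midline plane; points on the plane are `UNKNOWN`.

## Backbone extraction

Four rule-based steps reduce a skeleton to its lineage-tract backbone.

1. *Twig pruning.* Terminal chains of fewer than `twig_node_max` = 15
   nodes (~120 nm at 8 nm spacing) carrying no connector are removed,
   iterating to a fixpoint so nested twigs cannot survive a single pass.
   Connectors are attached to skeletons by nearest node within 250 nm;
   unmapped connectors are ignored. Twigging is **root-protected**: a
   chain that reaches the root before any branch point is not a twig.
   The root is the soma, and a backbone that loses its soma-side tip
   would break portal-crossing orientation; an unbranched skeleton is
   returned unchanged.
2. *Fragmentation.* The cleaned tree is cut at every node of degree ≥ 3
   into maximal unbranched paths; branch points are duplicated into each
   incident fragment (so fragments partition the edge set, and a
   connector mapped to a branch point counts in each incident fragment).
3. *Selection.* Fragments longer than 2500 nm are kept outright.
   Shorter fragments survive only if they exceed 80 nm and their
   connector count is below 0.01 × cable length in nm ("1% of the
   numerical value of the cable length", with cable length read in nm —
   all sibling thresholds are nm). Among these secondary survivors,
   fragments shorter than largest ÷ 2.5 are dropped. The alternative
   literal reading — discard secondary fragments shorter than
   2.5 × largest, which keeps essentially nothing but the large
   fragments — is available behind `literal_relative_rule=True`; the
   default reading is the only one that leaves the rule with any effect,
   and the brute-force oracle applies the same reading.
4. *Distal trimming.* Any remaining fragment whose minimum node-to-point
   distance to **both** endpoints of the largest fragment exceeds
   5000 nm is discarded. The fragment-to-endpoint distance is a minimum
   over the fragment's nodes, not its centroid, so long thin fragments
   are judged by their nearest approach. The trim applies to all
   non-largest fragments, large and small alike.

All parameters live in `BackboneParams` with these defaults. The
implementation is checked node-set-for-node-set against an independent
brute-force implementation of the rule list (networkx, naive loops) on
1000 random ≤ 50-node skeletons.

## Lineage assignment

A `BundleAnnotation` gives each lineage an entry portal (point + unit
normal of the plane where the bundle enters the neuropil), seed fiber
positions on that plane, a capture radius, and optionally a soma-cluster
center and a dorsal axis. For each neuron the backbone polyline is
walked root-outward; its first intersection with a bundle's portal plane
(linear interpolation between straddling nodes) is compared against the
seed fibers. The bundle with the smallest crossing-to-seed distance d
wins if d ≤ capture radius (method `PORTAL`), scored exp(−d/r). If the
backbone crosses no portal, the fallback distance is the backbone's
closest approach to the seed fibers (method `TRAJECTORY`). A mean
backbone-to-seed distance was considered for the fallback but cannot
pass the same capture gate — a backbone necessarily extends far from any
portal — so closest approach is used with the identical gate, keeping
`UNASSIGNED` reachable and the scoring uniform. Ties break by
soma-to-cluster distance, then lexicographic lineage id. Unassignable
neurons are retained with method `UNASSIGNED`.

Hemilineages: within each annotated bundle, portal crossings are
projected onto the bundle's declared dorsal axis (or their widest
principal direction) and split at the largest gap into at most two
groups; the group with the higher dorsal projection is labelled `d`.
Bundles without a declared axis are left unsplit. The same split applied
at a second annotated plane yields dorsal/ventral subpopulation labels
on the FB approach.

The CX large-field filter keeps a neuron iff (1) it has at least one
connector in a CX region, (2) its CX T-bars + PSDs total **strictly
more than** 15, and (3) it makes at least one output connection to a
single partner **strictly stronger than** 5 synapses (connection
strength = summed weight per ordered neuron pair, over the whole table).
CX regions are matched by compartment-name prefix (PB/EB/FB/NO/AB) by
default and are configurable.

## Connectivity and spatial summaries

Connection matrices sum connector weights by source × target group,
optionally region-restricted; totals are conserved exactly.
Max-normalization divides by the global maximum (all-zero matrices warn
and stay zero). "Lateral input" fractions count postsynaptic weight
onto target groups outside the CX regions (PSD-side counting; a flag
switches to the presynaptic side — the input-sector convention is not
uniquely determined by the summaries it feeds, so both are exposed).
Upstream shading weights each output synapse by its neuron's total
upstream input divided by the maximum per-target total, which keeps the
weights in [0, 1]; normalizing by the largest single pairwise connection
instead could exceed 1 whenever a target pools several connections.

The EB circular projection collapses the ring azimuth: for a fitted or
configured torus axis model (center, unit axis, ring radius R), a point
maps to v = signed axial offset and u = distance-to-axis − R. Point
count and weight are conserved; u + R reproduces the 3-D distance to
the axis to 1e-9 relative error. Axis fitting uses the direction of
least variance of the point cloud (a filled ring is flattest along its
symmetry axis), centroid center, and mean axis distance as R; the axis
sign is fixed toward a configured anterior direction. Synthetic runs may
use the generator's true axis to isolate projection behaviour from
fitting error.

The FB topography statistic: per neuron, the dendritic centroid is the
weighted mean of its PSD-side connector positions outside the CX,
projected on a configured anatomical axis (the library never hardcodes
a neuraxis); the output layer is the FB layer holding the plurality of
its presynaptic connectors, ties to the lower layer index. Spearman's
rho is reported per lineage (NA below 3 neurons) and pooled. With
several neurons sharing a layer, tied layer ranks cap attainable rho
below 1 once centroids carry any noise; the noiseless planted gradient
reaches exactly 1 because the tie structure then matches on both sides.

## Synthetic connectome generator

The generator emulates the structure of a hemibrain-style dataset, not
its biology: nm-scale skeletons sampled every 8 nm (so the 15-node twig
threshold is ~120 nm of cable), lineages of 50–150 fibers per tract
(drawn per tract unless fixed), soma clusters in a cortical rind, tracts
as a shared centerline plus a per-fiber lateral offset (σ = 100 nm) and
2 nm node jitter, entry portals with true seed fibers written to the
bundle annotation, terminal arbors as persistent random walks confined
to their compartment primitive, and 3–12-node connector-free twigs
attached on the cortical (pre-portal) tract segment. Compartments are a
torus EB with five annular domains (anterior / outer- and
inner-central / inner- and outer-posterior split by u/v bands of the
tube cross-section), nine 1000 nm FB layer slabs, PB box, NO1–3, AB,
bulb partitions (BUs/BUa/BUi), LAL and SMP spheres, mirrored across the
x = 0 midline when a two-hemisphere brain is requested.

Synapse budgets are realized **exactly** (deterministic allocation), so
recovery tolerances in the tests come only from spatial randomness; a
Poisson mode exists behind a flag. Positions are rejection-sampled
inside the declared region against the priority-resolved membership
predicate, which makes the "every synapse lies inside its declared
region" audit hold by construction. Optionally each source neuron is
restricted to a small partner set (`partners_per_source`), producing the
strong single-partner connections real connectomes show — without this,
uniform pairing dilutes every connection below the catalog filter's
strength rule. Everything is reproducible byte-for-byte from
(config, seed) through a single random stream.

Two fixed-shape scenarios:

* **AVP** — two tuberculo-bulbar hemilineages target disjoint bulb
  partitions (DALcl1d → BUa/BUs, DALcl2d → BUi) and each ring-neuron
  subclass receives bulb input from exactly one of them; ring-neuron
  output fills planted EB annular domains. Planted exclusivity is 100%.
* **FB** — five large-field lineages receive 20 000 lateral input
  synapses in the SMP with exact shares 28.6% / 23.2% / 22.3% for the
  three dominant lineages (14.0% / 11.9% for the remainder); each
  neuron's dendritic locus sits along the posterior axis in proportion
  to its output layer (250 nm per layer, locus jitter confined to the
  plane orthogonal to the gradient axis), so the planted topography
  correlation is +1, degraded only by the 200 nm default synapse
  scatter. Scenario population sizes (48/44/40/24/20 target neurons)
  are a deliberate scale-down of catalog-sized populations; the planted
  fractions and gradient are size-independent.

What the generator does **not** emulate: realistic morphology
(arbors are geometric walks, not biological trees), EM imaging noise,
reconstruction merge/split errors, soma-size variation, or partner
selection beyond the block structure. Passing tests therefore certify
the pipeline's rule implementations, conservation laws and geometric
contracts under the stated conditions — not robustness to reconstruction
pathologies in real EM data.

## Numerical choices and degenerate inputs

Closed (boundary-inclusive) region membership plus declared priority
makes all point classification deterministic. Assignment distance ties
are rounded at 1e-9 nm before tie-breaking. Empty inputs warn and
return empty-but-well-formed results (empty backbone, all-zero
normalized matrix, all-NA fractions, empty ECDF). The pipeline removes
partial outputs when a stage fails and names the stage. Problem sizes
in the test suite (e.g. 200 recovery neurons, 1000 oracle trials, 20
assignment seeds, 20 000 FB synapses) are the package's chosen
verification sizes; all scale linearly if enlarged.

## Known limitations

* Bundle annotations must be supplied (digitized or generated); there is
  no de-novo bundle discovery from images.
* Neurons whose tracts originate outside the volume are only assignable
  via the trajectory fallback or an explicit annotation override; no
  projection-envelope matching metric is implemented.
* The flat compartment model does not represent nested ROI hierarchies;
  a hierarchy must be flattened to one priority list on ingest.
* The circular projection fixes a (u, v) convention; display handedness
  of published cross-section figures may differ.
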