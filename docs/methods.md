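# Methods

## Data model

Neurons are skeletons: rooted trees of 3-D nodes with radii, in nanometres
(the FAFB convention; SWC files are assumed to carry micrometres and are
scaled by `unit_scale=1000` on read, overridable).  Synapses are stored
connector-centric: one presynaptic link and one or more postsynaptic links
per connector, exactly mirroring the annotation rule that one continuous
synaptic cleft is a single presynapse and each opposing membrane a
postsynapse.  A "connection" throughout the package is one postsynaptic
link, so a polyadic connector contributes once per link; per-edge synapse
counts are always derived from connectors, never stored.  Skeleton and
connector identifiers are opaque strings.

Volumes are axis-aligned boxes or closed triangle meshes.  Box membership is
a closed-interval test (boundary inside).  Mesh membership uses the
generalized winding number (sum of signed solid angles per triangle,
van Oosterom & Strackee), with w ≥ 0.5 − 1e−9 counted inside so surface
points are included; meshes must be closed and consistently oriented (every
directed edge appears exactly once in each direction).  Cable length inside a
volume sums parent–child edge lengths whose **both** endpoints are inside —
node-resolution bookkeeping, no edge clipping — so edges straddling a
boundary belong to neither side and spatial partitions can undercount total
cable by at most those straddling edges.

## Saturation sampling

All (connector, postsynaptic-link) pairs downstream of the query set, with
the connector location inside the scope volume, form the pool (deterministic
order: connector id, then post skeleton id).  Draws are uniform without
replacement over pool entries — matching a workflow that annotates *all*
postsynapses and then samples them — not uniform over partners.  A draw of a
previously unseen partner is a novel hit and appends (partner, true
connection total) to the novel history.  After each novel hit, once at least
`window` (default 10) novel hits exist, sampling stops if the last `window`
of them all have totals below `weak_threshold` (default 5).  If the pool
empties first the run is flagged `exhausted`.

The totals driving the rule are ground truth within the sampled scope (in
the original workflow each hit was reconstructed and its connections
counted): the simulator supplies them, and a live mode recomputes them from
any connectome.  Scope is volume-restricted by default, mirroring the lACA
workflow; passing `volume=None` widens the counts brain-wide.  Whether the
original count was volume-restricted or brain-wide is not documented; both
modes are provided and the default is a package choice, not a claim.

Two monotonicities follow from the rule and are enforced by tests: raising
`weak_threshold` weakens the stop predicate's complement (more hits count as
weak), so the stop is pointwise **earlier**; enlarging `window` requires a
longer run of weak novels, so the stop is pointwise later.

A structural property of the rule worth knowing: once every strong partner
(total ≥ `weak_threshold`) has been seen, no future novel hit can interrupt
the window, so the rule fires after at most `window` further novel hits.
With few strong partners over a long singleton tail the stop therefore
arrives early, and partners near the threshold are discovered with
probability roughly 1 − (1 − d/N)^(fN) for degree d, pool size N and stop
fraction f.  The acceptance script records the empirical discovery rate over
500 seeded runs rather than assuming a value.

## Circuit extraction and census

Adjacency cells count postsynaptic links from source to target, optionally
restricted to a volume (connector location) and to per-neuron allowed node
sets (e.g., dendrites flagged by the KC splitter, for analyses where only a
target's dendrites or a source's axon is considered).  Pooling rows or
columns by type is plain summation and commutes with counting.

Thresholds are deliberately asymmetric and pinned by tests: circuit
membership from the lACA queries is inclusive (summed input ≥ 5), brain-wide
strong targets are strict (> 150).  Input budgets zero out raw cells of ≤ 2
synapses before renormalizing the survivors to 1 (mode `"vp"`), or group
sources into user-mapped categories (VP, VP+SEZ, gustatory, olfactory,
visual, lACA targets) and normalize by total identified input (mode
`"identified"`).

The census implements the bookkeeping rules for the sensory/projection
neuron counts: hemisphere totals pool by summation (52 + 36 = 88 VP PNs);
novel types subtract previously described and previously misassociated types
(38 − 9 − 6 = 23); completion percentages are reported to one decimal
(20/42 → 47.6%); and the chamber-II triad rule sets a hemisphere's
chamber-II VP4 RN count equal to its VP5 RN count (the two classes cohabit
chamber-II triad sensilla), the remainder originating in chamber I, with the
VP1d count likewise tied to VP5 so the VP1d + VP4 side total is VP4 + VP5.
Note the source material reports both 88 and 89 for the pooled VP PN total
in different sections; the arithmetic here implements 52 + 36 = 88 and the
discrepancy is surfaced rather than resolved.

## Morphology

Skeletons are reduced to dotprops: unbranched chains are resampled at fixed
arclength spacing (default 1 µm) and each point's tangent is the first
principal axis of its k = 5 nearest resampled neighbours (k clamps to the
cloud size; tangent sign is meaningless and only |dot| is used).  The
directed score of query against target sums f(d, a) = exp(−d/σ)·a over query
points at their nearest target points, σ = 3000 nm.  The exponential kernel
was chosen for smoothness, f(0,1) = 1 and a closed-form oracle; published
tabulated (distance-bin × dot-bin) score tables can be supplied and override
the kernel.  Nearest-neighbour ties break to the lowest target point index.

Mean normalized scores — norm(q,t) = S(q,t)/S(q,q), averaged forward and
reverse — give a symmetric matrix with unit diagonal.  Types are assigned by
Ward clustering on the dissimilarity 1 − score (clipped below at 0) with the
dendrogram cut at height 0.8.  Ward on a non-Euclidean dissimilarity is
accepted as-is; the cut height is the conventional one for this kind of
type assignment.  Contralateral matching rigidly reflects one hemisphere
about a single sagittal plane (x = midline) and pairs a neuron when its best
off-diagonal score is its annotated partner; no nonrigid registration is
attempted, which is adequate for synthetic mirrored data but not for real
brain asymmetry.

KC dendrite splitting takes the main tract as the root-to-tip path of
maximal path length and flags every calyx-interior node lying off that path;
connected components of flagged nodes, keyed by their branch root, are the
claws.

## KC input null model

A claw observes a PN class when that class contributes at least `min_syn`
(default 5) synapses to the claw's nodes, all observed inputs weighted
equally; inputs from lACA-associated PNs located inside the lACA volume are
omitted.  The null draws each claw input independently from the bouton-share
vector (class bouton counts normalized to probabilities); a draw is one
(claw, class) event, with no without-replacement correction — the simplest
reading of a random draw.  Per-row input counts default to the observed
totals ("the same number of KCs and PN inputs" honored by matching totals);
holding them fixed versus resampling them is not documented in the source
workflow, so fixed is the default and a constant-per-row mode is provided.
Because inputs are independent, each replicate's class totals are one
multinomial draw of the grand total, which is how the simulation is
vectorized.

The published analysis reports only expected-versus-observed counts; the
Monte Carlo standard errors and empirical p-values here are an added,
clearly-labeled layer.  p-values are two-sided empirical tail probabilities
with the +1 continuity correction, p = min(1, 2·min((1+#{rep ≤ obs})/(R+1),
(1+#{rep ≥ obs})/(R+1))); on small discrete counts this is slightly
conservative, so null calibration sits at or just below the nominal level.
Valence roll-ups sum classes within each valence before computing the same
statistics; classes missing from the valence map are logged and assigned
"unknown".

## Regression

For each (PN, glomerulus) pair, the response is the count of synaptic inputs
from that glomerulus's receptor neurons and the predictor is the PN's cable
length inside the glomerulus volume.  The fit is unweighted ordinary least
squares with an intercept (statsmodels); R² and the F-test p-value (1, n−2
df) are reported.  Degenerate inputs (fewer than 3 samples, constant cable)
raise errors.

## Synthetic generator

The generator emulates the statistical structure the analyses assume, not
biology.  Defaults are the study-scale conditions: per-hemisphere RN counts
per glomerulus (VP2 3R/4L, VP3 4R/5L, VP4 14 per side, VP5 9R/7L, VP1d tied
to VP5, VP1l/VP1m ~7 each; VC5 8 per side is a package choice); two query
PNs (the VP3 vPN and VP2 adPN analogues) supplying ≥ 92% of PN presynapses
in the lACA (`laca_dominance=0.92`, enforced by capping non-query lACA
presynapse budgets); a long-tailed downstream degree distribution planted
exactly per query (default [(3,20), (2,8), (200,1)]: partners × connections
each); 27 KCs with 5 claws of one input each, drawn from an 8-class bouton
share vector (olfactory classes bouton-rich, thermo/hygrosensory classes
bouton-poor, 385 boutons total); planted claw inputs carry min_syn + 1 = 6
synapses plus a 2-synapse sub-threshold distractor from a random other
class; RN→PN synapse counts in each glomerulus are proportional to dendritic
cable at 5·10⁻⁴ synapses/nm plus noise, which the regression stage recovers.

Skeletons are biased random walks inside box envelopes — members of one
morphological type are jittered copies (σ = 100 nm by default) of a shared
prototype, mirrored across the midline for bilateral types.  This gives the
geometric within-type coherence and cross-type separation the morphology
stage needs while making no claim of realistic neurite geometry.  Features
of real data deliberately not emulated: realistic arbor branching
statistics, brain asymmetry, partner sets shared between queries,
electrical properties, and development; passing tests therefore validate
the *algorithms* against planted structure, not their behaviour on real
reconstructions.

Determinism: one numpy PCG64 stream per generation stage, all spawned from
the master seed; fixed seed gives byte-identical output files.  Ground truth
(planted partner degrees, claw draws, effective shares, type labels) is
always emitted in sidecar tables, because every downstream property test is
parameter recovery against it.

Problem sizes used by the test suite and acceptance script — the default
~280-connector-per-query lACA instance, a ~10⁴-connector instance for the
exhaustive-enumeration oracle, 500 seeded sampling runs, 200 null-model
calibration simulations at 1000 replicates, and 10 clustering seeds — were
chosen so the full suite completes in well under a minute per stage while
keeping Monte Carlo standard errors small relative to the tolerances tested.

## Known limitations

* The saturation rule's discovery guarantee degrades sharply when few
  partners exceed the weak threshold over a long singleton tail (see the
  structural note above); the recorded discovery rate, not an assumed one,
  is the honest summary of that regime.
* Mesh containment assumes closed, consistently oriented meshes; no repair
  is attempted and degenerate meshes are rejected.
* Ward clustering treats 1 − score as if it were a metric; dendrogram
  heights are therefore only comparable within one score matrix.
* The claw splitter relies on the main tract being the longest root-to-tip
  path, which holds for the generator's KCs and typical real KCs but can
  misassign neurons whose dendritic branches rival the tract in length.
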