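# Methods

## Scope and data model

The package operates on four inputs: skeletons (SWC, one rooted tree per
neuron, coordinates in nanometres), a connector table (TSV, one row per
(connector, postsynaptic partner) pair; an empty partner marks a peripheral
active zone and must carry a tissue tag), a neuron annotation table
(cell class, cluster, hemisphere, and — for sensory neurons only — a
modality), and two-ROI fluorescence traces (CSV). All distances stay in
nanometres end to end; no unit conversion happens inside the library.

Counting convention: a polyadic connector with k postsynaptic partners
contributes k synaptic pairs. Whether published budget counts in this field
refer to connectors or pairs is often left implicit; the pair convention is
used throughout and is the one assumption to check when comparing against
externally computed budgets.

## Skeleton geometry

Skeletons are validated on construction (unique ids, single root, resolvable
parents, connected acyclic tree). Geodesic distance is the sum of Euclidean
edge lengths along the unique tree path, computed on the raw node polyline
(no smoothing or resampling). Child iteration is ordered by ascending
node_id everywhere, which makes traversals, dendrogram layouts and generated
files deterministic. The dendrogram layout puts each node at
(arc position, lane): arc position is the geodesic distance from the root;
leaves take consecutive integer lanes in depth-first order and an internal
node takes its first child's lane, so sibling subtrees never overlap and an
unbranched chain lies flat in lane 0.

The origin node for placement analyses (anatomically, the nerve-junction /
CNS-entry point — the presumed locus of spike initiation) is always supplied
via the skeleton manifest or per call, never inferred from geometry, and is
configurable per neuron because the anatomically correct reference point can
differ between cell classes.

## Matrices, budgets, fractions

The input-fraction denominator is the target's **full** input count over the
whole connector table, including partners outside any analysis subset; a
column restricted to a subset of rows therefore sums to less than 1 unless
the subset is closed. Zero-input columns are NaN and logged — never silently
zero — and NaNs propagate out of downstream sums by exclusion.

Hemisphere budgets tally pairs by (pre hemisphere × post hemisphere) among
L/R-paired neurons; pairs touching an unpaired neuron are excluded and the
exclusion count is reported, since unpaired cells have no homologue to be
symmetric with.

## Pathway weights

Pathways are simple (no neuron revisited) and strictly layered:
sensory → L1 interneuron (→ L2 interneuron) → target. An
interneuron-to-interneuron hop is allowed only when two layers are
requested; deeper recursion is out of scope because fraction products decay
geometrically and the layered picture is how these circuits are analyzed.
Every hop uses the input fraction of the hop's *post* neuron. Each distinct
path is a separate record; per-(source, target) influence is the sum over
paths. The test suite checks this exhaustively against an independent
depth-limited path enumeration (agreement to 1e-12 on circuits of up to 40
neurons).

Modality rollups sum direct and indirect scores per (target, modality) and
normalize to percentages per target; argmax ties are broken
lexicographically and logged.

## Symmetry statistics

AI = (LL − RR)/(LL + RR) × 100 % (and LR vs RL for the contralateral index)
is undefined when both counts are zero. The cross-cluster ipsi-vs-contra
correlation uses Spearman's rho with mid-ranks (scipy's implementation,
large-sample p); whether to correlate percentages (default) or raw counts is
a flag, since published descriptions of such analyses rarely say which.
Undefined values are excluded pairwise and counted.

## Placement statistics

The synapse's position on the analyzed neuron is the connector's node on
that neuron: the presynaptic node for outputs, the postsynaptic node for
inputs. The one-way F statistic is computed from between/within sums of
squares directly (cross-checked against `scipy.stats.f_oneway` in tests)
so that the degenerate zero-within-variance case can be reported explicitly
as an F = +inf sentinel with p = 0 and a warning rather than a numerical
error.

## Trace analytics

Event detection: the signal is Gaussian-smoothed with a fixed 0.1 s kernel,
the baseline is the median, and the threshold sits `threshold_k` robust
standard deviations (1.4826 × MAD) above it; peaks need a minimum separation
(`min_interval`) and a prominence of `min_prominence` × signal range,
evaluated within a ±`min_interval` window so that slow baseline drift does
not inflate prominences. Detected peaks are refined to the raw-signal argmax
within the smoothing kernel's support, because smoothing delays the apparent
maximum of sharp-onset transients. All criteria are relative to the signal's
own scale, so detection is invariant under affine rescaling. Defaults:
threshold_k = 3, min_interval = 1 s, min_prominence = 0.1, all exposed on
the CLI. A flat signal (MAD = 0) yields zero events with a warning.

Pairing: each myogenic (ROI2) event is assigned greedily to the latest
unconsumed neurogenic (ROI1) trigger within the preceding `window`
(default 2 s, exposed). ROI2 events with no available prior trigger are
reported as orphans rather than dropped — physiologically, myogenic waves
without a neurogenic trigger should not occur, so orphans flag either noise
or a detection failure. Completion rate is 100 × completed/triggers
(undefined at zero triggers); cycle frequency is 60 × events/duration, and
both the trigger-based and completed-wave-based frequency are emitted
because "cycle frequency" is ambiguous between the two. Two-channel
reporters are summarized as per-cell numerator/denominator ratios averaged
without weighting per animal; single-channel reporters use a unit
denominator. One directional note: descriptive definitions of "completion"
in this literature sometimes run myogenic→neurogenic; this package
implements the neurogenic-trigger → myogenic-completion direction, which is
the one consistent with the observation that myogenic waves never precede
neurogenic activity.

## Synthetic generators

The circuit generator draws, per cluster edge and per (pre, post) neuron
pair, a Bernoulli connection with probability
`p_connect × lateral × asymmetry`, where `lateral` is `2·p_ipsi` for
ipsilateral and `2·(1−p_ipsi)` for contralateral pairs (default p_ipsi
0.85), and `asymmetry` scales left-origin probabilities by (1 + ε) and
right-origin by (1 − ε) — so the expected ipsilateral AI is 100·ε. Connected
pairs carry `1 + Poisson(mean_pairs − 1)` synapse pairs (shifted Poisson:
"connected" guarantees at least one). Pairs are grouped into polyadic
connectors of size `1 + Poisson(polyadicity − 1)` per presynaptic neuron.
Configs whose effective probabilities would exceed 1 are rejected before
generation. Skeletons are random-walk trees (branching probability 0.1,
fixed step length, root = origin node) — sufficient for geodesic and
placement tests, with no claim to realistic morphology. Peripheral active
zones are Poisson per modulatory neuron with a categorical tissue-tag
distribution (HCG, PVG, ring gland, midgut by default). The ground-truth
bundle (counts, fractions, budgets, tallies, and pathway sums by an
enumeration written independently of the pathways module) is computed
directly from the planted draws.

The trace generator plants triggers as a Poisson process with a refractory
period (default 2 s): peristaltic contractions are physically refractory,
and without this floor inter-trigger gaps shorter than the detector's
minimum interval would make planted events unrecoverable by any detector.
Each trigger completes with probability `completion_prob`, producing an ROI2
bump `latency_s` later; events are unit-amplitude instant-rise /
exponential-decay kernels (τ default 0.8 s) with Gaussian noise (default
5 % of amplitude). Defaults (20 Hz sampling, ~6 triggers/min) mirror a
confocal time-series recording of esophageal peristalsis at realistic event
rates.

What the generators do *not* emulate: realistic arbor morphology,
synapse-size variation, spatially clustered synapse placement, imaging
artifacts (bleaching, motion), or biologically structured connectivity
beyond the cluster-edge level. Passing recovery tests therefore demonstrates
the correctness of the bookkeeping and statistics on data of this structure,
not robustness to every property of real reconstructions.

## Problem sizes and numerical choices

The validation suite uses circuits of up to ~60 neurons, trees of up to 500
nodes, 20-seed ensembles for stochastic recoveries, and 200-trigger traces —
sizes at which the planted effects (e.g. a 0.3 left bias with ≥500 expected
pairs per side, recovered within ±5 AI points) are statistically
identifiable with wide margins while the full suite runs in seconds.
Floating-point comparisons against oracles use 1e-12 absolute tolerance for
sums of products and exact equality where both sides accumulate identically
(tree path sums). Determinism rests on a single `numpy.random.Generator` per
generator run, sorted iteration everywhere, and canonical shortest-repr
float formatting in SWC output (which makes write→read→write byte-stable).

## Known limitations

- No signed (excitatory/inhibitory) propagation; pathway weights are
  anatomical, not functional.
- Budgets count synapse pairs, not connectors (see above).
- Indirect pathways are limited to two interneuron layers with strict layer
  ordering.
- The trace model has a single event amplitude; amplitude heterogeneity
  would mainly stress the detector's prominence criterion, which is not
  explored.
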