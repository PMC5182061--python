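# Methods

## Data model

A connectome is a set of neuron skeletons (SWC node trees, coordinates in
nm), polyadic connectors (one presynaptic link, ≥ 1 postsynaptic links,
one 3-D position), optional dense-core-vesicle (DCV) records, and named
spatial regions given as unions of axis-aligned boxes. Axes are fixed as
x = medial–lateral, y = dorsal–ventral, z = anterior–posterior,
right-handed.

Two conventions matter everywhere downstream:

* **Polyadic counting.** Each postsynaptic neurite at a connector counts
  as one synaptic connection. A connector `pre=A, post=[B, B, C]`
  contributes A→B = 2, A→C = 1, and yields one `pre` record for A and
  three `post` records.
* **Connector positions are the synapse coordinates.** A polyadic release
  site is one point in space; every synapse record derived from it carries
  the connector position. (Presynaptic treenode positions would be an
  alternative; the difference is at most the neurite-to-cleft offset,
  which is small against the 2000 nm length scales used below.)

Annotations carry class label, hemisphere side (`left`/`right`/`medial`)
and a bilateral homolog id. Homology is symmetric and class-preserving;
medially unpaired neurons have no homolog and mirror to themselves.
Validation rejects violations rather than repairing them.

## Connectivity similarity

Per shared partner *k* of neurons *i*, *j*:
`f(a, b) = min(a,b) − C1·max(a,b)·exp(−C2·min(a,b))` with defaults
C1 = 0.5 (how strongly a one-sided partner is punished) and C2 = 1 (how
quickly the punishment decays once both neurons contact the partner).
The summed score is normalized to its attainable extremes
(Σ −C1·max … Σ max), giving a value in [0, 1]. Entries for the compared
neurons themselves (self-connections and the direct i↔j connection) are
excluded from the sum.

Edge cases and choices:

* If both restricted vectors are all-zero the score is *undefined*, stored
  as a masked entry, never as 0 — absence of evidence is not evidence of
  dissimilarity. Clustering maps undefined entries to the maximal
  distance 1 so no-data pairs never co-cluster.
* `incoming` compares presynaptic-partner profiles (adjacency columns),
  `outgoing` postsynaptic profiles (rows); `combined` is the unweighted
  mean of the two directional normalized scores. If exactly one direction
  is defined (e.g. output-less neurosecretory cells), the combined score
  equals the defined one; if neither is, the pair is masked.

## Synapse similarity

For each synapse *s* of neuron *i* (sign pre or post), the nearest
same-sign synapse *k* of neuron *j* is found with a k-d tree (verified
against exhaustive search in the test suite), and contributes
`exp(−d²/2σ²)·exp(−|n(is)−n(jk)|/(n(is)+n(jk)))`, averaged over all
synapses of *i*. σ sets what counts as "close" (default 2000 nm); ω is the
radius of the local-density counts n(·) (default 2000 nm). The density
penalty makes a lone synapse dissimilar from a synapse inside a dense
cluster even at zero distance.

Choices:

* Local counts include the focal synapse, so n ≥ 1 and the denominator is
  always defined.
* Signs never pool: a presynaptic site is only ever matched to
  presynaptic sites. If *j* has no synapse of the sign of *s*, that *s*
  contributes 0.
* The directional score S(i→j) is asymmetric. The matrix used for
  clustering averages S(i→j) and S(j→i); both raw directions remain
  available through `syn_sim(..., symmetrize=False)`.
* Distances are Euclidean in 3-D (no projection).

## Clustering

Average-linkage (UPGMA) on distance `1 − similarity`. The implementation
uses the Lance–Williams size-weighted update and a fully deterministic
tie-break: among equal-distance pairs, the one with the smallest
(index_a, index_b) in cluster-creation order merges first. UPGMA heights
are monotone, so cutting the dendrogram at distance `1 − t` — clusters are
the maximal subtrees whose internal merges all sit at height ≤ 1 − t — is
well defined; cut thresholds are expressed on the similarity scale
(defaults: 0.2 for synapse similarity, 0.4 for connectivity similarity).
A float tolerance of 1e-12 is applied at the cut boundary; similarity
equality tests in the suite use 1e-9 absolute. Clusters are numbered
contiguously from 1 in leaf order. Partition agreement is measured with
the adjusted Rand index (scikit-learn, behind an id-aligned wrapper).

## Circuit statistics

* **Partner filter** (reconstruction-inclusion rule): a candidate partner
  of the focal set is included iff (a) it has a bilateral homolog — medial
  neurons qualify by definition — and (b) it or its homolog exchanges at
  least `min_syn = 3` links with the focal set; sensory classes are exempt
  from (b). Coverage is the percentage of the focal set's pre-/postsynaptic
  links exchanged with candidates that land on included partners; with no
  candidate links it is vacuously 100. Links internal to the focal set are
  not part of the candidate universe.
* **Connection/region fractions**: percent of a neuron's directional links
  onto a partner set, or placed inside a region box (boundary-inclusive).
  Undefined (no links in the direction) is reported as NaN, never 0.
  Incoming links with an unknown presynaptic neuron stay in the
  denominator — they are real synaptic sites.
* **Bilateral consistency**: connection (s, t) is recapitulated iff
  (homolog(s), homolog(t)) also has ≥ 1 link.
* **DCV proximity**: percent of a neuron's presynaptic sites with at least
  one of its own DCVs within a radius (default 450 nm — "proximity" has no
  published quantitative definition, so the radius is an explicit
  parameter).
* **Identity assignment**: when recovered cluster sizes match a set of
  expected group sizes as multisets and all sizes are distinct, clusters
  are labelled by size; ambiguity or mismatch is an error, not a guess.
* The sensory→focal connectivity matrix applies a separate ≥ 2 display
  threshold; this is a reporting filter, independent of the
  reconstruction-inclusion `min_syn`.

## Synthetic connectome generator

The generator emulates the structure the analyses are designed for, with
one seeded RNG driving everything (equal configs ⇒ byte-identical saved
output):

* **Classes and pools.** Each of 4 classes has bilaterally paired member
  neurons and a class-private pool of partner pairs; a member contacts a
  pool neuron with probability 0.9 within its own class and 0.05 across
  classes.
* **Neurosecretory blocks.** 12 medially unpaired target neurons in blocks
  of 3/2/7 (labelled DH44/DMS/IPC), each block fed by its own pool of
  upstream partner pairs (30 per block) with the same 0.9/0.05 sharing
  probabilities. The pool size matters: mirrored right-side partners
  replicate edge counts exactly, so the per-side pool is the effective
  sample for separating within- from across-block similarity, and pools
  much below ~30 leave the planted structure statistically unresolvable at
  the 0.4 cut. Thirty per block also matches the scale of real
  reconstructions, where neurosecretory populations have dozens of
  upstream partners.
* **Link counts** per planted edge are zero-truncated Poisson with the
  configured *mean* (default 5); the underlying rate is solved from
  λ/(1−e^(−λ)) = mean so the empirical mean matches the configuration. An
  edge is realized as polyadic connectors with 1..3 postsynaptic links.
* **Sensory afferents**: 7 groups × 10 medially annotated neurons; each
  places 30 presynaptic connectors drawn from an isotropic Gaussian
  (sd 2000 nm) at its group centre; centres are sampled pairwise
  ≥ 12,000 nm apart (6 sd — cleanly separable by construction). Posts land
  uniformly on class neurons.
* **Mirroring**: wiring is generated for left-side presynaptic neurons and
  reflected across x = midline, homologs substituted, so every sided
  connector has an exact mirror image. Sensory neurons are medial so their
  spatial groups are not smeared by reflection.
* **DCVs**: placed within 450 nm of each presynaptic site with
  probability 0.9 (`dcv_prob = 1` makes DCV proximity exactly 100%).
* **Skeletons are minimal**: a soma root plus one neurite node per synapse
  involvement. No realistic morphology is attempted.

The shipped reference configuration (`default_fixture`, seed 1799) uses
all of the above defaults.

What the generator does *not* emulate — and therefore what passing tests
do not show about real data: realistic arbors and cable, partner pools
that overlap between classes in graded ways, spatially structured
(non-Gaussian, non-isotropic) synapse clouds, unannotated or orphan
neurites, reconstruction noise, and biological left/right asymmetries
(mirroring is exact). Recovery results on the fixture demonstrate
correctness of the computations under the planted model, not performance
on noisy reconstructions.

## Pipeline

`connclust.pipeline.run` chains input (load or simulate) → adjacency →
connectivity-similarity clustering of targets (incoming direction by
default; the targets have no outputs) → synapse-similarity clustering of
sensory afferents → statistics → JSON report. Artifacts are sorted,
floats are written with round-tripping `repr`, and nothing embeds
timestamps or absolute paths, so reruns are byte-identical. The CLI
(`connclust simulate/adjacency/connsim/synsim/cluster/stats/run`) is a
thin wrapper; each stage can consume the previous stage's files.

## Problem sizes

The reference fixture has 342 neurons, ~4,600 connectors and ~9,100
postsynaptic links; the full pipeline runs in a few seconds and the whole
validation suite in well under a minute. The block-recovery experiment
repeats 100 independent simulations; recovery of the exact 3/2/7 partition
at cut 0.4 lands at 96–98 of 100 across seeds.

## Known limitations

* `conn_sim_matrix` and `syn_sim_matrix` are O(n²) pairwise loops —
  adequate for hundreds of neurons, not tens of thousands.
* UPGMA is the naive O(n³) formulation with deterministic tie-breaks;
  again sized for matrices of hundreds of leaves.
* Region masks are axis-aligned boxes only; real neuropil compartments
  are not boxes. Region boundaries are user-supplied, never inferred.
* The synapse score treats every synapse with equal weight; synapse size
  or confidence is not modelled.
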