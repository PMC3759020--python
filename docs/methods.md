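# Methods

This note documents the models, conventions and numerical choices behind
`fluencynet`, in the order the pipeline runs. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

A category fluency dataset is a group label plus, per subject, the ordered
list of word tokens produced in the timed task. Tokens are normalised by
trimming and case-folding only; no stemming or synonym merging is applied
by default, because any such merge is a linguistic judgement that should be
explicit — an optional user-supplied variant map collapses spellings after
normalisation. Subjects with no valid responses are dropped with a logged
warning. Production order is stored (and round-trips through the CSV/JSON
formats) but is not analysed: the association measure below uses only
incidence, not adjacency in the response sequence.

The response matrix codes incidence binarily — cell (i, j) is 1 iff subject
i produced word j at least once; repetitions collapse to 1. The vocabulary
is sorted lexicographically, which fixes every downstream tie-break.

**Word-matched vocabulary.** For a two-group comparison the networks are
restricted to words produced by at least `min_subjects` (default 2)
subjects in *each* group. The selection is symmetric in the two groups and
errors out explicitly when empty.

## Word correlations

The association between words i and j is the Pearson correlation of their
binary response profiles across subjects, estimated with sample moments.
For binary vectors this equals the phi coefficient of the 2×2 contingency
table, which the test suite uses as an independent oracle. Words with
zero profile variance (produced by everyone, or by no one after
restriction) have no defined correlation; they are removed and reported,
never silently kept. Population versus sample variance scaling cancels in
the correlation ratio, so the choice is immaterial.

## PMFG construction

The complete weighted graph on the vocabulary is filtered by a greedy
single pass: sort all N(N−1)/2 candidate edges by correlation descending
and insert each iff the graph remains planar. The result is a maximal
planar graph — connected, exactly 3(N−2) edges, mean degree 6(N−2)/N —
which is then binarised to uniform weight 1.

Conventions the construction fixes:

* **Signed ranking.** Candidates are ranked by signed correlation, not
  absolute value; negative correlations can enter only if needed to reach
  3(N−2) edges. Similarity filtering in the PMFG literature ranks this
  way, and with a few dozen binary profiles the strongest associations are
  positive anyway.
* **Deterministic tie-break.** Correlations estimated from ~27 binary
  profiles produce many exact ties. Tied candidates are ordered
  lexicographically by their (smaller, larger) word pair, making the edge
  set a pure function of the labelled input matrix — verified by
  rebuilding under column permutations.
* **Early exit.** The pass stops once 3(N−2) edges are placed. A simple
  planar graph cannot exceed 3N−6 edges, so the exit is provably
  equivalent to scanning every candidate; the same bound implies that a
  PMFG is automatically *maximal* (any absent edge would exceed the bound),
  which the tests verify explicitly on small graphs by per-edge planarity
  checks.
* **Planarity testing** uses the left-right planarity algorithm
  (networkx), run without constructing the embedding. Two shortcuts avoid
  provably unnecessary tests: an edge joining two connected components
  cannot break planarity, and any graph with ≤ 8 edges is planar (the
  smallest non-planar subdivisions need 9 edges). The test suite checks
  the construction against a brute-force greedy oracle whose planarity
  decisions come from an exhaustive Kuratowski-subdivision search.
* Inputs with fewer than 3 words are rejected (3(N−2) is degenerate).

## Network statistics

* **L (ASPL):** mean shortest-path hop count over all unordered pairs of
  distinct nodes of a connected graph. Some toolboxes instead average the
  full distance matrix *including its zero diagonal* (the
  characteristic-path-length convention), which scales L by (n−1)/n —
  about 1.3% at n = 75. `aspl(..., self_pairs=True)` implements that
  convention for comparisons with values published under it, and the
  Erdős–Rényi reference comparison below reports it alongside the default.
* **D:** maximum shortest-path hop count.
* **CC:** mean over nodes of local clustering (triangles over possible
  neighbour pairs); nodes of degree < 2 contribute 0. This is the
  mean-local (Watts–Strogatz) convention, not global transitivity.
* **⟨k⟩:** 2E/N; equal to 6(N−2)/N for any PMFG.
* **S:** (CC/CC_rand)/(L/L_rand) with the reference values from an
  Erdős–Rényi ensemble matched in node count and edge count
  (p = E/(N(N−1)/2)). By default CC_rand and L_rand are means over 100
  seeded realizations — more stable than the single draw sometimes used in
  the literature; a single-realization mode is kept for fidelity with that
  practice.

Path metrics raise an explicit error on disconnected graphs; policy
decisions (below) live with the caller.

## Erdős–Rényi null model

`simulate_er` draws G(n, p) graphs and records L, D, CC per realization.
At the density matched to a 75-node PMFG (p = 219/2775 ≈ 0.079, mean degree
≈ 5.8) roughly 15% of draws are disconnected, almost always by a single
isolated node — the expected isolated-node count is n(1−p)^{n−1} ≈ 0.17.
The default policy computes L and D on the largest connected component and
reports the disconnected fraction; a resample-until-connected policy is
available. Clustering is always computed on the full graph.

Empirical significance of an observed value against a simulated null uses
add-one smoothing, p = (1 + #at-least-as-extreme)/(realizations + 1), so
p is never 0; two-sided p doubles the smaller tail (capped at 1).

With 10,000 realizations this reference reproduces the published
distribution for the 75-node case — mean L 2.58 under the
characteristic-path-length convention (2.61 under distinct pairs), mean
D 5, mean CC 0.08 — with one caveat: the spread of the clustering
distribution. The simulated sd of mean local clustering is ≈ 0.016
(≈ 0.013 for global transitivity); a published spread of 0.01 is not
consistent with the mean-local convention at this n and p, so comparisons
of that spread should not be read as a reproduction check.

## Bootstrapped partial-network comparison

Per realization a word subset (default 40 of the word-matched vocabulary)
is drawn; each group's partial network is **rebuilt from its correlation
submatrix** — not cut out of the full PMFG — and L, D, CC are recorded.
Subsets are shared between groups within a realization by default, which
removes subset-choice noise from the between-group contrast; an
independent-subsets mode covers the stricter reading of the procedure.
Degenerately, a subset equal to the full vocabulary reproduces the full
network every time, which the tests use as an exactness check, and a
6-word toy vocabulary is checked against exhaustive enumeration of all 15
subsets.

The per-metric group comparison is a pooled-variance independent t-test
over the two realization vectors (df = 2·realizations − 2). **This is
anticonservative by construction**: bootstrap realizations are resamples
of one fixed dataset pair, not independent observations, so the test
detects any finite-sample difference between the two datasets at rates far
above the nominal α. The same caveat applies to the impact-score t-test
below (75 dependent per-word scores per fixed network). Measured under an
exchangeable null — both groups generated from identical parameters,
different seeds — the impact test rejects at ~40% and the bootstrap tests
at ~15–20% at α = 0.05. The machinery replicates the published analysis
style; its p-values should be read as descriptive effect summaries, not
calibrated error rates.

## Word impact scores

WC(i) = ASPL(network rebuilt without word i) − ASPL(full network), with the
leave-one-out network rebuilt from the correlation submatrix (canonical);
an induced-subgraph mode (delete the node, no re-filtering, largest
component if disconnected) exists as a labelled non-canonical fast
approximation. Positive scores mean the word shortens paths while present.
With 4 words the full PMFG is K4 and every leave-one-out network a
triangle, so all scores are exactly 0 — a degenerate identity the tests
assert. An 8-word case is checked against a full brute-force
re-implementation (greedy-with-Kuratowski rebuild + Floyd–Warshall).

Because the networks are binarised and always carry 3(N−2) edges, removing
a word merely promotes the next-ranked candidates; impact therefore
rewards words whose associations are strong enough to make them *hubs* of
the filtered graph, not merely words that happen to sit between clusters.
The tests plant such a connector (correlated with both subcategories more
strongly than the within-subcategory ties) and verify it lands in the top
impact decile in ≥ 80% of seeded runs.

## Synthetic data generator

The generator emulates the clustering/switching account of category
fluency. Per subject: (1) each lexicon word is known independently with
probability p_know·rank^−knowledge_decay — frequency-graded vocabulary
knowledge; (2) a retrieval length is drawn (normal, rounded, clipped to
the known lexicon); (3) a walk picks a subcategory with probability
proportional to its known unretrieved words, emits words within it
proportionally to Zipf-like base weights without replacement, and switches
subcategory with probability p_switch (or on exhaustion). Output lists are
ordered and duplicate-free.

The rank-decaying knowledge term is load-bearing: with uniform per-word
knowledge the 27-subject union saturates the lexicon and the two groups'
distinct-word counts become indistinguishable. Group contrasts are encoded
exactly where fluency studies report them — lexicon coverage and retrieval
length. The shipped profiles (a 200-word lexicon in 12 subcategories;
`nh_like`: p_know 0.95, decay 1.1, retrieval 18±4; `ci_like`: p_know 0.85,
decay 1.3, retrieval 13±3.5; both p_switch 0.35, 27 subjects) are
calibrated so group draws produce ≈ 132 and ≈ 106 distinct words; their
word-matched common vocabulary is ≈ 44 words. No claim is made that these
parameters reproduce any particular group's network values — direction and
size of metric differences are empirical outputs.

What the generator does *not* emulate: real lexical semantics (words are
abstract tokens; subcategories are flat and non-overlapping), perseveration
and errors, time-varying retrieval rate within the minute, or
phonologically driven retrieval. Passing tests therefore show that the
pipeline recovers planted co-occurrence structure and behaves correctly on
data of realistic shape — not that any particular clinical contrast will
reproduce.

## Problem sizes and runtime choices

Planarity testing is pure Python, so PMFG cost grows steeply with N
(~5 s at 75 nodes, ~20 s at 132). The test suite therefore exercises the
full published sizes (up to 132 nodes) only in the structural-invariant
and degree-identity checks, and uses reduced sizes elsewhere: the
exchangeability calibration runs 50 repetitions on an 18-word lexicon with
30 bootstrap realizations, and oracle-agreement suites use ≤ 10-node
graphs where exhaustive Kuratowski search is feasible. The Erdős–Rényi
reference runs its full 10,000 realizations (array-based BFS via
scipy.sparse.csgraph, ~30 s).

## Known limitations

* The bootstrap and impact t-tests are anticonservative (see above); a
  permutation scheme over subjects would be the calibrated alternative and
  is out of scope here.
* PMFG construction cost limits interactive use to a few hundred words.
* The empirical p-values inherit Monte-Carlo granularity 1/(R+1).
* Correlation matrices from small samples carry heavy ties; results are
  deterministic given the documented tie-break but a different tie-break
  yields a different (equally defensible) network.
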