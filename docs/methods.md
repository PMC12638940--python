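# Methods

This note documents the models, conventions, numerical choices and known
limitations of `biomarknet`, in the order of the pipeline.

## Signed networks and the triangle census

A network is reduced at load time to its *signed subnetwork*: directed
edges whose annotation maps to +1 (activation) or −1 (inhibition).
Accepted sign tokens are `+`, `-`, `1`, `-1`, `+1`, `activation`,
`inhibition` (extensible for the SIF dialect). Rows without a
recognisable sign are counted and skipped with a warning; self-loops are
dropped; duplicate rows collapse. An ordered pair annotated with *both*
an activation and an inhibition is kept as two signed edges — both count
toward a motif's negative-edge total, while the pairwise *feature* "sign
of N→T" is reported as 0 for such conflicted pairs (the same encoding as
"no edge"; the conflict is rare and the triangle counts retain the
information).

Only fully connected three-node motifs (triangles) are consumed
downstream, so the census enumerates them directly from the undirected
skeleton (ordered-neighbour intersection) rather than classifying all
3-node subgraph types; for the triangle class the output is provably
identical and is tested against exhaustive triple enumeration on
hundreds of random networks. Classification per motif:

* **unbalanced** ⇔ the number of negative edges among all signed edges
  of the triple is odd (structural-balance convention);
* **cycle** ⇔ a directed Hamiltonian walk over the three members exists
  in at least one orientation, using any of the present edges
  (bidirectional edges may serve either direction).

Density is `2|E*| / (|V|(|V|−1))` with `|E*|` the number of distinct
unordered connected node pairs, so reciprocal edges count once and the
classical bound of 1 holds. All outputs are deterministically ordered
(lexicographic member triples) and thus byte-reproducible.

## IDP–target enrichment

The observed statistic is the fraction of triangles whose member triple
contains at least one IDP and at least one drug target. Two nulls are
computed and both reported, because "random chance" can be conditioned
in two defensible ways:

* **analytic** — each triangle is treated as three uniform draws without
  replacement from the pool of distinct triangle-member nodes,
  preserving the label counts restricted to that pool; the qualifying
  probability comes from exact multivariate-hypergeometric enumeration
  over the four label categories (both/IDP-only/target-only/neither).
  Under a uniform random relabelling of the pool this is also the exact
  per-triangle marginal, so the analytic value equals the expectation of
  the permutation null; the two differ only in the correlation structure
  used for spread estimates.
* **permutation** — node identities in the pool are shuffled with a
  mandatory seed (default 1000 permutations, vectorised); the null mean,
  standard deviation and a one-sided (+1-corrected) p-value are
  reported. This is the reference when triangle membership is
  degree-skewed, as it always is in real networks.

A node carrying both labels satisfies the conjunction by default; a
strict mode requires two distinct labelled members (condition: ≥1
IDP-labelled member, ≥1 target-labelled member, ≥2 labelled members).
The pool is the set of nodes appearing in any triangle, not all network
nodes — enrichment is asked relative to the triangle population.

Regulatory-motif over-representation uses a 2×2 Pearson chi-square
(IDP-target vs other × in-class vs not) without continuity correction,
dof 1; zero margins raise a named error rather than returning NaN.

## Disorder annotation

Disorder content is the fraction of residues called disordered:

| source | convention | threshold (default) |
|---|---|---|
| curated regions | residues covered by merged 1-based inclusive ranges / length | — |
| pLDDT (mmCIF B-factor) | score strictly **below** threshold | 50 (scale 0–100) |
| IUPred long/short | score strictly **above** threshold | 0.5 (scale 0–1) |

Strict inequalities put threshold-value residues on the ordered side.
pLDDT content is per-residue (equivalent to summing maximal
sub-threshold runs). mmCIF extraction takes one value per residue from
the CA atom, falling back to the residue's first atom, residues ordered
chain-then-sequence; multi-chain files concatenate. IUPred globular
scores are not modelled (they track long scores too closely to add
information). A missing source stays absent — never zero — and is
encoded downstream as `(value 0, missing-flag 1)` column pairs, because
curated disorder databases cover only a minority of the proteome and
absence is itself informative. Mean-score IDP calls used for third-node
aggregates: curated-region membership; mean pLDDT < 50; mean IUPred >
0.5.

## Pair features and labels

Every member of a triangle containing a target becomes a *neighbour* of
that target, regardless of edge sign and direction; two targets in one
triangle yield both ordered pairs. Rows are keyed (neighbour, target,
network); a physical pair present in several networks contributes one
row per network, and "combined" training scopes take the union of rows
(no deduplication — the per-network topology features genuinely differ).
Feature groups, in deterministic column order: per-network participation
flags; shared-triangle counts (total/unbalanced/cycle); the two directed
edge signs; neighbour-is-target and target drug-modality indicators;
per-source disorder contents and mean scores for both proteins with
missing flags; third-node aggregates (target count, per-source IDP
counts, per-source mean disorder over shared triangles — a fixed-length
summary of an unbounded set); betweenness and bridgeness-proxy
centrality of both proteins. The class label is never a feature and no
feature encodes the predictive-biomarker annotation.

Labels: class 1 when the neighbour carries a predictive-biomarker
annotation for a drug whose target set contains the paired target
(manual-curation outcomes enter as an optional override table mapping a
pair to a forced label, since curation cannot be recomputed); class 0 is
sampled, seeded and without replacement, from neighbours absent from the
biomarker annotation altogether, topped up from the remaining unlabelled
pool when the non-biomarker pool is too small (or drawn fully at random
under the `random` strategy). The negative:positive ratio defaults to
548/332 ≈ 1.65, the composition of a realistic curated corpus; all other
pairs stay unlabelled and are scored, not trained on.

## Learning

Random Forest (scikit-learn) and gradient-boosted trees (XGBoost) are
the two ensemble families; 2 algorithms × 4 training scopes (three
networks + combined) × 4 annotation scopes (DisProt, AlphaFold, IUPred,
all — implemented as feature-column masks) span 32 models.
Hyperparameters come from an in-package successive-halving random
search: `budget` configurations are sampled from a documented grid
(trees 100–1000, depth 2–10, learning rate 0.01–0.3, subsample 0.5–1.0,
feature subsampling), every survivor is scored by 3-fold stratified CV
accuracy on a stratified subsample that doubles per round (floor 30
records), the better half survives, and the winner is refit on the full
labelled data. The search is written in-package rather than through a
library class so that the budget-1 edge case ("evaluate and refit that
candidate") and the candidate-halving schedule are exactly specified and
deterministic; with a fixed seed the whole module is bit-reproducible,
and training rows are put in canonical sorted-key order before every fit
so results do not depend on caller row order.

Validation schemes: LOOCV (one held-out class-1 probability per record,
consumed by the score-fusion stage), repeated stratified k-fold (default
100 × 5-fold with re-shuffled folds per repeat; tests and the CLI use
far fewer repeats), stratified 70:30 split, cross-network transfer (fit
on one network's labelled rows, evaluate on another's, schema-checked),
and a degenerate resubstitution scheme kept for identity checks.
Stratification is used throughout because the default class imbalance
(≈38% positive) makes unstratified folds fragile. Metrics: ROC AUC,
precision, recall, F1, accuracy. Feature-group ablations rerun the
validation on biological-only, topological-only, centralities-only and
motif-count-only column subsets.

**Bridgeness proxy.** Module-overlap bridgeness values from external
modularisation tools cannot be recomputed here; the column
`bridgeness_proxy` is betweenness × the inverse-degree bridging
coefficient of Hwang et al. (a node bridges when it is low-degree
relative to its neighbours), computed on the undirected skeleton. The
name deliberately avoids claiming equivalence to any module-based
bridgeness.

## Biomarker Probability Score

Within each prediction column the m pairs get tie-averaged, 0-indexed,
**descending** ranks (rank 0 = highest class-1 probability);
`BPS(p) = 1 − (Σᵢ R_{p,i}/n)/(m−1)` over the n contributing columns.
Descending 0-indexed ranks are the only convention for which a pair
top-ranked by every prediction scores exactly 1 and a bottom-ranked pair
exactly 0; the ascending alternative (which mirrors the score) is
exposed behind a flag for sensitivity checks. Consequences asserted by
the tests: column rank sums are always m(m−1)/2, so the mean BPS is
exactly ½ with or without ties; the score is invariant under any
strictly monotone per-column transform; for n = 1 it is affine in the
single column's rank. n is whatever models are supplied (8 for a full
annotation scope); missing models are dropped column-wise before the
call — the formula tolerates no missing cells. Candidate calls use a
strict `BPS > 0.5` in at least one annotation scope, with a stricter
all-scopes flag reported alongside.

Because the score is purely rank-based, the `> 0.5` cut calls exactly
the pairs in the upper half of the rank distribution (up to ties). Two
consequences worth keeping in mind: probability *gaps* between
well-separated groups do not move the cut, and comparing BPS calls
against labels whose positive rate differs from ½ has an irreducible
floor of |positive rate − ½| even for a perfect ranker. The synthetic
noise-floor check therefore uses a balanced fixture: with 880 labelled
pairs, a continuous planted signal and 10% independent label flips, the
misclassification count at the BPS cut recovers the realised flip count
(≈88, i.e. ≈10%).

## Synthetic data

The generator emulates the *statistical* structure the pipeline
consumes, not the biology: directed signed Erdős–Rényi networks
(default 150 nodes, edge probability 0.06, 30% negative edges, three
networks per workspace); per-protein disorder levels from a
two-component Beta mixture (low Beta(2,10) / high Beta(8,3), 30% high)
so both well-folded low-disorder proteins (~7–11% content, the typical
kinase regime) and genuinely disordered proteins occur, with per-residue
noise and correlated pLDDT/IUPred tracks; curated-region coverage for a
sparse 40-protein subset; one or two drugs per target with
small-molecule/antibody modality. Labelled datasets default to 880
pairs with positive fraction 332/880 ≈ 0.38, matching the scale and
balance of a realistic curated corpus. The planted label thresholds a
signal score (a motif-count column, a disorder column, or their
standardised sum) at the attainable cut point closest to the configured
positive fraction — for discrete motif counts the achieved fraction can
deviate from the request, but the label remains a deterministic function
of the feature, which is what makes zero-noise recovery checks sharp.
Label noise flips each label independently. Everything is a pure
function of the config (hash-seeded per sub-stream), and every written
file round-trips through the package's own readers, including minimal
synthetic mmCIF structures carrying pLDDT in the B-factor column.

What passing tests on this generator do **not** show: behaviour under
real degree distributions (hubs concentrate triangles and centralities),
correlated annotation missingness, drug–target promiscuity, or
literature-curation bias in the labels. Results on real networks should
be validated with the permutation null and cross-network transfer before
being believed.

## Problem sizes and numerical choices

Test and demo runs use deliberately small instances — networks of
25–150 nodes, 200–880 labelled pairs, search budgets of 1–6 candidates,
ensembles of 30–60 trees — chosen so the full suite exercises every code
path, including leave-one-out loops, at interactive speed; all sizes are
plain parameters and scale up unchanged. Ties in ranking use
`scipy.stats.rankdata` averaging; chi-square uses no continuity
correction; probabilities at exactly the 0.5 decision threshold predict
class 1 (`>=`), while BPS candidate calls are strict (`>`). Degenerate
inputs raise typed errors (undefined density below 2 nodes, empty score
tracks, zero contingency margins, single-class training data, exhausted
negative pools) rather than returning sentinel values.

## Known limitations

* The bridging centrality is a proxy, not a module-overlap bridgeness.
* The analytic enrichment null assumes exchangeable triangle membership;
  report the permutation null alongside it on real data.
* Gradient-boosted probability scales are not calibrated; only their
  ranks enter the BPS, which is the point of the score.
* The negative-control composition on real data is a design choice
  (strategy + ratio in config), not something the method can infer.
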