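# Methods

## Sentence graphs

Each candidate drug pair gets its own graph, built from the blinded
sentence.  Blinding replaces the candidate mentions with `drug1`/`drug2`
(leftmost mention first) and every other drug mention with `drug`; for a
multi-token mention the span's syntactic head token (the token whose
dependency head lies outside the span) carries the placeholder and the
remaining span tokens are dropped from graph construction.  Non-candidate
mentions are blinded as well — only placeholders, never real drug names,
reach the feature space, so the learner cannot memorize drug identities.

The structure component represents either the dependency tree or the
predicate–argument structure.  Both use the same scheme: word vertices
(labels: lower-cased lemma, POS tag), one relation vertex per arc, directed
edges head → relation → dependent (predicate → relation → argument for
PAS).  PAS relation vertices are labelled `<predicate-lemma>_<role>`
(`by_arg2`), which keeps the governing predicate visible in the label;
a bare-role labelling is available via `predicate_in_label=False`.

Shortest paths between the pair are measured by edge count on the
undirected view.  When several geodesics tie, all of them are tagged: a
vertex v is on a geodesic iff dist(drug1, v) + dist(v, drug2) equals the
pair distance, and the analogous test marks edges.  The `_IP` suffix is
applied to *all* labels of an on-path vertex (lemma, POS and relation
labels alike), so path membership is visible in every feature the vertex
contributes.  Edge weights: 0.9 on geodesic edges, 0.3 elsewhere, 0.9 on
the linear chain.  A pair disconnected in the structure graph (routine for
PAS, where parses fragment across clauses) yields no tags and all-0.3
weights, with a logged warning rather than an error.

In the linear component drug1 itself carries `_B` and drug2 `_A`, so `_M`
marks strictly-between tokens; a sentence consisting only of the two drugs
has no `_M` vertices at all.

## Semantic classes

Eight classes cover the PK sublanguage: Drug, Enzyme, PK parameter, Number,
Mechanism, Change, Degree, Negation; Mechanism optionally refines into
Drug-enzyme, Enzyme-drug and Drug-metabolite (the refined sets must be
subsets of Mechanism, validated at load time).  Tagging matches case-folded
lemmas (surface as fallback), longest n-gram first (up to 4 tokens, the tag
landing on the n-gram's head token), with regex patterns as an extra route
into Number.  When one term belongs to several classes the precedence
Negation > Mechanism > Change > Degree > PK parameter > Enzyme > Drug >
Number applies — rarer, stronger cues win.  A refined run falls back to
coarse Mechanism for terms no subclass covers.

Integration substitutes the class name for the *lemma* label of the tagged
token's word vertices in both components, preserving the `_IP`/`_B`/`_M`/
`_A` suffix and leaving POS labels, relation vertices, edges and weights
untouched.  The `drug1`/`drug2` anchors are deliberately never substituted:
collapsing both to `Drug` would erase which vertex is which, and the
pair-anchor labels are what ties the two components together.  Generic
`drug` mentions are tagged Drug only when the lexicon is non-empty, so an
empty lexicon degenerates the SC pipeline to the identity exactly
(bit-identical scores to the base variant).

The shipped lexicon under `src/ddikernel/data/lexicon/` is a small
illustrative starter set; real deployments should point `--lexicon` at
their own directory (same layout: `<class>.txt`, `number.regex`,
`mechanism_refined/<subclass>.txt`).

## The all-paths kernel

With adjacency A (entry = edge weight) and label allocation L (binary,
|labels|×|V|), the feature matrix is G = L M Lᵀ with
M = (I−A)⁻¹ − I = Σ_{n≥1} Aⁿ, i.e. G[i,j] is the total weight of all
non-empty directed *walks* (vertex repetition allowed) from any vertex
carrying label i to any vertex carrying label j, each walk weighted by the
product of its edge weights.  The `−I` excludes the empty walk.  The
printed form of the series is ambiguous about orientation; the
implementation fixes the semantics above, the only orientation under which
the cross-graph sum K(G′,G″) = Σ_ij G′[i,j]·G″[i,j] compares like with
like.  K is a Frobenius inner product of feature matrices, hence every Gram
matrix is symmetric positive semi-definite.

Numerics: A and L are scipy CSR; the closed form solves the linear system
(I−A)X = Lᵀ (never an explicit inverse) — sentence graphs have tens of
vertices, so dense solves inside are cheap.  The closed form requires
spectral radius ρ(A) ≤ 1 − 1e−6 and raises a convergence error otherwise;
with both components acyclic (dependency edges follow head→dependent, the
chain runs left→right) A is nilpotent and ρ = 0.  A truncated variant sums
A¹..Aⁿ; on acyclic graphs it is exact once n reaches the longest path, and
for ρ < 1 its error is bounded by ‖A‖ⁿ⁺¹/(1−‖A‖).  The random cyclic test
graphs are rescaled to ρ ≤ 0.7, where the 60-term tail is below 1e−8 —
at ρ near 0.95 a 60-term truncation would still carry O(0.1) error, so
accuracy claims are only meaningful on this range.  Gram computation
flattens each sparse G into a row of an n × |labels|² matrix F and computes
K = FFᵀ as one sparse product.

Labels seen only at prediction time are dropped from L (equivalently: a
reserved out-of-vocabulary row whose kernel mass is zeroed).  Dropping
cannot create spurious similarity between two different unseen labels and
keeps test-set isolation exact: vocabulary, lexicon statistics, basis and
threshold all derive from training data only.

## Sparse RLS and thresholding

The learner is the subset-of-regressors form of regularized least squares:
basis B (≤ 500 instances sampled uniformly without replacement, seeded),
score(x) = Σ_b α_b K(x, x_b), α solving
(K_BT K_BTᵀ + λ K_BB) α = K_BT y with y ∈ {+1 DDI, −1 NDDI}.  With B equal
to the full training set this reduces exactly to dense RLS,
α = (K + λI)⁻¹ y (verified against that oracle in the tests).

λ defaults to 100.  The kernel is used without normalization, so Gram
diagonals on realistic sentences are O(10²–10³); a unit λ is then vacuous,
and the nearly unregularized system — rank-deficient whenever near-duplicate
sentences occur — produces numerically wild coefficients.  λ on the scale
of the kernel entries regularizes meaningfully and makes results almost
independent of the basis sample.  The solver uses Cholesky factorization
and falls back to a ridge jitter of 1e−8 × mean(diag) when the
factorization fails; the jitter is relative because an absolute 1e−8 is
below round-off at the kernel's magnitude.

The decision threshold comes from leave-one-document-out cross-validation:
for each training document, fit on the remaining documents (basis
restricted to their instances) and score the held-out document; pool all
held-out scores; the threshold is the midpoint between consecutive distinct
sorted scores that maximizes pooled F1, ties resolved toward the lower
threshold, plus one candidate below the minimum (predict everything).  If
no cut achieves F1 > 0 the threshold is placed above the maximum score.
The final model is refit on all training data with that threshold.

## Evaluation

Precision/recall/F1 with DDI as the positive class and shared-task
conventions for empty denominators (P = 0 with no predicted positives,
R = 0 with no gold positives, F1 = 0 when P + R = 0).  ROC curves sweep
the distinct scores (ties grouped) with trapezoidal AUC; the AUC equals the
normalized Mann–Whitney U statistic, which the tests assert to 1e−12.
Method comparisons use two-sided paired t-tests at p < 0.05 on per-document
F1 — the pairing unit is a configurable choice; documents were chosen
because the corpus unit of independence is the abstract.  Identical inputs
report t = 0, p = 1; a constant non-zero difference has zero variance and
is reported as t = ±∞ with a warning.

## Synthetic corpora

The generator emulates the *structure* of a PK-DDI corpus — documents →
sentences → drug mentions → labelled candidate pairs, with dependency and
PAS parses — using hand-authored templates, so no parser is required.  The
label rule mirrors the linguistic signal the kernel exploits: a pair is
positive exactly when a Mechanism/Change trigger lies on its dependency
path.  Five structural twin templates (active change verb, passive
mechanism verb, enzyme-mediated nominal, mechanism nominalization, relative
clause over an enzyme) produce positives and, with trigger vocabulary
swapped for open-class neutral words, structure-matched negatives; further
negative patterns are negated triggers (trigger on the path, label
negative), conjunction lists (three drugs, all pairs negative) and mere
co-occurrence.  Structure-matched twins take half of the negative
probability mass — they are the hard cases the method is about.  Clausal
sentences compose two clauses under a subordinating conjunction; their four
cross-clause pairs are negative, emulating the long multi-clause sentences
of in-vitro reports.  Variable adjuncts (cohort and time PPs, P-value
parentheticals) add the non-discriminative clutter of real sentences.

Trigger terms are sampled from class-specific synonym pools whose size is
the `synonym_pool_size` knob (default 8): small pools make lexical path
features sparse for the base variants while class substitution stays dense —
the contrast the semantic-class experiment measures.  Neutral and filler
vocabularies are deliberately large and independent of that knob, because
non-trigger vocabulary is an open class in real text; making it small would
hand the lexical model an unrealistic shortcut.  The sentence-level
positive probability is solved in closed form so the *pair-level* positive
fraction matches `positive_rate` despite multi-pair negative patterns, and
labels are then flipped independently with `label_noise_rate`.

Defaults (200 documents, 1–4 sentences each, ≈800 pairs, positive rate
0.35, noise 0.05, pools of 8, 10% clausal sentences, seed 42) give problem
sizes where the full six-variant experiment runs in about half a minute on
one CPU.  What passing tests on this corpus do **not** show: robustness to
parser errors, real lexical ambiguity, discourse phenomena (co-reference,
cross-sentence relations), or the coverage of any particular curated
lexicon — the shipped trigger lists are illustrative, not the published
resources.  Held-out F1 on the synthetic corpus is accordingly higher than
anything achievable on curated corpora; only the *ordering* of the variants
and the mechanism behind it (class substitution densifying sparse lexical
paths) transfer as qualitative claims.

## Known limitations

* Negation handling is purely lexical (a Negation class); no scope
  detection.
* The CoNLL-U reader ingests the 10 standard columns only and ignores
  multiword-token and empty-node lines.
* PAS graphs routinely leave cross-clause pairs disconnected; such pairs
  are represented with all off-path weights rather than skipped, which
  depresses PAS recall on clausal sentences.
* Kernel feature matrices are |labels|², so extremely large vocabularies
  (far beyond sentence scale) would need a sparser Gram path than the
  flattened-row product used here.
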