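# Methods

## The ranking model

Given a query pair `<g, d>` (a gene and a disease, each with an alias
set) and a candidate reference `r` (title + abstract), the ranker scores
`r` by thirteen factors grouped into three measures:

**Conclusiveness (factors 1–7).** `Length(r) = min(|r|/AvgLen, 1)` where
`|r|` is the token count of the body (title followed by abstract) and
`AvgLen` is the mean body length over the *training* references.
`GeneTF` and `DiseaseTF` are the alias-folded mention counts of `g` and
`d`, normalized as `min(TF/3, 1)`. `Gene@Title` / `Disease@Title` are
indicators for a mention inside the title. `Gene@Ending` /
`Disease@Ending` are `LastPos(x, r)/|r|`, with `LastPos` the 1-based
index of the final token of the last mention (so a mention ending on the
last token scores exactly 1, and an absent entity scores 0).

**Richness (factors 8–9).** `NotGeneNum` counts the distinct genes other
than `g` with at least one mention and squashes the count `c` to
`c/(c+1)`; `NotDiseaseNum` likewise for diseases.

**Focus (factors 10–13).** The title/ending counterparts of factors 4–7
applied to the *other* genes and diseases: an indicator that any
distractor appears in the title, and the maximum of `LastPos/|r|` over
distractor entities (one conclusively-treated distractor suffices to
dilute focus, hence the max rather than a mean).

All factors lie in [0, 1]. The three normalizations that are genuinely
open design choices here are: the TF cap at three occurrences (three
mentions already signal salience — the same threshold the
position-frequency baseline uses), the `c/(c+1)` squash (bounded without
an arbitrary cap, order-preserving), and max-aggregation for distractor
endings.

### Text normalization and matching

Every non-alphanumeric character becomes a space; tokens are lowercased
unless they contain at least two alphabetic characters that are all
uppercase (`BRCA1` is preserved, `HbS` folds to `hbs`). The two-letter
minimum is this package's reading of "all-uppercase terms keep their
case": a lone capital letter is ordinary prose, not a symbol.

Mention matching is strict dictionary matching on normalized tokens: a
left-to-right greedy scan in which the longest alias matching at the
current position wins and the scan resumes after it. Aliases owned by
several entities credit every owner. Matches never straddle the
title/abstract boundary. Sentences are obtained by splitting the raw
abstract on period-plus-whitespace unless the input supplies explicit
sentence lists (generated corpora do, so fixtures are exact).

### Learning to rank

The factors are integrated by a pairwise linear SVM (the
RankingSVM-by-classification reduction): within each training query,
every (target, non-target) pair contributes the standardized feature
difference and its mirror, and a no-intercept linear SVM (hinge loss, L2
penalty, `C = 1.0`, tolerance 1e-6) is fitted on the differences.
Feature means and standard deviations come from the training folds only;
constant features are dropped from the fit and given zero weight.
Candidates are ranked by descending score with ties broken by ascending
reference id, so every run is reproducible. The solver is deterministic
for a fixed seed; on non-separable data it may stop on an iteration cap
rather than the tolerance, which does not affect reproducibility.

### Baselines

* **BM25**: Okapi form with `k1 = 2`, `b = 0.75`, idf
  `ln((N − n + 0.5)/(n + 0.5))` floored at 0, alias-folded TF over the
  body. N and n are counted over training references.
* **VSM**: a classic practical tf-idf cosine surrogate,
  `sqrt(TF) · (1 + ln(N/(n+1)))² / sqrt(|r|)`, standing in for
  engine-specific vector-space scorers.
* **Proximity BM25**: BM25 fed with adjusted term frequencies
  `TF' = TF + Σ exp(−dist²/2σ²)` summed over all (gene occurrence,
  disease occurrence) pairs, σ = 25 tokens by default. This is a
  deliberately generic proximity enhancer: reproducing any specific
  published proximity model is out of scope; the contract preserved here
  is that co-located query terms raise the score and distant ones do
  not.
* **PosFreq**: eight indicator features (gene/disease in title, in
  first/last abstract sentence, at least three abstract mentions),
  integrated by the same pairwise SVM.

Integrative rankers concatenate components (`bm25+posfreq`,
`crfref_full+posfreq`, …) and train the pairwise SVM on the joint
vector; scalar baselines enter as one feature each.

### Evaluation

AP for one query is the mean over targets of `j / rank_of_jth_target`;
MAP averages AP over *all* queries, with zero-target queries
contributing 0 (ranking systems must also operate on uncorrelated pairs,
and dropping them would inflate every system equally). `P@X` keeps
denominator X even when fewer candidates exist. Cross-validation splits
queries (never individual candidates) into k = 4 folds by seeded shuffle
and round-robin assignment; corpus statistics and feature scalers are
recomputed per training fold so no held-out information leaks. Two
systems differ significantly only when both the paired t-test and the
Wilcoxon signed-rank test (zero differences dropped) reject at
α = 0.05; identical vectors yield a degenerate not-significant verdict,
and a constant nonzero shift is treated as p = 0 for the t-test (the
statistic is unbounded there).

## The synthetic study conditions

Real corpora for this task pair literature-database retrieval with
curator judgments and cannot be redistributed, so the generator emulates
the properties the method depends on, not the language. Each query pair
receives 10–30 candidate abstracts (title of 8 tokens, five sentences of
18 tokens) built from a filler vocabulary disjoint from all aliases.
Both query entities are always mentioned (every candidate passes
candidate filtering by construction); with configurable probabilities
they are planted in the title (0.35 gene / 0.45 disease) and final
sentence (0.4 each), with Poisson(1) extra mentions. Distractor genes
and diseases (Poisson(1.2) each) land in the body and, less often, the
title (0.15) or final sentence (0.25). Thesauri carry 1–3 aliases per
entity, including multi-token aliases (probability 0.5) and optional
cross-entity ambiguity.

Relevance is planted directly in factor space: each candidate's own
13-factor vector `f` gives `P(target) = sigmoid(β·f + intercept +
pair offset)`, labels are drawn and flipped at a noise rate (default
0.05). The default β weights conclusiveness and richness positively and
focus-dilution negatively; the intercept (−6.5) and per-pair offset
(uniform ±3) are set so per-pair target fractions range from 0 to above
0.8 with a mean near 0.35, including zero-target pairs — the diversity
the method must cope with in practice. Defining relevance on the factor
space makes recovery and ablation claims provable properties of the
generator; the price is that passing tests show the pipeline recovers
planted structure, not that the factor model describes real abstracts.

Two preset conditions serve specific experiments:

* **Recovery** (`recovery_config`): 200 pairs × 20 candidates,
  noise-free threshold labels (`y = 1` iff `β·f + intercept + offset >
  0`). Within a pair the threshold rule is a monotone function of
  `β·f`, so a perfect ranker exists; the trained weights are compared to
  β by cosine and held-out queries with targets must reach MAP 1.
* **Ablation** (`ablation_config`): 300 pairs, label noise 0.1,
  richness/focus coefficients an order of magnitude above the
  conclusiveness ones, heavier distractor placement, intercept +6.3
  against the strongly negative focus contributions. The preset was
  calibrated against the generating model itself: under these conditions
  the true-β scorer beats its conclusiveness-only restriction by ≈0.31
  MAP, so the full ≥ conclusiveness+richness ≥ conclusiveness ordering
  is a property of the data a correct learner must reproduce, not a
  hope.

What the generator does **not** emulate: linguistic structure, realistic
alias morphology, thesaurus hierarchy (symptom terms of the query
disease counting as distractors, a known limitation of
thesaurus-based focus), retrieval-engine query expansion, and
inter-annotator noise structure beyond i.i.d. label flips.

## Numerical and protocol choices

* Problem sizes in the test suite and acceptance script (120-pair
  comparison corpus, 300-pair ablation, 200-pair recovery, 500-rep
  type-I simulation at 30 resampled pairs) are chosen so the full
  pipeline exercises every stage in minutes on one CPU.
* All randomness flows from explicit integer seeds (corpus generation
  uses independent child streams for thesauri, documents and labels);
  regenerating with one seed is byte-identical, and the experiment
  command writes identical ranked runs and metric tables across
  repeated invocations.
* Ties (equal scores, equal fold sizes) break lexicographically or by
  round-robin, never by hash or insertion order.
* Degenerate inputs fail loudly: empty references, thesaurus rows
  without aliases, vacuous training sets (no query with both a target
  and a non-target), metric calls on empty run sets, significance tests
  on fewer than 5 pairs.

## Known limitations

* The pairwise-classification reduction is equivalent to ordinal
  RankingSVM for binary relevance in the large-margin limit but is not
  verified against the original solver.
* The proximity baseline is a stand-in with the right qualitative
  contract, not a reimplementation of any published proximity model.
* Factor normalizations (TF cap, count squash) are this package's
  choices; alternatives (log caps, per-corpus maxima) would preserve the
  orderings the tests check but change absolute factor values.
* MEDLINE reading covers PMID/TI/AB with continuation lines; other
  fields are ignored.
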