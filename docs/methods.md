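# Methods

This note documents the models implemented in `orthomem`, the
conventions adopted where the mathematics leaves room, the synthetic
study conditions used throughout the tests, and what those tests do and
do not establish.

## Pairwise orthographic similarity

All schemes score a probe word *i* against a studied word *j* as a
(weighted) match count *M* divided by a normalized alignment length:
*s* = *M* / (*a* + (1 − α) + (1 − Ω)), where *a* is the unit count
(letters or bigrams) of the longer word, α weights matches on the first
letter and Ω matches on the final letter of the **studied** word.  With
α = Ω = 1 this is simply *M*/*a*.  The normalization keeps *s* ≤ 1 for
α + Ω ≤ 2; fitted exterior weights above 1 (empirically plausible for
the initial letter) can push *s* slightly above 1, which downstream
code tolerates — the bound is only asserted for weights ≤ 1.

Conventions worth making explicit:

- **Slot codes** match letters at identical start-anchored positions.
  The **end-anchored** code indexes positions from the final letter
  (−1, −2, …); α and Ω still refer to the start and end of the original
  strings, so it is computed on the reversed strings with the exterior
  roles swapped.  The **both-edges** code is the mixture
  *w·s*<sub>start</sub> + (1 − *w*)·*s*<sub>end</sub>.
- **Overlap model.**  Each studied letter occupies a Gaussian
  distribution over positions, SD σ<sub>l</sub> = d(1 −
  exp(−(l − ½)/r)) for serial position *l*; a probe letter at position
  *k* collects the probability mass of matching studied letters inside
  (k − ½, k + ½].  When a letter repeats in the studied word, mass is
  summed over **all** of its positions — this convention reproduces the
  published nearest-neighbor value 0.30 for ledge→ledger at the
  perceptual-identification estimates r = 1.094, d = 1.544
  (nearest-position-only gives ≈ 0.29).  Two properties follow from the
  construction and are deliberate: self-similarity is below 1 whenever
  σ > 0, and the scheme is asymmetric in probe/studied order even for
  equal-length words, because the σ schedule applies to the studied
  word's positions.  The backward pass of the both-edges overlap model
  indexes σ by distance from the word end (a convention; the mixture at
  the published parameters lands within 0.01 of the printed 0.28).
- **Bigram codes** decompose a word into ordered letter pairs —
  adjacent pairs (closed) or pairs with up to two intervening letters
  (open) — plus a start marker `_x` and end marker `x_`.  Each bigram
  may match at most once (multiset intersection), which for identical
  tokens equals optimal bipartite matching; this prevents `ababab` from
  matching `ab` three times over.
- **Levenshtein similarity** is (*a* − *D*)/*a* for edit distance *D*.
- **Letter-"e" salience** (shallow-processing encoding tasks): when
  "e" occurs in *both* words, *s*\* = (*M* + ε)/(*a* + (1 − α) +
  (1 − Ω) + ε), position-free.  The joint-presence reading follows the
  verbal description of the manipulation (deciding whether an "e" is in
  the string), not a literal set-union reading.

One commonly quoted worked value does not survive the positional
rule itself: the end-anchored similarity of *kitten*/*smitten* is often
given as 4/7 ≈ .571 ("four shared letters"), but the pair matches at
end positions −1(n), −2(e), −3(t), −4(t), −5(i) — five matches, 5/7 ≈
0.714.  The positional rule is implemented as stated; the 4/7 figure
counts shared letter *types* rather than aligned letter tokens (an
analogous off-by-one affects the start-anchored count for the same
pair, where position 4 of both words holds "t").

## Global similarity

*g* = Σ<sub>j≠i</sub> *s<sub>ij</sub><sup>p</sup>* / *N<sub>L</sub>*.
Exclusion of the probe's own list entry is by string identity after
normalization; the divisor stays *N<sub>L</sub>* (the list length, not
the count of summed terms).  *p* must be positive; *p* = 1 is the
linear model.  The combined orthographic/semantic form mixes channels
per item before averaging, with semantic similarity the cosine between
embedding vectors truncated at 0 (orthogonality already means
"unrelated", and truncation keeps the power transform from amplifying
negatives).  Vectors are L2-normalized at load so cosine is a dot
product.  Out-of-vocabulary words score 0 with a logged warning by
default; a strict mode raises instead.

## Decision model

Two linear ballistic accumulators race from starts ~ U(0, *A*) to
thresholds *b* = *A* + *B* with normally distributed drift rates;
RT = decision time + *t*₀.  Global similarity shifts the mean drifts in
mirror image (*v*<sub>old</sub> + *v*<sub>new</sub> = 2*V*₀).  Drift SD
is a property of the **trial** (probe status): 1 for lures — the
scaling constraint that identifies the model — and a free
η<sub>target</sub> for targets, applied to both accumulators.

Trials on which both sampled drifts are negative never finish.  The
simulator redraws the drift pair; the likelihood for an observed
(response, RT) is accordingly
f<sub>winner</sub>(RT − t₀)·(1 − F<sub>loser</sub>(RT − t₀)) /
(1 − Φ(−v<sub>old</sub>/η)Φ(−v<sub>new</sub>/η)), so simulator and
likelihood form a matched pair (verified against each other by
quadrature and million-draw simulation in the tests).  RT ≤ t₀ yields
log-likelihood −∞ rather than an exception, so samplers reject such
proposals.

Numerics: the closed-form density cancels to exactly 0 in the far-left
tail (fast RT relative to b/v) although the true value is merely tiny;
inside the fitting path the density is floored at 10⁻³⁰ so single
extreme trials cannot strand a chain at −∞.  A = 0 and η → 0 limits are
handled explicitly (the distribution degenerates to a point mass at
b/v).

## Hierarchical estimation

Participant parameter vectors (V_target, V_lure, γ_target, γ_lure, B,
t₀, V₀, η_target, and optionally p) are tied by group-level normal
distributions, truncated to the support for positive parameters.  The
start-point range *A* is held at a common design value (0.5): the LBA's
scale is already fixed by η_lure = 1, and freeing *A* mostly trades
against *B* at these trial counts.  Priors are weakly informative and
deliberately flat on the scale the similarity signal actually takes:
group means of γ ~ N(0, 300), group SDs half-normal(30), p ~ TN(2, 5),
B ~ TN(1, 1), t₀ ~ TN(0.3, 0.3), V₀ ~ TN(2, 2), η_target ~ TN(1, 1),
V ~ N(0, 3).  Because *g* is an average over *N<sub>L</sub>* mostly
near-zero transformed similarities, γ is numerically large (tens to
hundreds); a prior that looks "wide" on a unit scale is strongly
informative here and measurably tilts the γ–p ridge toward zero, which
is why the γ prior SD is 300.

Sampling is blocked DE-MCMC: each participant's vector is one crossover
block (θ* = θᵢ + γ_DE(θⱼ − θₖ) + U(−10⁻⁴, 10⁻⁴), γ_DE = 2.38/√(2d)),
and each parameter's (μ, σ) pair is its own 2-D block with five sweeps
per iteration (group blocks are cheap relative to the participant
likelihoods and mix slowest).  Three standard accelerations are used:
chains start from per-participant Nelder-Mead penalized-MLE points
(jittered), a migration step during burn-in lets stranded chains adopt
the state of another chain, and 10% of iterations use full-length
γ_DE = 1 proposals to traverse the long, curved γ–p ridge.  Burn-in is
the first half; all randomness flows from one seed.  Fits report
split-chain R̂ (via arviz); production-length runs should reach
R̂ < 1.05 before WAIC values are compared — the scaled-down test fits
report R̂ but sit above that bar by design of their budget.

Pairwise similarities are precomputed per dataset because the fit
surface holds the representation parameters (α, Ω, w, d, r, ε) fixed;
freeing them would require recomputing every similarity per proposal.
Estimating representation parameters jointly is the natural extension
and is out of the provided fitting surface's scope.

WAIC = −2(lppd − p_waic) from the pointwise log-likelihood matrix over
thinned posterior draws; lower is better.  Model comparisons in the
tests use single-participant fits — WAIC needs only pointwise
likelihoods, and this keeps repeated-seed comparisons affordable.

## Synthetic study conditions

The generator emulates unrelated-word list-learning experiments: random
letter strings drawn from English letter frequencies (realistic
incidental overlap without a lexicon), study lists of 40 words of 4–7
letters, 300 test trials per participant in study/test blocks,
50/50 targets and lures.  A controllable fraction of lures are planted
near neighbors of studied words — single-letter deletions (edit
distance 1) at 2% of lure draws, matching the 1–3% incidence of such
lures in comparable datasets, plus distance-2 (10%) and distance-3
(12%) variants so every minimum-edit-distance class is populated.
Deletion position (start/middle/end) is controllable for the
exterior-letter analyses.

Generating group-level parameters: V_target = 1, V_lure = −1
(hit rate ≈ .88, baseline FAR ≈ .08), γ_target = 2 (effectively no
similarity pathway into targets), γ_lure = 100, p = 3 (the classic
cubic similarity transform), B = 1, A = 0.5, t₀ = 0.25 s, V₀ = 2,
η_target = 1.2, with between-participant SDs of roughly 10–20% of each
mean.  γ_lure = 100 is calibrated so the FAR rise from the lowest to the
highest global-similarity bin is ≈ .10 — the size of effect reported
for real unrelated-word datasets.  These conditions were fixed after an
identifiability analysis: profile likelihood over *p* (maximizing γ per
participant) peaks at the generating *p* = 3 with ≈ 8 log-units of
curvature across ±1, so the recovery study is a meaningful test rather
than a prior-dominated one.  With weaker similarity signal (longer
lists, longer words, fewer mid-similarity lures) γ and *p* are jointly
unidentified at these trial counts — a real limitation of the design,
not of the sampler.

What the synthetic data do **not** emulate: real lexical statistics
(morphology, neighborhood density, frequency), word frequency and
age-of-acquisition effects on memorability, semantic structure beyond
the synthetic cluster embeddings, sequential effects, and contaminant
RTs.  Passing recovery and signature tests therefore shows the
estimation machinery and the model's qualitative mechanics are sound
under the model's own assumptions; it does not validate the model
against real behavior.

## Analysis summaries

- Equal-count ("equal area") bins of *g*, computed separately within
  targets and lures, with P("old") and the .1/.5/.9 RT quantiles for
  correct and error responses per bin.  Ties in *g* break by stable
  trial order; fully degenerate *g* degrades to round-robin binning
  with a warning.
- Lure classification by minimum Levenshtein distance to the study
  list: 1 → HS, 2 → MS, 3 → LS, ≥ 4 → VLS, with multiplicity recorded
  as 1x vs 2x+ items at the minimum.  For HS lures the missing-letter
  subtype (start/middle/end) is the position of the unshared letter in
  the closest studied word: the first divergent position for
  deletion/insertion pairs, the substituted position for equal-length
  pairs.  Medians summarize lure RTs because HS lures are rare.
- Empty classes are reported as missing (NaN), never as zero rates.

## Known limitations

- The fitting surface fixes the representation parameters; only the
  LBA parameters and *p* are estimated.
- Short-chain fits leave R̂ ≈ 1.5–2 on the γ–p ridge; credible
  intervals from such fits are serviceable for coverage but not for
  publication-grade interval estimates.
- The packaged English word list (~2.3k common words) is for demos;
  the random-string mode is the tested default.
- Condition-varying parameter maps (V, γ by condition × status) are
  supported in the LBA layer, but the hierarchical fit surface
  currently distinguishes status only.
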