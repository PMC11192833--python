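# orthomem

Orthographic and semantic global-similarity models of recognition
memory, mapped onto choice and response time through a linear ballistic
accumulator (LBA) race, with hierarchical Bayesian estimation (DE-MCMC)
and WAIC model comparison.

`orthomem` is aimed at memory and psycholinguistics researchers who
want to ask *which representation of word form* best explains false
recognition: it implements seven pairwise string-similarity schemes
(slot codes, both-edges slot codes, the overlap model and its
both-edges variant, closed and open bigrams, and Levenshtein
similarity), aggregates them into a per-trial memory-strength signal,
and fits the full chain to trial-level old/new decisions and RTs.

## The model

For a probe word *i* and study list *L* of length *N<sub>L</sub>*, each
scheme produces pairwise similarities *s<sub>ij</sub>* ∈ [0, 1]
(weighted letter/bigram matches divided by the alignment length, with
exterior-letter weights α and Ω).  Global similarity is the
power-transformed mean

> *g<sub>i</sub>* = Σ<sub>j∈L, j≠i</sub> *s<sub>ij</sub><sup>p</sup>* / *N<sub>L</sub>*,

where the nonlinearity *p* ≥ 1 suppresses the many low-similarity
comparisons so that only near neighbors of the probe contribute.  An
optional semantic channel mixes in truncated word-embedding cosines:
*w<sub>o</sub>s<sup>p</sup> + (1 − w<sub>o</sub>)c<sup>p*</sup>*.

*g* enters the decision stage as a drift-rate regressor for a
two-accumulator LBA:

> *v*<sub>old</sub> = *V*₀ + *V* + γ·*g*  *v*<sub>new</sub> = *V*₀ − (*V* + γ·*g*)

with start points uniform on [0, *A*], thresholds *b* = *A* + *B*,
drift SD 1 for lures and η<sub>target</sub> for targets, and
non-decision time *t*₀.  Participants are tied together by group-level
(truncated) normal distributions sampled with differential-evolution
MCMC; representations are compared by WAIC.

A synthetic-data module generates word pools, study/test sessions and
simulated observers with the structure of list-learning experiments
(40-item lists, 4–7 letter words, rare edit-distance-1 lures), so the
whole chain is testable without any external dataset.

## Worked example

```python
from orthomem.orthography import slot_similarity, open_bigram_similarity
from orthomem.global_similarity import GlobalSimilarityParams, global_orthographic_similarity

slot_similarity("ledge", "ledger").value        # 0.8333  (5 matches / alignment 6)
open_bigram_similarity("sustain", "station").value  # 0.5882  (10 of 17 bigrams)

study = ["ledger", "stone", "crisp", "badge"]
global_orthographic_similarity("ledge", study, "open-bigram",
                               GlobalSimilarityParams(p=3.0)).g
# 0.10331...: only the near neighbor "ledger" survives the cubic transform
```

The same quantities from the shell:

```bash
$ orthomem similarity --scheme slot ledge ledger
0.8333333333
$ orthomem simulate --seed 1 --out run/        # synthetic study -> run/trials.csv + run/truth.json
$ orthomem fit --trials run/trials.csv --scheme open-bigram --iters 400 --seed 1 --out run/
{"waic": ..., "lppd": ..., "p_waic": ...}
$ orthomem analyze --trials run/trials.csv --bins 6   # HR/FAR + RT quantiles per similarity bin
$ orthomem classify --trials run/trials.csv --summary # FAR by HS/MS/LS/VLS lure class
```

Simulated datasets show the characteristic pattern: false alarm rates
climb across global-similarity bins (≈ .08 → .19 in the shipped test
conditions) while hit rates stay flat when similarity feeds only the
lure drift, and distance-1 ("high similarity") lures draw dramatically
more false alarms than distance-2 lures.

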