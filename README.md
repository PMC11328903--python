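# dentabc

Coalescent-based Approximate Bayesian Computation (ABC) with
random-forest model selection for **binary dental nonmetric traits**.

Ancient-DNA coverage of deep prehistory is sparse, but teeth survive —
and their minor morphological variants (ASUDAS nonmetric traits) are
heritable, mostly neutral, and abundant in the published fossil record.
`dentabc` treats each dichotomized dental trait as a single neutral
biallelic locus and asks which demographic history best explains the
trait frequencies observed across spatiotemporal samples of specimens.
It was built for Upper Paleolithic Europe — two regions (West, East),
three climate periods (MPG 47–28 ka, LPG 28–14.7 ka, LG&EH 14.7–7 ka),
and fourteen competing scenarios of continuity, replacement, glacial
bottlenecks, migration and ghost-population admixture — but every stage
is reusable: trait preprocessing, polarity estimation, the simulator,
and the forest-based selection are independent modules.

## The method in brief

For a trait observed in $n_{tg}$ specimens of group $g$, the observed
summary is the derived-state frequency per (trait, group) cell.  Under
each candidate model $M$ with parameters $\theta \sim \pi(\theta)$
(Table-style priors: log-uniform sizes, uniform proportions and split
times, log-uniform migration rates, uniform phenotypic mutation rate
$\mu$), a structured coalescent with serially sampled lineages
generates a genealogy per trait; mutations on branches define derived
lineages, and simulated frequencies are computed with exactly the
observed per-cell sample sizes and missingness mask.  The resulting
reference table $\{(s_i, m_i)\}$ trains a random-forest classifier
$s \mapsto m$.  The majority vote over trees at the observed vector
$s_\mathrm{obs}$ selects the model; a secondary regression forest on the
out-of-bag misclassification indicator approximates the posterior
probability $P(M = \hat m \mid s_\mathrm{obs})$; out-of-bag
classification of every row yields the power test (per-model
classification error CE and confusion matrix); and a Fisher
discriminant projection onto $M-1$ axes checks that the selected model
can generate the observed point.  Model comparison proceeds step-wise:
within categories of similar scenarios first, then a final contrast of
the category winners.

Trait **polarity** (is presence ancestral or derived?) is estimated
beforehand by correlating worldwide modern-population trait frequencies
with waypoint-routed great-circle distance from sub-Saharan Africa: a
negative cline marks presence as ancestral, and only traits with
significant clines (α = 0.05) enter the analysis.

## Worked example

Generate a synthetic Ice Age dataset whose true history is an East
replacement at 14.7 ka from the West (model 8), preprocess it, and ask
the classifier to pick among continuity (3), West-source replacement
(8) and ghost-source replacement (9):

```python
from dentabc import abcrf, coalescent as co, demography as dg, synthkit, trait_data

truth = synthkit.SyntheticTruth(
    model_id=8,
    specimens_per_group={g: 40 for g in co.GROUP_ORDER},
    seed=11, n_traits=8, missingness=0.35,
)
ds = synthkit.generate_synthetic_dataset(truth)
print(f"specimens: {ds.matrix.n_specimens}, traits: {len(ds.matrix.traits)}, "
      f"mean observable traits/specimen: {ds.matrix.mean_observable_traits():.2f}")

labels = trait_data.assign_groups(ds.matrix.metadata)
polarity = {d.trait_id: d.polarity for d in ds.trait_definitions}
gft = trait_data.summarize_frequencies(ds.matrix, labels, polarity)
vec = gft.flat_vector()
print(f"observed summary vector: {len(vec)} unmasked (trait, group) cells")

cfg = co.SampleConfig.from_grouped_table(gft)
rt = co.build_reference_table([3, 8, 9], dg.default_priors(), cfg,
                              n_per_model=400, seed=1,
                              mutation_mode="single_site")
res = abcrf.simultaneous_select(rt, vec, n_trees=500, seed=0)
print(f"votes: {res.selection.votes}")
print(f"selected model: {res.selection.selected_model} "
      f"(posterior {res.selection.posterior_probability:.2f}, "
      f"prior expectation {res.selection.prior_expectation_pct:.0f}%)")
print("per-model CE:", {m: f"{c:.0%}"
                        for m, c in res.power.classification_error.items()})
```

Output (about a minute on one CPU):

```
specimens: 240, traits: 8, mean observable traits/specimen: 7.31
observed summary vector: 48 unmasked (trait, group) cells
votes: {3: 138, 8: 221, 9: 141}
selected model: 8 (posterior 0.49, prior expectation 33%)
per-model CE: {3: '38%', 8: '33%', 9: '53%'}
```

The forest recovers the true replacement history: model 8 takes 221 of
500 votes against a prior expectation of 33%, and the power test warns
that the two replacement variants (8 vs 9 — same event, different
source) are the hard part of this contrast (CE 33–53%), exactly the
kind of honesty the power test exists to provide.

A command-line interface mirrors the library
(`dentabc synth | preprocess | polarity | build-rt | select | power |
lda | simulate`); every report embeds the seed and a configuration
hash.

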