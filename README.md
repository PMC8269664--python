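# homnet

High-order functional connectivity networks from central-moment features of
dynamic FC, with a t-test + LASSO + linear-SVM classification pipeline.

## The problem

Resting-state fMRI connectomics usually summarises each subject by a static
functional-connectivity (FC) network: the Pearson correlation of every pair of
region-averaged BOLD time series. That discards two kinds of information at
once — how connectivity *fluctuates* over the scan, and how regions interact
at a level *above* pairwise coupling. `homnet` implements a framework that
captures both, aimed at case–control classification studies (the motivating
application is autism-spectrum-disorder vs control) where the group difference
is hypothesised to live in the *moments* of dynamic FC rather than in its
mean.

## The model

Starting from a subject's ROI time-series matrix **X** ∈ ℝ^(M×R) (M time
points, R regions):

1. **Low-order dynamic FC network (LoD-FCN).** A window of length *W* slides
   in steps of *s*, giving K = (M−W)/s + 1 overlapping segments; each segment
   yields a Pearson correlation matrix **D**(k) = [ρ_ij(k)]. Edge (i,j)
   carries the FC time series ρ_ij = (ρ_ij(1), …, ρ_ij(K)).

2. **Central-moment networks CM(d).** Each edge series is summarised by its
   d-th central moment, mapped back to the correlation scale by a signed d-th
   root:

       m_ij(d) = sign(S) · |S|^(1/d),   S = (1/K) Σ_k (ρ_ij(k) − ρ̄_ij)^d

   with the mean ρ̄_ij substituted at d = 1. CM(2) measures FC volatility,
   CM(3) its skew, CM(4) its kurtosis, and so on. These summaries are — by
   construction, and bitwise in this implementation — insensitive to the
   chronological order of the windows.

3. **High-order networks Ho(d).** Row i of CM(d) is region i's *moment
   profile*: how its FC with every other region fluctuates. Ho(d) correlates
   profiles pairwise, h_ij(d) = corr(m_i(d), m_j(d)), exposing second-level
   interactions that no single edge expresses.

4. **Classification.** Each network's strict lower triangle (R(R−1)/2 edge
   features) feeds a two-sample t-test filter, then LASSO
   (½‖I − Ŷω‖² + λ‖ω‖₁), then a linear SVM, evaluated by repeated stratified
   5-fold cross-validation with all hyperparameters (p-threshold, λ, C) tuned
   by an inner nested 5-fold CV. Per-network classifiers can be combined by
   majority voting (a label wins with more than T/2 of T votes).

A synthetic-cohort generator produces ROI time series whose pairwise coupling
drifts block-wise around a base coupling matrix, with group differences
injected into the *variance* (and optionally skew) of that drift on chosen
edges — so the full pipeline is testable end to end without any imaging data.

## Worked example

Simulate a 15+15 cohort whose patients have more volatile coupling on the ten
edges among the first five regions, then classify with the static network (C),
the variance network CM(2) and the high-order network Ho(2), and combine them
by majority vote:

```python
import numpy as np
from homnet import (SlidingWindowSpec, SyntheticCohortSpec, simulate_cohort,
                    build_all_networks, build_feature_table, nested_cv,
                    selection_frequency, evaluate_strategy)

spec = SyntheticCohortSpec(n_per_group=15, seed=42)   # 15 patients + 15 controls
subjects, manifest = simulate_cohort(spec)
window = SlidingWindowSpec(W=30, s=2)

nets = [build_all_networks(ts, window, orders=[2]) for ts in subjects]
tables = {
    "C":     build_feature_table([n.cfcn  for n in nets], manifest.labels, "C"),
    "CM(2)": build_feature_table([n.cm[2] for n in nets], manifest.labels, "CM(2)"),
    "Ho(2)": build_feature_table([n.ho[2] for n in nets], manifest.labels, "Ho(2)"),
}
results = {tag: nested_cv(t, repetitions=3, seed=7) for tag, t in tables.items()}
for tag, res in results.items():
    m = res.metrics
    print(f"{tag:6s} ACC {m.acc:5.1f}%  TPR {m.tpr:5.1f}%  TNR {m.tnr:5.1f}%  F1 {m.f1:5.1f}%")

combo = evaluate_strategy(["C", "CM(2)", "Ho(2)"], results)
m = combo.metrics
print(f"{'vote':6s} ACC {m.acc:5.1f}%  TPR {m.tpr:5.1f}%  TNR {m.tnr:5.1f}%  F1 {m.f1:5.1f}%")

freq = selection_frequency(results["CM(2)"].records)
for k in np.argsort(freq)[::-1][:3]:
    i, j = tables["CM(2)"].feature_ids[k]
    print(f"edge (ROI_{i+1}, ROI_{j+1}) selected in {freq[k]:.0%} of folds")
```

Output:

```
C      ACC  70.0%  TPR  68.9%  TNR  71.1%  F1  67.7%
CM(2)  ACC  87.8%  TPR  88.9%  TNR  86.7%  F1  88.1%
Ho(2)  ACC  82.2%  TPR  82.2%  TNR  82.2%  F1  80.7%
vote   ACC  90.0%  TPR  91.1%  TNR  88.9%  F1  90.0%
edge (ROI_5, ROI_2) selected in 100% of folds
edge (ROI_2, ROI_1) selected in 100% of folds
edge (ROI_4, ROI_1) selected in 100% of folds
```

The static network sees little (the groups share the same *mean* coupling);
the moment-based networks recover the injected volatility effect, the
majority vote improves on every single network, and the selection frequencies
point exactly at the edges that carry the effect (all among ROI 1–5).

ACC/TPR/TNR/F1 are accuracy, sensitivity, specificity and F1-score over the
cross-validation folds; a selection frequency of 0.98 means an edge survived
t-test + LASSO selection in 49 of the 50 = 10×5 CV folds.

The same experiment is available from the shell via the `homnet` command
(`simulate`, `build-networks`, `build-moments`, `build-ho`, `classify`,
`vote`, and a config-driven `run` that sweeps a (W, s, d) grid).

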