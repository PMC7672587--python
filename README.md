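# enrichopt

Linear QSAR scoring equations derived by **directly optimizing virtual-screening
enrichment**, with the conventional residual-sd-optimizing MLR feature-selection
baseline, the full screening metric suite, and a synthetic imbalanced-benchmark
generator.

## The problem

Virtual screening ranks a large compound library by a model's predicted
activity and sends the top of the list to the bench.  QSAR models used for
this purpose are traditionally *derived* by regression criteria (minimize the
residual standard deviation, maximize R²) and *validated* by external
regression statistics (Q²F1/F2/F3) — but then *used* for a different task:
early recognition of a handful of actives inside thousands of presumed-inactive
decoys.  The two objectives can disagree badly: a model with excellent
R²/Q² can retrieve zero actives from a decoy pool, because the direction in
descriptor space that best fits continuous activity is not necessarily the
direction that best separates actives from everything else, and because decoys
often fall outside the applicability domain the regression was calibrated on.

`enrichopt` derives the scoring equation by optimizing the screening objective
itself.

## The algorithm

A model is a k-descriptor linear equation over z-scored molecular descriptors

    A_j = Σ_{i=1..k} X_{ji} · C_i

used only to *rank* the M training compounds, of which L are active.  The
objective is

    P = number of known actives within the first L places of the ranked list,

maximized by Metropolis Monte Carlo / simulated annealing over descriptor
identities and weights: each step either swaps one descriptor (probability
`p_swap`) or perturbs one weight by ±ΔJ; a step from P₁ to P₂ is accepted when
P₂ > P₁, otherwise with probability `exp(-(P₁-P₂)/RT)`.  RT follows a
saw-tooth schedule (linear descent 0.3 → 0.01 in 0.01 steps, 300 MC steps per
level, repeated until the step budget, default 10⁶, is spent or P = L is
reached).

Because P takes at most L+1 values, many models tie at the best count
P_best.  All of them are archived, and ties are broken by a rank-compactness
score: rank all compounds, z-score the active and inactive ranks separately
(to offset class imbalance), and set

    S_Z = Σ z(rank of actives placed beyond L) − Σ z(rank of inactives placed in the top L).

Lower S_Z is better; a perfect ranking scores exactly 0.

Models are evaluated by R² and Q²F1/F2/F3 where continuous activities exist,
and on every set by the actives retrieved in the top L, the enrichment factor

    E = (actives in top L / L) / (actives in library / library size),

the confusion matrix at the top-L cut, and the Matthews correlation
coefficient.  The baseline searcher reuses the same MC/SA engine but selects
descriptor subsets minimizing the residual sd of an ordinary least-squares fit
to pKi — the conventional recipe the enrichment objective is compared against.

## Worked example

```python
from enrichopt import (AnnealConfig, BenchmarkConfig, generate_benchmark,
                       prune_descriptors, zscore_normalize, run_eoa, screen,
                       round_half_up)

cfg = BenchmarkConfig(n_active_train=25, n_inactive_train=225,
                      n_active_valid=25, n_inactive_valid=225,
                      n_active_test=25, n_decoys=1000,
                      effect_size=3.0, seed=7)
bench = generate_benchmark(cfg)

pruned, report = prune_descriptors(bench.dataset)
normed, params = zscore_normalize(pruned)
result = run_eoa(normed.subset("train"), k=7,
                 cfg=AnnealConfig(seed=1, total_steps=20_000))
print(f"P_best = {result.archive.p_best} / L = {result.L} "
      f"({len(result.archive.solutions)} tied solutions archived)")

for name in ("train", "validation", "test1"):
    sub = normed.subset(name)
    L = int(sub.binary_labels().sum())
    ranked, sc = screen(result.best_model, sub, L)
    print(f"{name:<10} actives in top {sc.L}: {sc.actives_in_top_L:>3}  "
          f"enrichment {round_half_up(sc.enrichment, 1):>5} "
          f"(max {round_half_up(sc.max_enrichment, 1)})  MCC {round_half_up(sc.mcc, 2)}")
```

prints

```
P_best = 23 / L = 25 (6297 tied solutions archived)
train      actives in top 25:  23  enrichment   9.2 (max 10.0)  MCC 0.91
validation actives in top 25:  21  enrichment   8.4 (max 10.0)  MCC 0.82
test1      actives in top 25:  14  enrichment  23.0 (max 41.0)  MCC 0.55
```

The search ranked 23 of the 25 training actives into the top 25 places of the
250-compound training set (enrichment 9.2 of a maximal 10.0); the model
transfers almost unchanged to the held-out validation set, and retrieves 14 of
25 actives from a 1025-compound decoy pool — 23-fold enrichment over random
picking.

The same pipeline is available from the shell:

```sh
enrichopt simulate --out bench.csv --seed 7
enrichopt preprocess --table bench.csv --out-dir prep
enrichopt train --table prep/preprocessed.csv --out-dir models \
    --mode eoa --k 7 --seeds 0,1,2,3,4 --normalization prep/normalization.tsv
enrichopt screen --model models/eoa-k7-seed0.model.yaml \
    --table bench.csv --out-dir screened
```

`train --mode mlr-sd` runs the residual-sd baseline on the same data.
Input tables are delimited text (CSV/TSV) with a header, the compound id in
the first column, and named activity / label / set columns.

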