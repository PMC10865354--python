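# screenopt

Automated optimization of molecular-docking model parameterizations by
retrospective virtual-screening enrichment.

## The problem

A docking model — a docking engine plus one complete assignment of its
tunable parameters (grid/boundary settings, matching-sphere placement) —
is judged retrospectively: given known ligands (*positives*) and
property-matched decoys (*negatives*), a good model ranks the ligands
above the decoys. Building such a model by hand means guessing parameter
values, docking the whole labeled set, inspecting enrichment, and
iterating. `screenopt` automates that loop for computational chemists who
run structure-based virtual screens:

- a **multiplex DAG** derives every candidate parameterization from the
  input files and a YAML config (Cartesian product over declared value
  pools);
- **grid search** and **beam search** (top-fraction retention, range
  refinement around the incumbent, stochastic matching-sphere
  perturbation) explore the space;
- **normalized LogAUC** scores every candidate;
- an **empirical null distribution** with Bonferroni correction says
  whether the best model beats chance given how many models were tried;
- **Tanimoto-clustered leave-one-out cross-validation** checks that
  iterating the search does not overfit the known ligands.

The physical docking engine is abstracted behind a backend contract. The
shipped backend is a synthetic oracle whose class separation peaks at a
hidden parameter optimum, so the entire pipeline — search, statistics,
reports — runs and is testable on a laptop; an adapter for a real engine
implements two methods (`schema`, `dock`).

## The enrichment criterion

Scores follow the energy convention (lower = better). Ranking all
molecules produces a ROC; with λ = 0.001 as the floor on the false
positive rate,

    LogAUC = ( ∫_λ^1 TPR(FPR) d log₁₀ FPR ) / log₁₀(1/λ)

and the random-classifier expectation is R = (1 − λ)/(ln 10 · log₁₀(1/λ))
≈ 0.1446. The reported criterion is

    normalized LogAUC = (LogAUC − R) / (1 − R)

which is 1 for a perfect classifier, 0 in expectation for a random one,
negative for worse-than-random, with floor −R/(1−R) ≈ −0.169. The log₁₀
axis emphasizes early enrichment: in a prospective screen of millions of
molecules only the very top of the list is ever purchased and assayed.

## Worked example

```python
from screenopt import generate_dataset, run_pipeline

dataset = generate_dataset(n_pos=10, ratio=30, n_clusters=2, seed=7)
config = {
    "seed": 7,
    "parameters": {
        "electrostatic_thin_sphere_radius": {"low": 0.1, "high": 1.9, "n": 4},
        "desolvation_thin_sphere_radius": {"low": 0.1, "high": 1.9, "n": 4},
    },
    "search": {"mode": "beam", "n_steps": 3, "max_beam_width": 4},
    "matching_spheres_perturbation": {"radius": 0.4, "counts_per_step": [5, 10, 15]},
    "significance": {"null_reps": 50_000, "p_value": 0.01},
}
result = run_pipeline(config, dataset, "example_run")
```

prints (see `examples/05_optimize_pipeline.py`):

```
models evaluated: 228
best normalized LogAUC: 1.0000
best parameter bindings: {'desolvation_thin_sphere_radius': 0.7, 'electrostatic_thin_sphere_radius': 1.9}
Bonferroni-corrected threshold: 0.299 -> best model significant
```

228 docking models were built and scored; the best separates ligands from
decoys perfectly (criterion 1.0), and because 1.0 exceeds the 0.299
threshold — the (1 − 0.01/228) quantile of the random-classifier null for
10 positives at this class ratio — the enrichment cannot plausibly be a
fluke of having tested 228 models. `example_run/` then contains
`results.csv` (one row per model), `report.html` (threshold histogram,
linear–log ROC, per-parameter boxplots, pairwise max-criterion heatmaps,
score-by-charge violins, energy-term ridgelines), `best_retrodock_jobs/`
(top-k score tables + dockfiles) and `working/` (all candidates'
dockfiles).

The other scripts in `examples/` each demonstrate one capability:
dataset generation, the metric's boundary values, `.sph` file
perturbation, null-distribution thresholds, and cross-validation. A thin
CLI mirrors the library: `screenopt run|report|simulate-null|generate-dataset|crossval`.

## Layout

```
src/screenopt/      dataset, spheres, enrichment, nullstats, dag,
                    search, oracle, crossval, config, pipeline,
                    report, executor, cli
tests/              pytest suite (unit, property and end-to-end)
examples/           one narrative script per capability
docs/methods.md     models, assumptions, numerical choices, limitations
```
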