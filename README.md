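# stressfeat

Feature-engineering post-processing for finite-element (FE) bone stress
fields, built around a concrete question from animal biomechanics: when a
cat lands from different heights, **which paw bones' stress distributions
carry the information that distinguishes the landing patterns?**

Conventional FE post-processing compares stress heatmaps and maximum stress
values between conditions, which is fragile — extrema depend on mesh
smoothness and morphology, and the mass of unremarkable nodes hides the
real differences.  `stressfeat` instead treats each bone's full node-stress
distribution as a candidate *feature* and runs the whole recognition chain:

1. **GRF waveforms** — force-platform trials are contact-detected
   (vertical force > 10 N), zero-phase low-pass filtered (4th-order
   Butterworth, 50 Hz), resampled onto 101 points (0–100 % landing phase),
   and decomposed by PCA; each trial's rank-1 reconstruction
   `mean + score_1 · component_1` yields the *principal GRF* per axis.
2. **Stress structuring** — per bone, node stresses are ranked descending,
   binned into 30-range Pareto distributions, summarised into percentile
   bands (last 50/80/90/95 %, first 5 % of nodes), and restricted to top-k
   node subsets (all/2000/1000/500/200).
3. **Wrapper feature selection** — binary particle-swarm optimisation
   (w = 0.9, c1 = c2 = 2, 100 iterations, positions decoded by a 0.5
   threshold) searches bone subsets R ⊆ S minimising

   `fitness = α·E_R + (1 − α)·|R|/|S|`,  α = 0.9,

   where `E_R` is the hold-out error (fraction 0.2) of a KNN learner on the
   selected columns.  The reported selection is the consensus: the three
   bones selected most often across 20 seeded runs.
4. **Pattern recognition** — per-bone accuracies under stratified 10-fold
   cross-validation for three classifier families (KNN, RBF-SVM, small
   neural network), aggregated per node-subset case and per landing-height
   comparison.

No FE solver or animal data is required: a seeded synthetic generator
produces node-stress fields with the right structure (heavy-tailed
log-normal stresses where the top decile of nodes carries most of the
summed stress, planted multiplicative shifts in designated bones, two
landing conditions) and bell-shaped multi-axis GRF trials.  See
[docs/methods.md](docs/methods.md) for the model, calibrations and
limitations.

## Worked example

Plant a 1.5× high-stress-tail shift in bones MP4 and PP2 between two
landing conditions, build the top-200 feature matrix, and ask the selector
which bones recognise the landing pattern:

```python
from stressfeat import (
    StressSimSpec, gen_stress_field, build_feature_matrix,
    BpsoFeatureSelector, train_eval_cv, default_classifier_specs,
)
from stressfeat.stress import NodeSubsetSpec

spec = StressSimSpec(effect_map={"MP4": 1.5, "PP2": 1.5},
                     condition_labels=("0.8m", "1.0m"), seed=0)
fields_low, fields_high = gen_stress_field(spec)

fm = build_feature_matrix(fields_low, fields_high,
                          NodeSubsetSpec.from_case(200), summary="sampled", seed=0)
selector = BpsoFeatureSelector(n_seeds=20, random_state=0).fit(fm.X, fm.y)
print(list(selector.consensus_labels_))

knn = default_classifier_specs(0)[0]
for bone in ("MP4", "PP2", "MP1"):
    acc = train_eval_cv(fm.X[bone].to_numpy()[:, None], fm.y, knn,
                        folds=10, fold_seed=0)
    print(f"10-fold CV accuracy, {bone} alone: {acc:.3f}")
```

Output:

```
['MP4', 'PP2', 'DP2']
10-fold CV accuracy, MP4 alone: 0.735
10-fold CV accuracy, PP2 alone: 0.718
10-fold CV accuracy, MP1 alone: 0.487
```

The two planted bones top the 20-seed consensus (selected 20 and 14 times;
no unshifted bone exceeds 4) and classify the landing condition well above
the ~0.5 chance level of the unshifted MP1.

## Command line

The same chain is available as a CLI for shell use:

```bash
stressfeat run --seed 1 --out run/            # full demo pipeline
stressfeat simulate --seed 1 --out data/      # synthetic stress + GRF CSVs
stressfeat waveform --grf data/grf_raw_1.0m.csv --out wf/
stressfeat rank --stress data/stress_0.8m_vs_1.0m.csv --case 200 --out ranked/
stressfeat select --features run/features_0.8m_vs_1.0m_200.csv --out sel.json
stressfeat classify --features run/features_0.8m_vs_1.0m_200.csv --out acc.csv
stressfeat report --run run/ --out report.md
```

`run` executes: simulation → waveform PCA and event extraction → stress
structuring → 20-seed BPSO selection for every comparison × node-subset
case → cross-validated recognition report → manifest with per-stage seeds
and artifact checksums.  Reruns with the same seed are byte-identical.

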