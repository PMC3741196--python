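# tissuevote

Consensus prediction of **tissue-specific** and **2-selective** genes from
multiple expression datasets.

Drug-target and biomarker work routinely asks whether a gene is
preferentially expressed in one tissue (tissue-specific), in exactly two
(2-selective), or broadly (ubiquitous). Individual expression atlases and
individual detection statistics disagree on this question, so `tissuevote`
combines them at the interpretive level ("high-level integration"): each
detection method is applied to each dataset separately, the verdicts are
merged by rule-based voting and scoring, and every gene receives a final
category, tissue assignment, support band and coverage. The package is
aimed at computational biologists who have several tissue-panel expression
matrices (microarray, RNA-seq, or mixed) and want a single defensible call
per gene.

## Method

Three detectors classify one probe-set profile x = (x_1, ..., x_n) over n
tissues (log2 intensities):

- **ROKU-SPM** — the profile is robustly centred with a one-step Tukey
  biweight T(x), and the Shannon entropy
  H = −Σ_t p_t log2 p_t with p_t = |x_t − T(x)| / Σ|x − T(x)|
  gates specific vs ubiquitous (H ≤ h_max). An AIC-based one-sided outlier
  search locates up to two candidate tissues, which must be confirmed by the
  specificity measure SPM — the squared cosine between the (linear-scale)
  profile and the tissue indicator, SPM_i = x_i² / Σ_j x_j² — against the
  thresholds spm1 (single tissue) and spm2 (pair).
- **Decision function** — on the sorted profile x(1) ≥ … ≥ x(n), the gap
  g_k = x(k) − x(k+1), the specificity fraction sp_k = g_k / (x(1) − x(n))
  and the decision value d_k = g_k / sd(x(k+1..n)) must clear g_min, sp_min,
  d_min for k = 1 (specific) or k = 2 (2-selective).
- **Bayes factor** (replicated datasets only) — an encompassing-prior Bayes
  factor for the order constraint μ(1) > c·s(2..J) + max_{j≥2} μ(j)
  (specific; the analogous constraint on μ(1), μ(2) for 2-selective), where
  s(2..J) is the between-tissue standard deviation of the remaining sample
  means and c a margin constant. BF = (posterior fraction of draws
  satisfying the constraint) / (prior fraction); thresholds bf1, bf2 are
  calibrated by simulation to a target null call rate.

Per probe set, the 2–3 method calls are merged by a **consensus vote**
(an unordered rule table: e.g. {T, T, Uq} → T; {T, (T,S), Uq} → T;
{(T,S), (T,S), Uq} → (T,S); a minority informative call loses to the
ubiquitous majority). Per gene and dataset, the **inner score** merges probe
sets: ubiquitous probe sets are dropped when at least half of the probe sets
agree on a tissue (Rule 1); a tissue/pair reaching the 50% homogeneity bar
scores 1 (specific) or 0.5 + 0.5 (pair) (Rule 2), otherwise per-tissue
contributions are averaged. The **total score** S_total ∈ [0, 1] averages
the inner scores over the datasets in which the gene is represented;
**coverage** reports "present out of total" datasets. Support bands:
specific genes — strong (S = 1), high (0.75 ≤ S < 1), medium-high
(0.5 < S < 0.75), medium (S = 0.5); 2-selective — strong (S = 0.5),
medium-high (0.3 ≤ S < 0.5).

Detector thresholds θ are fitted per dataset by minimising the training
penalty Σ_g s(g), with s = |τ − 1| for annotated specific genes and s = τ
for annotated ubiquitous genes (τ = number of tissues called), over a
parameter grid — a `Model.fit()` returning a `Results` object.

## Worked example

The gene GRHPR is measured by three probe sets in GNF1H, GeAZr and GSE7307
and one in GDS3113. Its per-dataset consensus calls ship as a fixture:

```python
from tissuevote import (generate_worked_example, inner_score, total_score,
                        dataset_call, final_call)

calls, n_datasets = generate_worked_example("GRHPR")
inner = {ds: inner_score(c, "GRHPR", ds) for ds, c in calls.items()}
for ds, ts in inner.items():
    print(ds, ts.scores)
total, coverage = total_score(inner, {ds: True for ds in calls}, "GRHPR")
result = final_call("GRHPR", {ds: dataset_call(c) for ds, c in calls.items()},
                    total, coverage)
print(total.scores)
print(result.category.value, result.tissues, result.score, result.support)
```

prints

```
GNF1H {'Liver': 0.5, 'Lymph': 0.5}
GeAZr {'Liver': 1.0}
GSE7307 {'Liver': 0.75, 'Kidney': 0.25}
GDS3113 {}
{'Liver': 0.5625, 'Lymph': 0.125, 'Kidney': 0.0625}
SPECIFIC ('Liver',) 0.5625 medium-high
```

GNF1H's two concordant 2-selective probe sets give Liver and Lymph 0.5 each
(the ubiquitous probe set is non-informative); GeAZr's three Liver-specific
probe sets give Liver 1; GSE7307's split evidence averages to 0.75/0.25;
GDS3113 contributes 0. The total score 0.5625 = (0.5 + 1 + 0.75 + 0)/4
places GRHPR in the medium-high band, Liver-specific, coverage 4 of 4.

A full synthetic study runs through the model interface:

```python
from tissuevote import (StudyConfig, generate_study, training_set_from_truth,
                        TissueSpecificityModel)

study = generate_study(StudyConfig(seed=0))           # 4 datasets, 500 genes
training = training_set_from_truth(study.truth, 20, 10, seed=0)
model = TissueSpecificityModel(study.datasets, study.probe_maps,
                               training_set=training)
results = model.fit(seed=0)                           # grid-search thresholds
print(results.summary())                              # params, bands, coverage
frame = results.predict_frame()                       # one row per gene
```

On this study the fitted pipeline recovers 96.9% of the planted specific
genes (218/225) at support ≥ medium with 0.5% (1/200) of planted ubiquitous
genes called specific.

The same stages are available from the shell:

```bash
tissuevote simulate --out study --seed 0
tissuevote detect   --config study/study.yaml --out study/calls --seed 0
tissuevote score    --config study/study.yaml --calls study/calls --out study/scores
tissuevote train    --config study/study.yaml --training training.tsv --out study/params
tissuevote evaluate --config study/study.yaml --training a.tsv --training b.tsv --out agreement.tsv
```

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices and known limitations.
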