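# gpclusters

Consensus clustering of English GP practices into models of care from
practice-level appointment data.

English general practices organise their appointment books very
differently: some favour pre-booked, face-to-face appointments delivered
by a mix of staff ("routine care"), others fulfil demand on the day by
telephone with a GP ("same-day care"). `gpclusters` identifies these
models from monthly practice-level appointment count tables of the kind
NHS England publishes (counts by healthcare-professional type,
consultation mode, wait-time band and national appointment category),
for health-services researchers and analysts who want a reproducible,
tested version of that analysis — plus a synthetic-data generator so the
whole pipeline can be exercised without the real extract.

## What it does

1. **Ingest & clean** — validate the appointment and registry tables and
   apply a staged quality filter: practices with fewer than 1000 patients
   or outlying appointment rates, then practices with >10% of
   appointments unmapped to a standard national category, then practices
   with <50% of appointments carrying a care-model annotation. Each
   practice is attributed to the first stage it fails, so the counts
   partition the input (the shape of an inclusion flow diagram).
2. **Annotate** — map national appointment categories to
   `{same_day, routine, triage, unknown}` with a user-supplied dictionary.
3. **Measures** — derive 12 appointment-system measures per
   practice-month (GP share, telephone share, booked >1 week ahead,
   same-day GP share, annotated same-day/routine shares, routine care
   delivered within a day, monthly triage use 0/1, appointments per 1000
   patients, …), average over the analysis window, min-max scale to
   [0, 1].
4. **Cluster** — ensemble consensus clustering: five base methods
   (Lloyd k-means, Ward agglomerative, a hierarchically clustered
   self-organising map, partitioning around medoids, Gaussian mixtures
   with BIC model selection), each repeated on random 80% subsamples of
   practices; runs are label-aligned to a reference and combined by
   majority vote. Stability is summarised by the mean pairwise adjusted
   Rand index (ARI) over run pairs,

   ARI = (Σᵢⱼ C(nᵢⱼ,2) − E) / (½[Σᵢ C(aᵢ,2) + Σⱼ C(bⱼ,2)] − E),
   E = Σᵢ C(aᵢ,2) Σⱼ C(bⱼ,2) / C(n,2),

   on each pair's shared practices.
5. **Validate** — prepare a held-out month identically, assign its
   vectors to the trained consensus (or re-cluster from scratch), match
   cluster labels by optimal assignment and report the proportion of
   practices keeping their cluster.
6. **Describe** — per-cluster tables of measures, sociodemographics and
   workforce full-time equivalents, in the style of published practice
   characteristics tables.

The synthetic generator (`gpclusters.synthdata`) draws practices from a
two-component mixture whose per-cluster measure means/SDs, mixture
weight, list-size distribution and covariates follow the published
two-cluster characterisation, inverts the measure definitions into count
tables (round-trip accurate to 0.02), and can inject quality defects
matching each cleaning rule.

## Worked example

```python
from gpclusters import (
    SyntheticConfig, generate_dataset, annotate_counts, filter_practices,
    compute_measures_table, average_window, scale_matrix, ConsensusClustering,
)

cfg = SyntheticConfig(n_practices=600, master_seed=1)
bundle = generate_dataset(cfg)

ann = annotate_counts(bundle.appointments, bundle.annotation_dictionary)
registry = bundle.registry.set_index("practice_id", drop=False)
included, report = filter_practices(
    ann, registry, list(cfg.months),
    standard_categories=bundle.standard_categories,
)
vectors = average_window(
    compute_measures_table(ann[ann.practice_id.isin(included)], registry, list(cfg.months))
)
scaled = scale_matrix(vectors)

model = ConsensusClustering.from_dataframe(scaled.values, k=2, reps_per_method=20)
result = model.fit(master_seed=1)
print(result.summary())
```

prints

```
Consensus clustering results
============================================
items                600
clusters (k)         2
methods              kmeans_lloyd, hierarchical_ward, hsom, pam, gmm_bic
runs                 100 (20 reps x 5 methods)
subsample fraction   0.80
mean pairwise ARI    0.8661
--------------------------------------------
cluster 0: n=402 (67.0%), mean vote share 0.976
cluster 1: n=198 (33.0%), mean vote share 0.979
--------------------------------------------
within-method ARI kmeans_lloyd       0.9966
within-method ARI hierarchical_ward  0.8794
within-method ARI hsom               0.8465
within-method ARI pam                0.8959
within-method ARI gmm_bic            0.9586
```

Two clusters emerge with roughly a third of practices in the smaller,
same-day-oriented group (cluster 1); the mean pairwise ARI of 0.87 says
the hundred subsampled runs agreed strongly on that partition, and the
vote shares near 1 say almost every practice was placed consistently.
`result.to_frame()` gives per-practice labels and vote shares;
`summarise_clusters(...)` then tabulates what distinguishes the groups.

A command-line interface wraps the same pipeline:

```
gpclusters simulate --out demo --n 600 --seed 1
gpclusters all --config demo/pipeline.yaml
```

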