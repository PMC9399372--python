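# radiosig

Discovery pipeline for **radiosensitivity gene signatures** from
post-irradiation time-course expression and per-cell-line SF2 survival
fractions, aimed at computational biologists studying radiotherapy response.
The package chains five analysis stages into one reproducible funnel and
ships a synthetic-data generator that plants ground-truth signature genes, so
every stage — and the pipeline end to end — is verifiable without any
external download.

## The method

Cellular radiosensitivity is summarized by **SF2**, the surviving fraction
after a 2 Gy dose (SF2 ∈ (0, 1]; lower = more sensitive). The funnel is:

1. **Time-response filter.** Genes varying across post-irradiation
   timepoints (0, 2, 4, 8, 12, 24 h) by one-way ANOVA (p < 0.05, cell lines
   as replicates).
2. **Temporal profile clustering.** Short time-series clustering against a
   library of unit-change model profiles (|change| ≤ c per interval,
   (2c+1)^(T−1) candidates, flat excluded, m maximally separated
   representatives). Cluster sizes are referred to a permutation null with
   Benjamini–Hochberg control across profiles (significant at q < 0.01).
3. **Cluster eigengene screen.** Each significant cluster is summarized by
   the first principal component of its member × cell-line submatrix (the
   eigengene, sign-oriented); clusters with |Spearman ρ| > 0.1 against SF2
   survive.
4. **Single-gene fail-both filter.** Each candidate is scored by a
   regression random forest (out-of-bag permutation importance for SF2
   prediction) and by the **single-gene linear-quadratic (SGLQ)** model

       SF = e^(α·E_i − β·E_i²)

   the per-gene analogue of the classical LQ dose–response law
   SF = e^(−αD−βD²), fit as a no-intercept OLS of ln SF2 on (E, E²). A gene
   is excluded only when it fails both routes.
5. **Multi-omics hub screen.** A 4-layer network — HotNet2-style
   random-walk-with-restart heat diffusion over mutation and copy-number
   heats, a TOM/WGCNA-style co-expression layer, and a confidence-filtered
   protein-interaction layer — is unioned, and a gene is called a **hub**
   when its degree, betweenness and (harmonic) closeness are all strictly
   above the network medians. Final candidates are the retained genes that
   are hubs, annotated by hypergeometric over-representation.

See `docs/methods.md` for model assumptions, parameter defaults and
limitations.

## Worked example

```python
import radiosig as rs

cfg = rs.SimulationConfig()          # 2,000 genes, 20 planted, 16 lines, seed 20220810
bundle, truth = rs.simulate_bundle(cfg)
report = rs.run_pipeline(bundle)
print(rs.funnel_summary(report).to_string(index=False))
print(report.truth_metrics)
```

prints

```
             stage  n_in  n_out  pct_retained  pct_excluded
             anova  2000    103           5.2          94.8
  profile_clusters   103     22          21.4          78.6
sf2_cluster_screen    22     22         100.0           0.0
  fail_both_filter    22     20          90.9           9.1
        hub_screen    20     18          90.0          10.0
{'n_candidates': 18, 'n_planted': 20, 'true_positives': 18,
 'precision': 1.0, 'recall': 0.9}
```

Reading the funnel: 103 of 2,000 genes are time-responsive (the 5.2% is the
20 planted genes plus the expected ~5% ANOVA false positives), two temporal
clusters reach q < 0.01 and both track SF2, the fail-both filter removes two
stragglers, and 18 of the 20 planted genes end up as network hubs
(precision 1.0, recall 0.9). The planted-signature gene set is the top
over-representation hit at p ≈ 5×10⁻⁴².

The same run from a shell:

```bash
radiosig simulate --out bundle/
radiosig run --bundle bundle/ --out results/
radiosig stage anova --bundle bundle/ --out anova.tsv   # single stages
```

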