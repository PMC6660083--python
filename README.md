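# metsig

Case-control discovery for targeted serum metabolomics: control-referenced
Z-scoring, PLS-DA/VIP metabolite selection, pathway "metabolic impact"
ranking, validated sparse diagnostic panels, differential
correlation-network coupling, and a per-subject partition of metabolic
abnormalities — packaged as a reusable, tested pipeline with a synthetic
cohort generator so every stage can be exercised and calibrated without
access to a clinical dataset.

The motivating setting is a small case-control study (for example 20
affected veterans vs 20 healthy controls, 358 metabolites across 46
biochemical pathways) in which no single metabolite is decisive but a
*pattern* of pathway disturbances — raised ceramides, sphingomyelins and
phosphatidylcholines, lowered purines and endocannabinoids — forms a
usable biosignature.

## The methods at the core

**Z-scores.** Intensities are log-transformed and every sample is scaled
per metabolite by the control group's statistics:
`z = (x − x̄_control) / SD_control`, so a case's value is expressed in
control standard deviations.

**PLS-DA and VIP.** A NIPALS PLS1 regression of the centered case
indicator on the Z-score matrix yields, per component *a*, a unit weight
vector `w_a`, scores `t_a`, and explained response variance `SSY_a`.
Variable importance in projection follows Wold:

    VIP_j = sqrt( p · Σ_a SSY_a w_ja² / Σ_a SSY_a )

with `p` metabolites, so mean squared VIP is exactly 1. A metabolite is
*significant* when `VIP > 1.5` **and** its two-sided Mann-Whitney U
p-value is ≤ 0.05.

**Pathway impact.** The top-30 significant metabolites by VIP are mapped
to pathways. Per pathway: expected hits `= (N_pathway/N_total)·30`, fold
enrichment `= observed/expected`, impact `= Σ VIP` of its hits, and the
impact fraction of the total.

**Panels.** 1–6-metabolite classifiers are grown greedily and scored by a
seeded random forest: out-of-bag AUROC with a bootstrap 95% CI, a 2×2
table at the Youden-J operating point, repeated double cross-validation
(100 stratified 2/3-in / 1/3-out resamples, model refit per split), and
an empirical permutation p-value with the (b+1)/(B+1) convention.

**Networks.** All m(m−1)/2 metabolite pairs are correlated (Spearman on
Z-scores) within each group; pairs with BH FDR < 0.05 count as coupled,
and the case/control coupling contrast is a ratio plus a two-sided Fisher
exact test. Networks export to d3 force-layout JSON and GraphML at the
display threshold Pearson r ≥ 0.85.

**Abnormality partition.** Per subject, each |Z| ≥ 2 metabolite is
*diagnostic* if the cohort screen selected it (VIP ≥ 1.5) in the same
direction, else *individualized*.

## Worked example

```python
import metsig as ms

config = ms.CohortConfig(seed=42)          # 20 v 20, 358 metabolites
cohort, truth = ms.generate_cohort(config)
z = ms.zscore_against_controls(ms.log_transform(cohort))
screen = ms.screen_metabolites(z, ms.fit_plsda(z))
print(screen.n_significant)                # -> 30
table = ms.build_impact_table(screen, config.catalog, k=30)
print(table.iloc[0][["pathway", "observed_hits", "fold_enrichment"]])
# pathway ceramide, 11 hits, fold enrichment 4.2
```

Running `python examples/01_screen_metabolites.py` prints the screen:
30 metabolites pass the joint rule, the top of the VIP ranking is
dominated by planted ceramides (e.g. `cer_04`, VIP 2.75, U p < 1e-4,
direction up), and 18 of the 30 carry a planted shift — the others are
the small-sample false discoveries such a design genuinely produces.
`examples/03_diagnostic_panels.py` then grows panels (a 3-metabolite
panel reaches AUROC 0.93, rdCV 0.95, permutation p 0.005), and
`examples/04_correlation_network.py` recovers the planted excess coupling
(case network denser than control at FDR < 0.05). The remaining examples
cover pathway tables, the abnormality partition and the end-to-end run.

A thin CLI mirrors the stages:

```sh
metsig simulate --seed 1 --out-dir sim
metsig discover --matrix sim/cohort.csv --annotation sim/annotation.csv
metsig run-all --simulate --seed 1 --out-dir run
```

Input format: a CSV with columns `sample_id, group, <metabolite...>`
(`group` ∈ {case, control}) plus an annotation CSV
`metabolite_id,pathway`.

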