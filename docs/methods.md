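# Methods

This note documents the models and procedures implemented in `metsig`,
the defaults and why they were chosen, what the synthetic cohorts do and
do not emulate, and the numerical conventions that pin down every
result.

## Preprocessing and the Z-score scale

All analysis runs on control-referenced Z-scores. Intensities are
natural-log transformed (a pseudocount of 1 is applied only when zeros
are present), then every sample — cases *and* controls — is scaled per
metabolite by the control group's mean and sample SD (n−1 denominator).
Log first, Z-scores second: the order matters only for skewed raw
scales, and log-normal serum intensities make the log scale the natural
place to express shifts. Metabolites with zero control SD are dropped
with a warning, as are metabolites missing in more than 20% of samples
(mirroring a design in which only metabolites measurable in every sample
are analysed); remaining missing values are excluded pairwise.

A consequence worth remembering at n = 20 controls: the Z-scores of an
independent sample are not standard normal but t-inflated —
`(x − x̄)/s · sqrt(n/(n+1)) ~ t_{n−1}` — so the chance rate of |Z| ≥ 2
is about 0.066 per metabolite, not the Gaussian 0.0455. The abnormality
partition tests use the exact t form.

## PLS-DA, VIP, and the selection rule

The discriminant model is a NIPALS PLS1 against the centered 0/1 case
indicator with column-centered X, sequential components and deflation of
both X and y. Default 2 components (the scores plane used for visual
separation); VIPs are computed over all fitted components with the
standard Wold formula, which guarantees Σ VIP² = p. The selection rule is
the conjunction VIP > 1.5 and two-sided Mann-Whitney p ≤ 0.05; direction
is the sign of the mean case Z. Rankings break ties by VIP desc, then p
asc, then metabolite ID. A two-group design makes Fisher's-LSD post hoc
machinery inert, so none is implemented.

The Mann-Whitney test uses the exact null distribution when the combined
sample size is ≤ 20 without ties, else the tie-corrected normal
approximation with continuity correction. At the default cohort size
(20 v 20) the approximation branch is in force, which is also what any
standard tool would do there.

## Pathway impact

Expected hits, fold enrichment and summed-VIP impact are computed at
full precision; *display* tables round half-up to 1 decimal (whole
percents for impact fractions), matching how such tables are printed.
Impact fractions normalise over pathways with ≥ 1 hit; zero-hit pathways
are omitted from the report but available via `include_empty`. The
selection takes the k = 30 top significant metabolites by VIP; when
fewer are significant, all of them are used with a warning. No
enrichment p-value is attached — the statistic of interest here is the
fold enrichment and the VIP mass, not a hypergeometric test.

## Diagnostic panels

Panels are scored by seeded random forests (sqrt-features splits).
Apparent performance uses **out-of-bag** class probabilities:
resubstitution probabilities of a forest essentially reproduce the
labels and would report AUROC ≈ 1 on pure noise. The AUROC CI is a
100-resample bootstrap percentile interval over the (score, label)
pairs. The 2×2 table is taken at the Youden-J point of the OOB ROC.

Validation is repeated double cross-validation — 100 stratified
2/3-in / 1/3-out random splits, forest refit per split, mean held-out
AUROC — and a label-permutation p-value `(1 + #{perm ≥ obs}) / (B + 1)`
with B = 1000 by default. The permutation statistic defaults to the OOB
AUROC; a model-free alternative (AUROC of the panel's mean Z) exists for
large calibration studies, where refitting B forests per replicate would
dominate the cost; the permutation machinery is identical for any
statistic. Greedy forward selection maximises the rdCV score at each
step over a candidate pool (default 12 top-VIP metabolites) and is not
exhaustive — other panels may perform equally well.

Forest sizes: 200 trees for the single apparent model, 50 inside
resampling loops, and 30 rdCV splits while scoring greedy candidates
(the final panel of each size is always re-scored at the full split
count). These sizes keep a full 1–6 panel growth at interactive speed;
all are configurable in `PanelConfig`.

Sample-size planning uses the normal-approximation two-group formula
`n = 2(z_{1−α/2} + z_{power})²/d²` per group with an optional additive
inflation of one subject per group per model predictor. Conventions for
"n for selecting k predictors in a multiple regression" vary across
tools and are rarely reported precisely, so the function states its
convention in its output rather than claiming to match any particular
published figure.

## Correlation networks

Within each group, all m(m−1)/2 pairs get Pearson r and Spearman ρ on
the Z-scores; Spearman p-values use the t approximation, and BH FDR and
Storey q are computed within the group over all pairs (not pooled across
groups). Edge significance is Spearman FDR < 0.05; Pearson r is carried
for the display threshold (signed r ≥ 0.85 by default, |r| mode behind a
flag, because captions of published first-neighbour figures are
ambiguous between the two). Exports are d3 force-layout JSON (nodes
carry their pathway as `group`; links carry weight and sign) and
GraphML; isolated nodes are dropped.

The Storey π0 estimate smooths `π̂0(λ) = #{p>λ}/(m(1−λ))` over
λ ∈ {0.05, …, 0.95} with a precision-weighted (w = √(1−λ)) least-squares
cubic evaluated at the largest λ, clipped to (0, 1]. An *interpolating*
spline would return the raw λ = 0.95 tail estimate unchanged (SD ≈ 0.14
at m = 1000), which is why a genuine smoother is used; on uniform
p-values the estimator averages 0.96 with ~92% of seeds in [0.85, 1].

## The synthetic cohort generator

The generator defines the study conditions: 20 cases vs 20 controls and
a 358-metabolite catalog in 46 pathways with the named pathway sizes
(ceramides 31, phospholipids 56, sphingomyelins 36, purines 18,
pyrimidines 9, endocannabinoids 4, eicosanoids 7, branched-chain amino
acids 8; the remaining 189 metabolites fill 38 null pathways of ~5).

Control log-intensities follow a one-factor-per-block Gaussian with
exchangeable correlation ρ_within = 0.5 inside pathways and
ρ_between = 0.05 elsewhere (positive semi-definite by construction for
0 ≤ ρ_b ≤ ρ_w < 1), scaled by per-metabolite log-means U(2, 8) and
log-SDs U(0.2, 0.8) and exponentiated. Raw-intensity distributions are
not reported for such panels; log-normality is an assumption and is
recorded in the truth file. The correlation levels are a choice —
within-class correlations of serum lipid panels typically sit in this
range — also recorded per run.

Case shifts are planted on the log scale in units of the control log-SD,
so they are exactly the Z-shifts downstream stages should recover. The
default effect table encodes the studied per-pathway directions and
magnitudes: ceramides +0.80 on 11/31 members, phosphatidylcholines +0.78
on 4/56 and one phospholipid −0.66, sphingomyelins +0.75 on 4/36,
purines −0.70 on 4/18, pyrimidines +0.89 and −0.88 on one member each,
endocannabinoids −0.84/−0.60, one eicosanoid −0.84, one branched-chain
amino acid +0.64. Tighter case coupling is implemented by shrinking
case-specific idiosyncratic noise within blocks —
`ρ_w,case = 1 − (1 − ρ_w)/c²` — which preserves unit variances and
positive semi-definiteness; c = 1.5 is the studied condition for
differential-coupling analyses (c = 1 default otherwise).

**What the generator does not emulate.** Real metabolome correlation is
not exchangeable within curated pathway blocks: its spectrum is more
diffuse, cross-pathway biology (e.g. sphingomyelin→ceramide flux)
creates off-block structure, and measured panels include strongly
redundant near-duplicate species with r > 0.9 even at small n. Two
consequences for interpreting passing tests: (i) a real control network
shows hundreds of FDR-significant pairs at n = 20 while the simulated
control network at ρ_w = 0.5 shows very few (Spearman ρ ≈ 0.5 does not
survive BH across 63,903 tests), so simulated coupling ratios are more
extreme and more variable than real ones — the direction, not the
magnitude, is the calibrated quantity; (ii) instrument-level effects
(retention-time drift, ion suppression, batch) are out of scope
entirely. Passing tests demonstrate that the *procedures* recover
planted structure under honest sampling noise, not that any particular
clinical dataset would reproduce.

**A power limit worth stating.** Under the study conditions a planted
0.8-SD shift gives the per-metabolite U-test only ≈ 65% power at
p ≤ 0.05, so pathway-level impact rankings are noisy: the
largest-planted pathway (ceramides) attains rank 1 by impact in about
two-thirds of seeds, with large null-rich pathways occasionally
overtaking it through correlated false discoveries. This is a property
of the 20 v 20 design itself and is the quantitative reason a
single-cohort pathway ranking needs replication before being treated as
stable.

## Reproducibility conventions

One global seed fans out to fixed per-stage offsets, so stages can be
rerun in isolation; every run manifest records the seed and all
thresholds actually applied (VIP 1.5, p 0.05, FDR 0.05, Z-cut 2.0,
top-k 30, display r 0.85, resampling sizes). Intermediates are stored at
full precision; rounding happens only at report rendering. The
consolidated acceptance run uses reduced resampling (50 rdCV splits, 200
permutations, candidate pool 10) as the package's default consolidated
problem size; full-size resampling remains available through
`PanelConfig`/`RunConfig`.

## Known limitations

- Greedy panel growth has no optimality guarantee and its rdCV sequence
  is not strictly monotone.
- Storey's π0 is noisy below m ≈ 100 p-values; the implementation
  refuses fewer than 10.
- The Wilson intervals on sensitivity/specificity are one convention
  among several; published tables rarely state theirs.
- The exchangeable block model concentrates within-pathway correlation
  in a single factor, which maximises group-mean sampling noise for a
  given ρ; richer factor structures would change pathway-ranking
  stability at the same average correlation.
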