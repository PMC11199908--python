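# Methods

`toxconcord` analyzes probe-level expression counts from concentration-
response studies in primary hepatocytes, of the kind produced by targeted
probe-based sequencing assays (TempO-Seq-like), and asks a mode-of-action
question: does a test chemical's transcriptomic response look like that of
a reference receptor agonist, and does that response depend on the
receptor?  The package bundles a synthetic study generator with the full
analysis chain — sample QC, differential expression, gene-set
overrepresentation, targeted ToxPi-style aggregation, and benchmark-
concentration (BMC) modeling — so every claim the analysis makes can be
tested against planted truth.

## The emulated study

The generator's default design mirrors a two-genotype (wild-type vs
PPARα-knockout) mouse hepatocyte experiment: five chemicals — a test PFAS
surfactant (HFPO-DA), a PPARα agonist (GW7647), a PPARγ agonist
(rosiglitazone), and two cytotoxicants (acetaminophen, d-galactosamine) —
each at four concentrations plus vehicle controls (water for HFPO-DA,
DMSO for the rest), exposed for 12, 24 or 72 h with 3/4/3 replicate
wells.  That is 440 wells per study.  The default transcriptome is 2,000
genes measured by 1–3 probes each (~2,600 probes), a desk-scale stand-in
for a ~20k-gene, ~30k-probe assay; the `tiny` preset keeps the full
design with 300 genes.

### Count model

Counts are negative binomial with mean/dispersion parameterization,
Var = μ + α μ²:

    count_ij ~ NB( mean = s_j · b_i · 2^Δ(cell_j, gene_i), α_gene )

where `s_j` is a per-well depth factor (log-normal, σ = 0.2; planted
low-quality wells are scaled ×0.02), `b_i` a probe baseline (gene
baseline log-normal around 150 counts × probe wobble), and `α` per-gene
log-normal around 0.05 (σ = 0.5).  The dispersion range is a modeling
choice, not an estimate from any deposited dataset; it is in the range
routinely reported for bulk count assays.

### Planted effects

Genes belong to modules: `ppara` (12%), `pparg` (8%), `cytotox` (10%),
`null` (the rest).  A chemical perturbs only its target module's genes,
with a Hill-shaped log2 effect

    Δ(c) = L · c^h / (EC50^h + c^h),   t ≥ onset;   Δ = 0 before onset

with maximal log2 fold change L ~ U(1,3) (85% induced, 15% repressed),
h ~ U(1,2), and EC50 = (chemical anchor) × (gene potency factor,
log-normal σ = 0.3).  Anchors place the response inside each chemical's
ladder (e.g. 5 µM for HFPO-DA, 0.2 µM for GW7647, ~4 mM for the
cytotoxicants).  Two genotype-dependent features are planted for the
PPARα module only: the knockout multiplies its EC50 by the shift factor
(default 10) and delays its onset from 12 h to 24 h.  These are the
synthetic analogues of a receptor-dependent potency shift and temporal
delay; recovering them end-to-end is what the acceptance checks measure.

What the generator does **not** emulate: batch or plate effects, probe
cross-hybridization, compensatory regulatory feedback (the delay is a
hard onset switch, not kinetics), cytotoxic RNA degradation, and
correlated gene-gene noise.  Passing the recovery tests therefore shows
the pipeline is correct and well calibrated under its stated model, not
that it is robust to all the structure of real data.

## Sample QC

Two rules, each computed within genotype in a single pass (thresholds are
not recomputed after exclusions): a sample is excluded when its total
read count, or its number of detected probes (≥1 read), falls strictly
below mean − 2·SD of its genotype cohort.  SD uses the n−1 denominator.
"Probes detected" is interpreted as probes with at least one read — the
count table offers nothing deeper for that rule.  After exclusion, any
(genotype, chemical, concentration, timepoint) cell with fewer than 2
surviving wells is dropped from differential expression.

## Differential expression

Size factors are median-of-ratios, computed within genotype and rescaled
to geometric mean 1.  Each treatment cell is tested against its
vehicle-matched control (same genotype, timepoint, vehicle) with a
negative-binomial GLM (log link) per probe.  Small-sample calibration is
the delicate part at 3–4 wells per arm; the test statistic is moderated
in the quasi-likelihood style:

1. a mean-dispersion trend α(μ) is estimated across probes by binned
   method of moments on normalized counts;
2. group means are fitted by Newton iteration under the trended α, giving
   the Wald statistic for the log fold change;
3. per-probe departure from the trend is captured by a quasi-dispersion
   s² = Pearson-X²/df and squeezed toward a moment-matched scaled-F prior
   (prior df d₀ estimated from the s² distribution on the log scale);
4. the moderated statistic Wald/√(s²_post) is referred to t(d₀ + df).

On all-null simulations this keeps p-values uniform (KS) and the type-I
rate at nominal at n = 3–4 per arm, where an unmoderated Wald z is
visibly anti-conservative.  Probes with all-zero counts are excluded from
testing and from the BH multiplicity count.  DEPs are probes with BH
adjusted p < 0.10; a gene is a DEG when any of its probes is a DEP, with
the representative probe chosen by smallest adjusted p, then larger
|log2FC|, then probe id.  No independent filtering or fold-change
shrinkage is applied.

## Gene-set overrepresentation

Per contrast and direction (up/down separately), the DEGs are tested for
overrepresentation in each gene set by the upper-tail hypergeometric
P(X ≥ k) with universe N = genes with ≥1 tested probe in that contrast.
BH adjustment runs across sets within one (contrast, direction); sets
are significant at adjusted p < 0.05.  Sets are intersected with the
universe first and dropped below 3 genes; the BMC stage deliberately
applies no such size filter (see below), and the difference is
intentional.

## Targeted aggregation (ToxPi profiles)

The targeted analysis scores how strongly the gene sets containing each
chemical's top interacting genes (a 10-gene list per chemical, supplied
as a file or generated from the planted modules) respond:

* **reverse-log scaling** — over all treatment groups of one genotype
  (upregulated direction), nonsignificant sets score 0 and significant
  sets score −log10(padj)/−log10(padj_min), so the globally most
  significant set scores 1.  Adjusted p-values are clipped at 1e-300.
  The scope of the "=1" anchor is global per genotype by default; a
  per-timepoint scope is available as a config knob.
* **aggregation** — per treatment group, the scores of significant sets
  containing an interacting gene are summed per gene (a set containing
  two interacting genes contributes fully to both).
* **scaling** — *internal*: each group's vector divided by its own max;
  *external*: each gene's slice divided by that gene's max across all
  groups and timepoints within the genotype.  All-zero vectors stay zero
  (an "empty ToxPi").  Both scalings are idempotent and preserve the
  within-group ranking of slices.

Only upregulated enrichment is aggregated by default.  Profile
concordance is summarized by PCA on the profile vectors, pairwise
Euclidean distances, and per-chemical covariance ellipses.

## Benchmark concentrations

Per (genotype, chemical, timepoint), probes passing a one-way ANOVA
prefilter (p < 0.05 on log2(normalized count + 1) across concentration
groups) are fitted against concentration with five least-squares
families on group-mean responses: linear, quadratic, power (exponent
0.1–4), Hill (free coefficient 0.5–8), and a saturating exponential.
Group means are weighted by pooled-SD/√n (constant variance on the log2
scale); the winner is the lowest-AIC converged fit (AIC = χ² + 2k;
ties → fewer parameters, then a fixed family order), and the fit p-value
is the residual χ² tail.

The BMC solves |f(c) − f(0)| = BMR with BMR = bmr_factor × control SD
(default factor 1.0 on the log2 scale; 1.349 selectable).  The pooled
within-group SD stands in for the control SD — at 3–4 wells a single
group's SD estimate is too noisy to define a stable BMR.  The crossing
is searched from lowest_conc/10⁴ up to the highest tested concentration;
no crossing flags the probe above-range.  BMCL/BMCU are 95% bounds from
a delta-method interval on log BMC (numerical gradient of the BMC
against the parameter covariance of the weighted fit), with a seeded
parametric bootstrap (250 draws) as fallback when the covariance is
unusable.  Profile-likelihood bounds were considered and set aside: with
five dose groups the delta interval is adequate for the ratio filters it
feeds, at a small fraction of the cost.

Retention requires all of: winning fit p ≥ 0.1; lowest_conc/10 ≤ BMC ≤
highest_conc; BMC/BMCL ≤ 20; BMCU/BMC ≤ 20; BMCU/BMCL ≤ 40.  Each
removed probe records the specific rule(s) it failed.  Gene-level best
BMC is the minimum retained probe BMC.  Pathway summaries report, per
gene set, Fisher's exact two-tailed enrichment of responsive genes
(significant below 0.1) and median BMC/BMCL/BMCU over responsive member
genes, with no minimum/maximum set-size filter.  Accumulation curves are
sorted values against cumulative count.

### Known estimation behavior

Two properties of desk-scale BMC estimation are worth stating plainly.
First, when a planted BMC falls below the lowest tested concentration
the estimate is an extrapolation and its error grows; the >10-fold-
below-range filter exists precisely to remove those probes, and the
parameter-recovery check is therefore run in the regime the filters keep
(planted EC50s inside the tested ladder).  Second, a fixed dose ladder
samples a potency-shifted curve at a different relative position: with a
10× EC50 shift the knockout's toe is better sampled than the wild
type's, and parsimony-selected models interpolate the unsampled wild-
type toe slightly too steeply.  The measured effect is a ~×1.2 upward
bias in the KO/WT median-BMC ratio (true value 10, typical estimates
10–13), well inside the recovery band and of the same kind that any
fixed-ladder benchmark-dose analysis carries.

## Sample-level overviews

PCA and average-linkage hierarchical clustering run on log2 normalized
counts of the top-500 variable probes (a config knob; the choice of a
variance filter is a standard default, not derived from any particular
dataset).

## Determinism and problem sizes

All randomness flows through integer seeds (`numpy` `SeedSequence`
children per stage); identical config + seed reproduce every output TSV
byte-for-byte, and the run manifest records SHA-256 digests to verify
it.  The recovery experiments run at reduced sizes chosen so Monte-Carlo
error does not dominate the quantity under test: null calibration at
5,000 probes; Hill recovery at 200 probes with 4 replicate wells per
group and σ = 0.1; the genotype-shift experiment at 400 genes (~48
marker genes in the median); the delay and concordance experiments at
300 genes.  These sizes are the package's own choices for desk-scale
verification.

## Limitations

* The DE engine is a self-contained re-implementation; it aims for
  correct calibration and planted-truth recovery, not numeric parity
  with any specific established package.
* The interaction map is an input (or generated from planted modules);
  no live database querying is performed, and the generated map is a
  synthetic stand-in, not curated interaction data.
* Upstream-regulator inference over a causal knowledge base is out of
  scope.
* Only the hypergeometric overrepresentation statistic is implemented
  for gene-set testing; rank-based (GSEA-style) and combined-probability
  variants are not.
* The BMC model family is a compact stand-in for the full suites of
  dedicated benchmark-dose software; winners and bounds will not match
  such software case-by-case.
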