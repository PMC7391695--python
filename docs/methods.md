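# Methods

## Scope and data model

`psomi` analyses genus-level 16S abundance tables for two-group (psoriasis
case vs control) stool cohorts. The in-memory currency is a taxon × sample
matrix of non-negative read counts (or per-sample proportions, flagged as
such) with a Greengenes-style lineage attached to every taxon, plus a sample
metadata table (group, severity stratum, optional covariates) and a rooted
phylogeny with branch lengths over the taxa. All file formats are plain
text: TSV tables, newick trees, JSON index definitions.

Two lineage dialects are accepted on input — prefixed (`k__Bacteria;
p__Firmicutes; …`) and bare (`Bacteria;Firmicutes;…`) — and the prefixed
form is emitted, since validation cohorts routinely arrive with a different
convention than the training cohort. Ranks missing from a lineage stay
explicit empty strings; taxa unnamed at the collapse rank are pooled per
nearest named ancestor (`unclassified_family_Ruminococcaceae`), never into
one global bucket, so the genus sets that enter the index are unambiguous.

The low-confidence filter drops every taxon whose cohort-wide total is
strictly below 0.1% of all reads (a taxon exactly on the boundary is kept).
It runs at the input (OTU) level before genus collapse by default; the order
is exposed as a config switch (`filter_stage`) because either convention is
found in practice and the choice is not neutral for rare genera.

## Synthetic cohorts

Raw cohort sequencing data cannot travel with a package, so a generative
model stands in for it. Per sample, genus proportions are drawn from a
Dirichlet distribution with mean equal to the group's genus profile and
precision (concentration) θ; read depth is lognormal (parameterised by its
natural-scale mean and SD, default 29 873 ± 6 453 to match typical
post-filter 16S depths); counts are multinomial. Case profiles are the
control baseline multiplied by per-genus fold-changes and renormalized, so
effects remain interpretable and proportions valid.

The default cohort spans 23 genera across six phyla with control-group
phylum totals Bacteroidetes 59.9%, Firmicutes 33.0%, Proteobacteria 4.2%,
Verrucomicrobia 1.4%, Actinobacteria 0.8%, Fusobacteria 0.7%. The injected
dysbiosis signature multiplies *Faecalibacterium* and *Blautia* by 2.5 and
*Bacteroides* and *Paraprevotella* by 0.4, which moves the case phylum
balance to roughly 47% / 45% and the Dirichlet-mean F:B ratio from ≈ 0.55 to
≈ 0.95. Group sizes default to 55 cases / 27 controls. The concentration
default is θ = 200; at that dispersion the four signature genera are
recoverable with near-certain power at 50 samples per group while per-sample
compositions still scatter visibly (Bacteroides SD ≈ ±2.7 points). An
optional `verrucomicrobia_case_multiplier` (default 1.0) additionally
depletes *Akkermansia* in cases, mimicking the near-absence of
Verrucomicrobia reported in psoriasis stool; it is off by default so that
the injected ground-truth signature is exactly the four-genus panel the
recovery benchmarks target.

What the simulator does **not** emulate: the long tail of rare taxa (tens of
genera at < 0.1%), depth–composition correlation, taxonomic mis-assignment,
and the heavy overdispersion of real 16S data (real per-sample F:B ratios
scatter several-fold; at θ = 200 the simulated SDs are far tighter than
values reported from sequencing cohorts). Passing benchmarks on these
cohorts therefore demonstrates correctness and internal consistency of the
estimators, not expected field performance on real data, where group overlap
is substantially larger and AUCs well below 1 are the norm.

The random phylogeny used as the UniFrac substrate is built by uniformly
random pairwise joins with Exponential(1) branch lengths on all non-root
branches (n − 1 internal nodes, 2n − 2 branches; the root carries no
branch). It provides realistic tree shape variety for testing, not
biological signal: simulated effects are compositional, not phylogenetically
clustered.

## Diversity

**Chao1** uses the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)).
**Rarefaction** subsamples without replacement (multivariate
hypergeometric), seeded. Group comparison of alpha diversity computes
per-sample Chao1 at a common rarefaction depth (default: the cohort minimum
total) and contrasts groups with a two-sided Mann–Whitney U test; Welch's t
is available via `test="ttest"`. Both the depth policy and the test are
config choices because neither is standardised across published cohorts.

**UniFrac** is computed by branch accumulation. For every non-root branch e
with length ℓₑ, let Aₑ, Bₑ be the fraction of each community descending
through e. Unweighted UniFrac is the length bearing exclusively one
community's taxa over the length bearing either (presence/absence); weighted
UniFrac is Σ ℓₑ·|Aₑ − Bₑ| on proportions, with an optional normalized
variant dividing by its maximum attainable value Σ ℓₑ·(Aₑ + Bₑ). The
non-normalized weighted form is the default, matching the common QIIME 1.x
convention. The all-pairs path vectorises the per-branch flows into a
branch × sample matrix; unit and acceptance tests pin both paths to a naive
per-edge oracle at 1e-10.

**PCoA** is classical scaling of the Gower-centred −½D² matrix; negative
eigenvalues (non-Euclidean inputs) are reported but excluded from the
proportion-explained denominator, and only positive axes carry coordinates.

**PERMANOVA** uses the one-way pseudo-F partition of the squared distance
matrix (total minus within-group sums of squares, degrees of freedom k−1 and
N−k) with label permutations and the add-one estimate
p = (1 + #{F\* ≥ F}) / (1 + n_perm). Defaults: 999 permutations, seeded. A
zero within-group sum of squares yields F = ∞, which compares correctly
under the permutation ordering.

## Differential abundance

The genus screen follows the two-class LEfSe design. Samples are rescaled
to per-million internally, making the output invariant to per-sample
scaling. Stage 1 is a per-genus tie-corrected Kruskal–Wallis test at
α = 0.05 (all observations identical is treated as degenerate: H = 0,
p = 1, never reported). The subclass Wilcoxon stage is a structural no-op
with two plain classes and is omitted. Stage 2 runs 30 bootstrap rounds; in
each, two-thirds of every class is subsampled without replacement and a
one-component linear discriminant is fitted over the surviving genera
jointly. A genus's effect in a round averages its share of the
discriminant-axis class separation (|w_g|·gap) with its raw class-mean
difference, and the reported score is log₁₀(1 + mean effect over rounds);
features need score ≥ 2.0. Columns with zero within-class variance in a
round are jittered minutely so the within-class scatter stays invertible, as
the original tool does. Exact numeric parity with any specific LEfSe release
is not a goal; the contract is recovery of injected signatures, correct
direction labels, scores monotone in effect size, and calibrated
false-positive behaviour.

A consequence of the α-level screen worth knowing: on a cohort with ~20
genera, about one chance genus per run passes both stages (its per-million
effect size easily clears the 2.0 threshold once it has survived the
screen). This matches the screen's nominal calibration, and the benchmarks
treat it accordingly — single-run recovery is checked as "all injected
genera recovered with correct directions", while exact-set recovery is
checked on the majority-vote signature across ten independent cohorts,
where chance survivors (each appearing in ≤ 2 of 10 runs) vanish and the
injected panel (10 of 10) remains.

The F:B ratio is computed per sample after phylum collapse, with half the
smallest nonzero phylum sum as pseudocount when a denominator is zero;
groups are contrasted by two-sided Mann–Whitney U (Welch optional).
Bonferroni adjustment (min(1, m·p)) is provided for families of phylum-level
comparisons; the LEfSe screen itself is uncorrected, as in the original
tool.

## The index

PMI = log₁₀(Σ increased genera / Σ decreased genera) on per-sample relative
abundances. Log base 10 is the default (matching the LDA-score convention
and giving the cutoff a familiar scale) and is configurable. Relative rather
than count abundances make the score depth-independent — the property that
lets a frozen cutoff transfer across cohorts sequenced at different depths.
The pseudocount policy is half the table's smallest nonzero proportion,
applied to both sums only for samples where either sum is zero, so typical
samples are untouched. Genera named by the index but absent from a table
contribute zero and trigger a warning rather than an error, since external
cohorts rarely contain every training genus.

ROC curves place thresholds at midpoints between consecutive distinct
scores with ±∞ sentinels; classification is "case if score ≥ threshold".
AUC is computed by rank-based pairwise concordance, P(case > control) +
½P(tie), which equals the trapezoid area. The operating cutoff minimizes
|sensitivity − specificity| (the intersection of the two curves), with ties
broken by the larger sensitivity + specificity, then the smaller threshold.

Cross-validation is stratified tenfold (seeded). By default the
discriminant genera are re-selected by LEfSe inside each training fold
before scoring the held-out fold, so pooled held-out performance contains
no selection leakage; a frozen-index mode (`reselect=False`) reproduces the
optimistic variant in which the index was chosen on all data. On clean
simulated cohorts the two modes barely differ; on marginal signatures the
frozen-index mode overstates AUC, which is why re-selection is the default.
`apply_index` scores an independent cohort with a frozen index and cutoff
and reports sensitivity/specificity at that cutoff plus the test-set AUC.

## Pipeline and reproducibility

`run_pipeline` executes ingest/simulate → filter → collapse → normalize →
alpha → beta (distances, PERMANOVA, PCoA) → F:B → LEfSe → index → ROC/cutoff
→ cross-validation → external application, writing every artifact as text
and a `report.json` carrying the package version, the seed and a config
hash. One global seed fans out to per-stage seeds by hashing the stage name,
so any stage can be re-run in isolation and a fixed config yields
byte-identical outputs. A stage failure aborts the run with the stage name
attached.

## Benchmark problem sizes

The test suite and acceptance script run entirely on simulated data at
sizes chosen to make the statistical checks decisive while keeping runs
quick: oracle equivalence on 200 random trees of ≤ 10 leaves and exhaustive
AUC configurations up to n = 8; type-I calibration on 500 null cohorts
(PERMANOVA, 199 permutations each) and 20 null cohorts (LEfSe) of 50
samples per group; parameter recovery, tenfold CV and external transfer
over 10 seeds at 50 per group; the acceptance script itself runs the full
pipeline at the 55/27 group sizes with 999 permutations.

## Known limitations

- Genus-level 16S resolution only; no species/strain profiling, no
  functional inference.
- The LEfSe reimplementation targets behavioural, not bit-level, agreement
  with the original tool; scores can differ in the second decimal.
- The simulator's Dirichlet-multinomial noise understates real microbiome
  overdispersion (see above), so simulated AUCs saturate near 1.
- PERMANOVA is one-way (group labels only); covariate-adjusted designs are
  out of scope.
- Trees are assumed rooted with non-negative branch lengths; unrooted input
  is not auto-rooted.
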