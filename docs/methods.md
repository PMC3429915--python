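# Methods

`riqtl` implements the quantitative-genetic analysis of a diet-responsive
trait measured in a recombinant inbred (RI) mouse panel: a set of fully
inbred strains derived from a two-parent cross (labelled LG and SM
throughout, after the classical large/small body-size selection lines),
phenotyped in a full strain × sex × diet factorial and genotyped at
homozygous SNP markers.  The motivating trait is liver fat accumulation
under high- versus low-fat feeding, but every routine is generic over the
trait column.

## Trait construction

Liver fat mass scales with liver size, so the analysis trait
("fattiness") is the residual of fat mass regressed on lean mass by
ordinary least squares, pooled over all animals.  A single pooled slope is
the default because one residual trait is used in every downstream stage;
fitting per-cohort slopes would remove cohort mean differences and
decouple the cohorts, so it is available only as an explicit option
(`per_cohort=True`).  Residuals are invariant to adding a constant to all
fat masses and equivariant under scaling, which the tests verify.

Percent liver fat, fat/(fat+lean), serves as the descriptive companion
trait for strain-level dietary-response summaries.  The denominator is
the sum of the two measured compartments, the operational "total mass"
when only fat and lean are recorded.  Per-strain dietary response is the
percent change of the cohort mean on the high-fat diet, tested with a
two-sided Welch two-sample t-test at α = 0.05; Welch is chosen over the
pooled-variance test because cohort sizes and variances are unequal by
design.  Pairs in which either diet cell has fewer than two animals get
the percent change where computable and a missing p-value.

## Variance components and heritability

The trait is decomposed with the three-way mixed ANOVA

Y_ijk = μ + Sex_i + Diet_j + Strain_k + Sex×Diet + Sex×Strain
      + Diet×Strain + Sex×Diet×Strain + e_ijk,

with sex and diet fixed and strain random.  Sums of squares are Type III
from the sum-to-zero coded full factorial fit, because the panel is
unbalanced whenever breeding success varies between strains; on balanced
data they reduce to the classical mean-deviation decomposition, which the
tests check against a brute-force oracle and against
`statsmodels.anova_lm(typ=3)`.  F denominators follow mixed-model
expected mean squares: each fixed effect is tested against its
interaction with strain (sex vs sex×strain, diet vs diet×strain, sex×diet
vs sex×diet×strain) and strain plus all strain interactions against the
residual.

Variance components use method-of-moments mean-square contrasts,
σ²_term = (MS_term − MS_r)/n₀, with the Sokal–Rohlf adjusted group size
n₀ = (N − Σn_i²/N)/(a − 1) computed from each component's own grouping
(strain cells for σ²_str, sex×strain cells for σ²_sexstr, and so on).
Raw components can be negative by sampling error; they are reported as-is
and truncated at zero only where a bounded heritability requires it.
Broad-sense heritability is H² = σ²_str/(σ²_str + σ²_r); the dietary-
response, sexual-dimorphism and three-way heritabilities use the same
ratio with the corresponding interaction component in the numerator (the
simplest denominator consistent with the overall H² form).  Within-cohort
H² comes from a one-way random-effects ANOVA restricted to the sex-diet
cohort, keeping strains with at least two animals.

Genetic (between-strain) correlations are Pearson correlations of strain
means: RI strain means average away within-strain environmental noise, so
their correlation estimates the correlation of genetic effects, and r²
is the shared genetic variance.  Between-trait correlations use strain
means pooled over sex and diet; the between-environment correlation of
one trait uses strain-by-diet means.  Both groupings are exposed through
`strain_means(by=...)`.

Method-of-moments, not REML, is deliberate: the mean-square formulas are
the specification of this analysis, and the estimators are transparent
and exactly testable against designed variance ratios.

## QTL scan

Strain-sex-diet cohort means are the unit of observation (a full
18-strain panel gives 72 rows); means are usable as trait values because
RI strains are isogenic.  Each marker is tested with the factorial model

Y = μ + Sex + Diet + Genotype + Sex×Diet + Sex×Genotype + Diet×Genotype
  + Sex×Diet×Genotype + e,

dropping the absent factor and its interactions in sex, diet, and
sex-diet sub-cohort scans.  The scan statistic is the partial (Type-III)
F of the genotype main effect; interaction p-values are reported but do
not drive calling, because cohort-stratified scans are the mechanism for
cohort-specific QTL.  Since genotype has two levels, the partial F equals
the squared t of the sum-coded genotype coefficient, which the
implementation computes from the normal equations — the permutation
oracle re-runs the scan tens of thousands of times, so the per-marker fit
must be cheap.  Cohort means are equally weighted (an n-weighted fit is a
documented alternative, not the default, since the means themselves are
the observations).  Markers whose minor genotype class covers fewer than
3 strains are skipped as unstable and logged; strains with a missing call
drop out of that marker's fit only.

Evidence is summarised as LOD = log₁₀(1/p).  Per chromosome and cohort,
one QTL is called where the peak LOD clears the chromosome-wide
threshold, ties breaking deterministically toward the lower position.
The ~95% localisation interval is the one-LOD drop: the contiguous run of
markers around the peak with LOD ≥ peak − 1, extended one marker beyond
the last qualifying marker on each side ("bracketing") because the true
crossing lies between markers; the strict qualifying span is available
via `bracketing=False`.  The additive genotypic score is
a = (mean of SS-class strain means − mean of LL-class strain means)/2,
so a > 0 means the SM-derived allele raises the trait.

## Significance thresholds

Linked markers are correlated, so thresholds use the effective number of
independent tests: genotypes are coded ±1, the marker correlation matrix
is computed across strains (pairwise-complete under missingness, with a
warning when any pair has fewer than 4 complete observations), and each
eigenvalue λ ≥ 0 contributes I(λ ≥ 1) + (λ − ⌊λ⌋) to Meff.  M
independent markers give Meff = M, M copies of one marker give Meff = 1.
Eigenvalues are rounded at 1e-8 before the integer/fractional split so
exact duplicates land on integers.  One caveat is inherent to the
estimator: adding an exact duplicate of a marker that is itself
correlated with its neighbours can raise Meff by up to ~1 (trace grows by
one and eigenvalues interlace); the duplicate-invariance property is
exact only when the duplicated marker's companions are orthogonal.

The chromosome-wide point-wise level is Šidák,
α_c = 1 − (1 − α)^(1/Meff), reported as a LOD threshold log₁₀(1/α_c);
"multiplicity-adjusted" is read as Šidák rather than raw division because
the two differ negligibly at α = 0.05 (raw α/Meff is available via
`method="bonferroni"`).  The genome-wide level sums Meff over
chromosomes, since chromosomes assort independently in an RI panel.  A
strain-label permutation oracle (`permutation_threshold`) estimates the
same threshold empirically as the ⌈(1−α)·n_perm⌉-th order statistic of
per-permutation max LOD, and agrees with the analytic threshold to about
±0.3 LOD on independent-marker panels.

## Synthetic panel generator

The generator emulates the study design so every stage is testable
without external data.  Genomes are two-state Markov mosaics per
chromosome: the first marker is LL or SS with probability ½ and adjacent
markers switch with the sib-mating RI map-expansion probability
R = 4r/(1 + 6r), r from the cM gap via Haldane's map function.  Parental
strains are fixed all-LL (LG) and all-SS (SM).  Default map: 512 markers
split evenly over 19 autosomes + X, 80 cM per chromosome with even
spacing (the true spacing of an informative panel is platform-specific);
the X is treated as an autosome because RI strains are homozygous
throughout.  Dominance and epistasis are not modelled — an RI design
cannot estimate them.

Phenotypes realise the ANOVA generative model: fixed sex, diet and
sex×diet effects; strain and strain-interaction effects drawn once per
strain (or strain-by-factor cell) from centred normals; optional planted
QTL adding ±a by genotype class within a scope (everywhere, one sex, one
diet, or one sex-diet cell); i.i.d. residual noise.  Lean mass is drawn
from a positive normal (default 800 ± 80 mg) and fat = 0.5·lean + value,
so the fat-on-lean residual recovers the simulated value by design; the
slope and offset are arbitrary and the residual pathway is invariant to
them.  Fat is clipped at zero with a warning, since clipping distorts
residuals.

Defaults are the study conditions: 16 RI strains plus both parentals, 7
animals per strain-sex-diet cohort (the design aimed at 8 but averaged
seven), and variance components (0.282, 0.136, 0.205, 0.099 against a
unit residual) chosen so the designed heritabilities match the magnitudes
reported for diet-responsive liver fat in this kind of panel (overall
~22%, diet×strain ~17%, sex×strain ~12%, three-way ~9%).  Unequal cohort
sizes are supported through a per-cohort count table; missing genotypes
through a configurable rate (default 0).

What the generator does not emulate: real linkage-disequilibrium decay
from an actual breeding pedigree, genotyping error, shared-cage and batch
effects, or non-normal trait distributions.  Passing tests therefore
demonstrate that the estimators recover the parameters of this generative
model at the design scale — not that any particular biological dataset
satisfies the model.

## Numerical choices and scaled problem sizes

Design matrices use sum-to-zero coding; Type-III SS come from
column-drop partial residual-SS comparisons with `numpy.linalg.lstsq`,
and singular designs (empty factorial cells) are rejected with a
diagnostic rather than silently reparameterised.  Scan p-values are
clipped away from zero before the log so LOD stays finite.  A constant
trait yields an all-zero ANOVA with F reported missing.

Simulation-backed checks use sizes chosen to give stable Monte-Carlo
estimates at interactive runtimes: 10,000 strains for map-expansion and
allele-frequency checks, 200 replicate panels for variance-component
recovery, 20 panels × 1,000 permutations for threshold calibration, and
100 end-to-end runs each for power and false-positive rates.  The power
configuration plants a²/σ²_r = 25 on a 5-chromosome, 18-cM-spaced map so
that the peak is expected at the planted marker itself rather than at a
neighbour sharing its strain distribution pattern.

## Known limitations

- The cohort-mean scan inherits the method's pseudo-replication: when
  between-strain variance is present, a strain's four cohort means share
  its strain effect, and the genotype F test treats them as independent.
  Under realistic background heritability the scan is anti-conservative
  at the nominal threshold; the null-calibration guarantee holds for the
  residual-noise null.
- Meff duplicate-invariance is exact only for orthogonal companions (see
  above).
- Negative variance components are truncated for heritability only;
  downstream consumers should inspect the raw values.
- One QTL is called per chromosome per cohort; multi-QTL models,
  composite-interval mapping and epistasis scans are out of scope, as is
  gene annotation of support intervals.
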