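# Methods

## The observable and its unit

The unit of observation is one maternal meiosis, observable inside a
three-generation family: a genotyped offspring, its genotyped dam (the focal
parent), and at least one genotyped grandparent on the dam's side. The dam's
two haplotypes are labelled by grandparental origin; each switch of origin
along the gamete she transmitted is one crossover. A dam with several
genotyped offspring contributes several meioses; the meiosis, not the cow, is
the row of every downstream table.

## Crossover calling

Phasing is single-pass Mendelian deduction, not statistical phasing: at a
dam-heterozygous site, a homozygous grandsire fixes the grandpaternal allele,
otherwise a homozygous granddam fixes the grandmaternal one; everything else
stays phase-unknown. The transmitted allele is deduced only when the
offspring is homozygous, or heterozygous with a homozygous other parent. A
site is *informative* when dam-heterozygous, phase-known and
transmission-resolved. One crossover is called per adjacent informative pair
with differing origins, into the 0-based half-open interval between the two
marker positions; the interval midpoint serves when a point summary is
needed.

This rule set deliberately trades yield for correctness: ambiguous sites are
excluded rather than imputed, so on error-free data the called count per
chromosome equals, exactly, the number of *detectable* true crossovers — the
parity of true events between consecutive informative markers. Two true
crossovers landing between the same informative pair cancel and are
invisible; events outside the informative span are invisible too. The test
suite asserts this equivalence event-by-event on simulated truth.

Mendelian inconsistencies (genotyping errors) are never fatal: the site is
set missing and counted, and a family whose inconsistency rate exceeds a
threshold (default 2% of markers) is dropped. A double-crossover artifact
filter (two switches within a short window) is deliberately not applied by
default; the interval representation keeps such events auditable downstream.

Study filters, each surfaced in configuration with its standard value:
autosomes only; BED-masked problematic regions removed before phasing;
families on panels below 50,000 nominal markers excluded; meioses with more
than 45 genome-wide events discarded as artifacts.

## Covariates and the adjusted phenotype

- **A** — maternal age at the offspring's birth, complete calendar months.
- **B** — the dam's calendar birth year. Both enter untransformed together
  with their squares, matching the conventional coefficient scales; a
  `center` option exists purely for numerical conditioning (the solver also
  equilibrates columns internally, since uncentered B and B² are nearly
  collinear).
- **T1 / T2** — three-level temperature categories (hot > 26.67 °C,
  cold < 4.44 °C, boundaries inclusive to "normal" since the definitions are
  strict inequalities) of the monthly average at the relevant farm for the
  calendar month preceding the offspring's birth (T1) and the dam's own
  birth (T2). A configurable alternative references the month before
  conception (birth minus a 280-day gestation) instead, because temperature
  exposure during early fetal development is the biological target and the
  two conventions differ; the pre-birth month is the default. Records with a
  missing station-month are flagged and excluded from temperature analyses.
- **Y** — the phenotype: the genome-wide count R residualized by OLS on
  panel-class indicators plus the informative-marker count. Denser panels
  resolve more crossovers, so without this step panel density would
  masquerade as biology. The functional form (categorical class + linear
  informative count) is a pragmatic choice; residuals are exactly orthogonal
  to the adjustment design by construction.

For grouped displays, ages are binned from 20 months in 10-month steps into
ten groups, the last open-ended above 110 months; ages under 20 months are
excluded from grouped displays only.

## The mixed model

Y = α + T1 + T2 + A + A² + B + B² + g + ε with g ~ N(0, σ²_g G) over dams,
ε ~ N(0, σ²_e I) over meioses, and an incidence matrix sharing one g across a
dam's meioses. G is the VanRaden method-1 genomic relationship matrix,
ZZ′/(2Σp(1−p)) with Z column-centered at 2p, allele frequencies observed,
missing dosages mean-imputed and monomorphic markers excluded.

Estimation is exact REML. With V = σ²_e (I + γ ZGZ′), γ = σ²_g/σ²_e, one
eigendecomposition of the dam-space matrix L′Z′ZL (G = LL′) reduces every
restricted-likelihood evaluation to O(n); σ²_e profiles out analytically and
the remaining one-dimensional criterion in h² = γ/(1+γ) is minimized by
bounded scalar search on [0, 1). This was chosen over average-information
updates with EM fallback: for a single genetic variance component the profile
criterion is cheap and the bounded search cannot step outside the parameter
space, stall, or miss the boundary solution σ²_g = 0, which is checked
explicitly and reported as such. The unprofiled restricted likelihood is
exposed (`reml_loglike`) so the optimum can be verified against grid search,
and the tests do exactly that.

Fixed effects are GLS at the REML variances, with SEs from the inverse
coefficient matrix and two-sided Wald z-tests declared significant at
P < 0.05 (no multiplicity correction — each factor is one pre-specified
hypothesis). h² = σ²_g/(σ²_g+σ²_e) gets a delta-method SE from the observed
information of (σ²_g, σ²_e), evaluated by central finite differences with a
relative step of 10⁻²; much smaller steps sit below the round-off floor of
the likelihood and return noise, which the implementation avoids by
construction. At the σ²_g = 0 boundary the information is evaluated one-sided
and the SE should be read as approximate.

The age trend is summarized by a cubic smoothing spline with
generalized-cross-validation smoothing (replicate ages are averaged with
count weights, which leaves the penalized criterion unchanged), reporting the
fitted curve on an age grid and its argmin; group summaries report n, mean
and sd/√n, and temperature categories get standard 1.5×IQR boxplot
statistics.

## The synthetic-data generator

The generator emulates the structure of a genotyped national dairy pedigree
at desk scale and is the package's source of ground truth.

**Genome.** Five autosomes of 100 Mb, 400 markers each by default, random
positions, uniform genetic map; per-chromosome map length defaults to
base rate / number of chromosomes so the expected genome-wide crossover count
matches the count model below. Founder allele frequencies are Uniform(0.05,
0.5); founders are drawn in Hardy–Weinberg proportions. There is no
linkage-disequilibrium structure beyond what the pedigree itself creates —
a deliberate non-goal.

**Pedigree.** Equal-size non-overlapping generations; every non-founder has a
sire and dam from the previous generation, inherits the dam's farm, and is
dated by the dam's age at calving, drawn as 20 + Gamma(1.6, 14) months —
chosen once so that ~92% of calvings fall below 65 months and ~1% above 100,
matching the reported age distribution of US dairy records. Chip-class labels
(default 80% 50K-class, 20% HD) are metadata for the panel filter, not the
simulated marker count.

**Temperature.** Monthly farm averages follow an annual cosine peaking in
July with mean 15 °C, amplitude 13 °C and month noise sd 2.5 °C — chosen once,
analytically, so that uniformly distributed birth months yield roughly
16% hot / 68% normal / 16% cold exposures, the proportions reported for US
dairy data.

**Counts.** One maternal meiosis's count is Poisson given a latent rate
λ = α + β·x + g + e (floored at 0.5), where x holds A, A², B, B², T1 and T2
indicators with the published effect magnitudes as generating defaults
(cold −0.194, hot +0.167, age −0.082, age² +4.69×10⁻⁴, year +5.02×10⁻³,
year² −4.41×10⁻⁷; the T2 effects default to zero), g = Z·u is a polygenic
value built from the animal's own centered marker dosages with
Var(g) = h²·(target variance), and e is Gaussian. The intercept and Var(e)
are calibrated analytically against the realized covariate spread so the
marginal count distribution has mean 23.2 and variance 98.3 with h² = 0.10 on
the count scale (Var(count) = E λ + Var λ, the Poisson layer contributing the
mean). The rate floor truncates the lower latent tail and shrinks the
realized variance by well under 1%, visible as sample variances a point or
two below 98.3 at large n. A Poisson-given-Gaussian-rate form is the
package's own choice — the empirical distribution is only reported as
approximately normal with those moments — because it yields the required
overdispersion and a well-defined latent-scale heritability.

Paternal meioses receive plain Poisson(base rate) counts with no covariates
or genetics: they exist only to complete offspring genotypes, since only
maternal crossovers are analysed.

**Placement and transmission.** Given a count, crossovers are allocated to
chromosomes in proportion to map length and placed uniformly on genetic
distance (no interference — the analysis uses only counts and interval
positions, and an interference model would not change either's
definition). Gametes are exact strand switches of parental haplotypes, so
before error injection every offspring genotype is a perfect Mendelian
transmission. Genotyping errors and missingness are injected at configured
rates (defaults 0).

`simulate_rate_study` exposes the count-generating layer alone (covariates,
polygenic values from simulated genotypes, calibrated latent variance) for
estimator experiments at sizes where full transmission simulation adds
nothing.

**What passing tests do and do not show.** The simulator has independent
founders, no LD, uniform maps, no interference, a stationary seasonal
climate, and exactly the fitted model's covariate structure. Recovery of
h² and of the fixed effects therefore demonstrates correctness of the
estimator and pipeline, not robustness to the confounding, ascertainment and
map misspecification present in real national data (e.g. culling of older
cows, which the original study itself flags as a possible source of the
post-65-month upturn).

## Problem sizes and numerical choices

Test and verification experiments use desk-scale sizes chosen to make the
Monte-Carlo error small relative to each tolerance: calibration moments at
10,000–12,000 meioses; heritability recovery as the mean of 10 replicates of
1,000 dams; fixed-effect coverage over 20 replicates of 5,000 meioses
(1,000 dams × 5); Wald type-I error over 400 replicates of 600 meioses;
caller exactness over 500 meioses on 5 × 2,000 markers. REML convergence uses
a 10⁻¹⁰ bracket tolerance on h²; GRM eigenvalues are clipped at zero;
rank-deficiency of the fixed design is detected by scaled QR and reported
with the aliased column's name. Ties in the spline argmin resolve to the
left-most grid point; the grid spans the observed age range with 201 points.

## Known limitations

- The adjustment regression and the mixed model are fitted sequentially, as
  in the original analysis, so uncertainty in the adjustment is not
  propagated into the fixed-effect SEs.
- h² and its SE are asymptotic quantities; at boundary fits (σ²_g = 0) the
  SE is one-sided and approximate.
- The caller reports detectable events only; with sparse informative markers
  the counts are attenuated relative to truth, which the panel/informative
  adjustment compensates for only linearly.
- Uncentered B and B² are nearly collinear over a short span of birth years;
  estimates remain well-defined through column equilibration but their
  individual SEs are large in small samples. Use `center=True` when the
  coefficient scale convention is not required.
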