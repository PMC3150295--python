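# Methods

## What the simulator does

Coalescent simulators (ms, msHOT, msms, GENOME) produce genotypes — binary
haplotypes at segregating sites, `0` ancestral and `1` derived — but no
phenotypes. phenosim attaches a phenotype to each simulated individual under
a user-chosen genetic architecture, subsamples the population the way a real
study would, and writes files that GWAS tools read directly. The point is
power studies: with genotypes from an arbitrary demographic scenario and
phenotypes with a known causal architecture, one can measure how often an
association method finds the truth.

The pipeline per replicate: parse haplotypes → (pair chromosomes into
diploids if requested) → select causal sites → assign phenotypes to the full
population → optionally remove causal markers and subsample markers and
individuals → write output formats. All stages are driven by one root seed
with independent substreams per stage (site selection, environmental noise,
penetrance draws, marker and individual sampling), so changing one stage
never perturbs the draws of another.

## Quantitative trait model

Each quantitative trait nucleotide (QTN) *j* is parameterized by the
proportion of phenotypic variance it should explain, π_j ∈ [0, 1); the sum
of all effects, plus any epistatic effect π_E, is the trait heritability
h² < 1. The phenotype of individual *i* is

    Y_i = Σ_j β_j g_ij (+ β_E a_iE) + ε_i,    ε_i ~ N(0, 1)

with genotype codings

* haploid: g_ij = a_ij ∈ {0, 1} (derived-allele indicator),
* diploid additive: g_ij = Q_ij ∈ {−1, 0, +1} (homozygous ancestral /
  heterozygous / homozygous derived),
* diploid dominant: g_ij ∈ {0, 1}, 1 for carriers of at least one derived
  allele.

The coefficient is fixed by the variance contract:

    β_j = sqrt( π_j / ( v_j · (1 − h²) ) )

where v_j is the variance of the coding at the QTN's **realized** sample
frequency f: v = f(1−f) for every 0/1 coding and v = 2f(1−f) for the diploid
{−1, 0, +1} coding under random pairing of chromosomes. With independent
QTNs this is the unique scaling under which Var(Y) = 1/(1−h²), each QTN
carries the fraction π_j of total phenotypic variance, and the noise carries
1−h². The scaling is verified empirically (regression-based variance
recovery at n = 20,000) rather than asserted.

For dominant QTNs the coding variance uses the realized carrier frequency
p_D = P(≥1 derived allele), not the allele frequency — that is what makes
the dominant indicator contribute exactly π_j.

### Epistasis

A positive additive epistatic interaction between exactly two QTNs is
modeled as a fictive third QTN: a_iE = 1 iff individual *i* carries at least
one derived allele at **both** basal QTNs. Its coefficient β_E is computed
like any other 0/1 QTN, using the realized frequency f_E of the fictive
allele in the sample (the fictive allele's frequency is induced by the
basal QTNs; it is not a free parameter). If the fictive allele is
monomorphic in the sample the model is degenerate and generation fails with
advice to re-select the basal QTNs.

**Known limitation — correlated terms.** The fictive indicator is, by
construction, positively correlated with its basal QTN columns, so the
variance contributions of the three terms are not orthogonal: the covariance
inflates Var(Y) slightly above 1/(1−h²), and the indicator's realized share
of phenotypic variance lands a little below its nominal π_E (about 0.075
for π_E = 0.08 with the default study conditions). The same caveat applies
whenever QTNs are in strong linkage disequilibrium, e.g. under the
common-haploblock constraint; there the meaningful quantity is the total
variance explained by the full causal design matrix, not per-term shares.

**Measuring a term's contribution.** Throughout the tests and the
reproduction script, the "variance share" of term *j* in the fitted
regression of Y on the causal columns is β̂_j² · Var(x_j) / Var(Y) — the
marginal phenotypic variance carried by that term. For mutually independent
predictors this equals the increment in R² from adding the column; for the
correlated epistatic indicator the increment-in-R² reading instead measures
only the component orthogonal to the basal QTNs (≈ 0.03 under the default
conditions) and is **not** the quantity the generative scaling calibrates,
so the marginal share is the reading used.

## Qualitative (case/control) traits

A penetrance model maps each one- or two-locus genotype to a probability of
being affected: 2 (haploid) or 3 (diploid) entries per locus, a 2×2 or 3×3
table for two loci. Statuses are independent Bernoulli draws. The
closed-form prevalence Σ_g P(g)·penetrance(g) is exposed
(`expected_prevalence`) as an oracle for the empirical case fraction.

Because low-frequency risk alleles yield few cases, the ascertainment stage
can sample a minimum number of cases (plus a control quota) from a larger
simulated population, mirroring case/control recruitment. When the
population cannot supply the requested cases, the error reports how many
were available so the user knows to simulate a larger population.

## Causal-site selection

Sites are drawn uniformly at random from the polymorphic sites, optionally
restricted to a derived-allele frequency range (realistic risk-allele
frequencies change the local linkage pattern, so this matters for power
studies). Manual site choices are honored verbatim and bypass the frequency
filter. Eligible sites are enumerated in ascending column order before
sampling, making selection reproducible across platforms.

With the common-haploblock constraint (two QTNs), the pair is drawn
uniformly from all eligible pairs that lie inside a single haploblock.
Haploblocks are maximal runs of sites that mutually pass the four-gamete
test (fewer than all four gametes 00/01/10/11 observed), built greedily left
to right with the all-pairs rule: a site joins the current block only if it
is compatible with every site already in the block. The all-pairs rule (as
opposed to adjacent-pairs only) is a deliberate choice: it is deterministic,
order-stable, and guarantees every within-block pair is tree-compatible.

## Subsampling

Order of operations is fixed: phenotypes are assigned on the full
population; then causal columns are removed (if requested) **before** the
marker subsample; then markers are drawn uniformly without replacement and
re-sorted by position; finally individuals are ascertained or drawn
uniformly. Genotype–phenotype pairing is preserved throughout. When causal
markers are kept, they enjoy no retention privilege in the marker subsample;
the indices of any that survive are returned remapped to the new columns.

## Output formats

PLINK PED/MAP, transposed TPED/TFAM (the layout EMMAX consumes), EMMA plain
genotype/phenotype matrices, and a generic TSV pair. Ancestral/derived
alleles are written as A/T (coalescent output has no nucleotide identities;
the letters are arbitrary but fixed), case/control statuses as 1/2 per the
PLINK convention, quantitative values at full round-trip precision. All
writers are byte-deterministic (LF endings, no timestamps), and derived
allele counts per marker are conserved across formats. Fractional ms
positions convert to base pairs by rounding half up at a configurable locus
length (default 1 Mbp); collisions are bumped +1 bp with a warning because
PLINK requires distinct integer positions.

Out of scope for this version: Blossoc/QBlossoc, QTDT/MERLIN and TASSEL
writers, VCF ingestion/export, and running coalescent simulators as
subprocesses.

## Synthetic fixture generator

`generate_fixture` draws each site independently: chromosome × site Bernoulli
draws at per-site derived-allele probabilities, positions sorted-uniform on
[0, 1]. It reproduces allele-frequency structure but **no linkage
disequilibrium and no genealogy** — adjacent sites are uncorrelated, unlike
real coalescent output. Consequently tests built on fixtures validate the
variance-partition arithmetic, selection constraints, sampling contracts and
formats, but say nothing about LD-driven behavior (e.g. how often a nearby
non-causal marker tags the QTN); haploblock tests use constructed matrices
with known block structure instead, since independent common sites on many
chromosomes yield almost exclusively singleton blocks.

## Study conditions used in the checks

The variance-recovery checks simulate 20,000 haploid individuals at 200
sites with per-site derived-allele probabilities uniform in [0.2, 0.8], 50
replicates per model — large enough that Monte-Carlo error on a mean R² is
below 0.001, small enough to run on one CPU in seconds. Two architectures
are exercised: (i) two QTNs with π = 0.05 each, and (ii) two QTNs with
π = 0.01 each plus π_E = 0.08 (both with h² = 0.10). For model (ii),
replicates whose fictive-allele frequency falls outside (0.1, 0.9) are
discarded before averaging (a near-monomorphic indicator makes its share
estimate unstable); under these conditions the filter keeps nearly all
replicates.

The penetrance check draws 200 random tables (uniform entries, alternating
one- and two-locus diploid models) at n = 10,000 and compares the empirical
case count against the closed-form prevalence with a per-table exact
binomial test at α = 0.01/200 — a familywise 1% error budget; the binomial
reference is conservative for the Poisson-binomial case count, since
Σp_i(1−p_i) ≤ n·p̄(1−p̄).

## Numerical and degenerate-input choices

* Monomorphic sites can never be QTNs or penetrance loci; frequency and
  coding variances are always computed from the realized sample.
* `segsites: 0` parses to an empty matrix (row count from the command line's
  sample-size token when present) — not an error.
* Haplotype rows that mismatch the declared site count, or contain
  characters outside {0, 1}, fail with the 1-based line number.
* Sample-size mismatches between the ms command line and the haplotype rows
  warn but do not fail (third-party output is ingested permissively);
  likewise non-monotone GENOME positions are re-sorted with a warning.
* Ties in base-pair rounding go half up; equal positions are separated by
  +1 bp bumps.
* Exit codes of the CLI: 0 success, 2 configuration error, 3
  data/eligibility error; a failing replicate is logged with its stage name
  and skipped, and only an all-replicates failure aborts the run.
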