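# Methods

This note documents the statistical model, the defaults and the design
choices behind `pedmut`, and what its synthetic validation does and does not
demonstrate.

## Trio genotype model and the de novo score

A site is modeled biallelically. The joint posterior over the 27 trio
genotype configurations factorizes into three per-individual genotype
likelihoods (taken from the genotyper via `PL`/`GL`; converted to natural
log by −PL·ln10/10 and normalized so the maximum entry is 0), a
transmission prior and a parental prior. The de novo score DN_p is the
normalized posterior mass on (offspring het, mother hom-ref, father
hom-ref), computed in log space with a log-sum-exp normalization over all
27 configurations; equivalence with direct enumeration is maintained to
10⁻¹² in the test suite.

*Transmission.* Each parent transmits one allele chosen uniformly from its
two; the transmitted allele flips ref↔alt with probability `mu_prior`. This
is a biallelic collapse — no 1/3 factor for the choice among alternative
bases — because sites are represented biallelically and DN_p is used as a
ranking score, where constant factors are immaterial.

*Parental prior.* Parents are independent with P(het) = θ,
P(hom-alt) = θ²/4 and the remainder on hom-ref. Trio-aware callers each use
their own variant of this prior; this concrete form was chosen because it
is normalized, testable and adequate for ranking. DN_p is not interpreted
as a calibrated probability.

*Defaults and why.* `mu_prior = 1e-6` and `theta = 0.008` are deliberately
liberal relative to realistic values (per-site per-generation rates near
1e-8–1e-9; wolf-population heterozygosity near 0.0015). Realistic priors
suppress candidates whose parents might carry a missed heterozygote; the
liberal values push such sites above the cutoff so that the downstream
validation step, not the prior, decides. The candidate cutoff is
DN_p > 0.3, strictly: a score of exactly 0.3 is not a candidate.

*A note on monotonicity.* In the candidate regime (offspring evidence
favoring het, prior mutation probability ≤ 1e-3) DN_p increases with
`mu_prior`, as expected: the DNM configuration's prior mass grows linearly
in μ. This is not a global property — when the offspring's likelihood
strongly favors hom-alt, configurations whose transmission probability
grows as μ² dominate the normalizer and the score can decrease — so the
property is asserted, and should be relied on, only in the het-evidence
regime.

## Callable-genome filters

Seven pure per-site predicates, applied in a fixed order for stage-count
reporting (the final callable set is order-independent):

| filter | rule | default |
|---|---|---|
| repeat | site inside a repeat-annotation interval | BED input |
| missing | zero depth in any member, or deletion-read fraction above cutoff | > 5% |
| depth | coverage below/above limits in any of the three members | < 10× or > 100× |
| parental_alt | ≥ 1 alternative-allele read in either parent | — |
| density | > N other variant sites within the window on either side | > 3 in ± 200 b |
| gap | reads with alignment gaps at the site | ≥ 3 |
| gc | GC fraction of the surrounding window above cutoff | > 0.60 in 100 b |

Coordinates are VCF 1-based; BED intervals 0-based half-open. The GC window
is the site ± 50 bases excluding the site base itself (immaterial at this
width); an all-ambiguous window is treated as failing, conservatively. The
GC filter is a toggle because rates are reported with and without it. The
depth filter applies to the three trio members only: filtering is per-trio
by design, to maximize each trio's chance of retaining a true DNM.

*Variant sites for the density filter.* A "variant site" is one where any
trio member's MAP genotype — likelihood plus the per-individual
heterozygosity log-prior (`density_call_theta`, default 0.008) — is
non-hom-ref. A genotype *call* is essential here: defining variant sites by
raw ≥ 1-alt-read evidence marks roughly half of all sites variant at
realistic error rates (1% per read, ≥ 10× coverage) and the filter would
remove the entire genome; a bare maximum-likelihood call without the prior
fails the same way at low coverage, where two error reads out of twelve
already flip the ML genotype. With the prior call the filter removes a few
percent of sites, consistent with its purpose of flagging mismap-prone
neighborhoods. The site itself is excluded from its own neighbor count.

`estimate_filter_fraction_by_sampling` supports the genome-scale situation
where a filter is too expensive to evaluate everywhere: a seeded binomial
subsample with its standard error, exact when the sample covers the stream.

## Candidates, validation and count bounds

Candidates are callable sites with ≥ 1 offspring alternative read, zero
parental alternative reads and DN_p > 0.3, ranked by descending score with
coordinate tie-breaks for determinism. The report annotates each candidate
with its percentile in the trio's own background distribution of QD and
MQRankSum (callable sites with ≥ 1 offspring alt read) and flags likely
false positives at QD < 4 or MQRankSum < −2 — thresholds below which
validated candidates have historically been almost always artifacts.

Manual alignment inspection cannot be automated faithfully, so it is
modeled as an external decision: the pipeline emits the report, the user
returns a status per candidate (`confirmed` / `false_positive` / `failed` /
`untested`). Failed validations might be real mutations, so the observed
count is only bracketed: x_min counts confirmed DNMs, x_max adds failures.
Untested candidates were never advanced and contribute to neither.

## False-negative rate by planting

β is the probability that a true DNM at a callable site scores ≤ 0.3. It is
estimated by assembling synthetic DNM trios from real likelihood triples:
an offspring triple drawn from a donor site where the offspring and at
least one parent are heterozygous (by maximum likelihood), paired with two
parental triples drawn independently from clean sites (no alternative reads
anywhere, all filters passed). Heterozygous donor sites cannot themselves
be callable — a het parent carries alternative reads — so het donors come
from sites passing every filter *except* the parental-alt-read filter. The
two parental draws are independent (whether the original procedure paired
parents from one donor site is unknowable; independence is the simpler
choice and parents' likelihoods are independent given their genotypes
anyway).

Planted trios are scored with the same DN_p and cutoff as real data. The
per-depth miss fractions are combined with weights equal to the fraction of
callable sites at each offspring depth; depths with callable weight but no
planted draws are excluded and the weights renormalized (logged). The
default of 10,000 planted DNMs per trio keeps the standard error of β below
0.005 at plausible values. Because filters are applied before pooling,
donor depths always lie within the 10–100× callable band and no
extrapolation rule is needed.

The generator-based validation shows β falling as offspring coverage rises
from ~12× to 30×. Real data additionally show the FNR *not* vanishing at
high depth (mismapped reads appear as low-frequency alternative alleles and
depress the score); that behavior depends on artifacts the generator only
partially models and is not asserted.

## Rate posterior

Pooled model: ΣX_i ~ Poisson(T·μ) with exposure T = Σ 2·L_i·(1−β_i)
site-generations (the factor 2 counts the two transmitted gametes per
site). The Jeffreys prior μ^(−1/2) — improper, but yielding a proper
posterior for any ΣX ≥ 0 without truncation — gives
μ | data ~ Gamma(ΣX + ½, T). Quantiles come from the Gamma quantile
function; the suite checks them against a 10⁶-draw Monte-Carlo oracle and
the density against the normalized kernel μ^(ΣX−½)e^(−Tμ).

Conservative bounds: 5th percentile of the posterior under x_min, 95th
under x_max. Point estimate: the mean of posterior means over the 2×2
scenario grid (GC filter on/off × count bound), mirroring how a study
reports a single number while acknowledging both uncertainties; the grid is
configurable. Per-trio point estimates x/(2L(1−β)) are reported for
comparison across trios. A pooled run refuses trios filtered under
inconsistent GC settings, since the scenarios would be incoherent.

The high-variant sensitivity utility answers a specific robustness
question: if the density filter removed a fraction f of the genome, a
fold-elevation k of the mutation rate there changes the genome-wide mean by
c = (1−f) + f·k. At f = 0.04, doubling the mean requires k = 26 — filtered
high-diversity regions cannot plausibly bias the estimate much.

## Divergence-time recalibration

Branch lengths in mutations are what sequence data constrain, so a time
estimated under rate r scales to t·r/r′ under rate r′. Interval endpoints
are rescaled conservatively — published lower endpoint with the upper rate
bound, upper endpoint with the lower rate bound — so the recalibrated
interval absorbs rate uncertainty. Default recalibration rates are
4.5×10⁻⁹ (point) with bounds 2.6×10⁻⁹ and 6.2×10⁻⁹; 2.8×10⁻⁹ (the narrower
GC-filtered lower bound) is exposed as `ALT_LOWER_RATE`. The wider 2.6
value is the default because it reproduces the published recalibrated
interval endpoints exactly; published tables mix rounding conventions, so
the reproduction test uses a ±1 ka tolerance, and the table function rounds
to the nearest ka by default.

## Annotation statistics

Subtelomeres are the 5 Mb at each end of an assembled chromosome, closed on
[1, 5·10⁶] and (length−5·10⁶, length]; chromosomes shorter than two windows
are entirely subtelomeric (flagged). Subtelomeric enrichment uses the exact
one-sided binomial upper tail. Chromosomal excess uses a Monte-Carlo
multinomial tail for a caller-specified focal chromosome: because the focal
chromosome is typically identified in the observed data, the uncorrected
per-chromosome tail probability is reported (matching common practice),
with a Bonferroni-adjusted companion value for the skeptical reader. The
substitution spectrum collapses the 12 substitution types onto 6
strand-symmetric classes with transition/transversion totals, compared
against transmitted (inherited) variants passing the same filters.

## Synthetic data generator

The generator emulates exactly the data-generating assumptions the model
makes, which is what makes it a valid end-to-end test harness:

- parental genotypes i.i.d. from the HWE-style prior at `theta_true`
  (default 0.0015, a realistic wolf-scale heterozygosity — distinct from
  the liberal scoring prior);
- Mendelian transmission; a DNM flips one transmitted allele with
  probability 2·`mu_true` at otherwise hom-ref × hom-ref sites (one chance
  per gamete). DNMs at sites where a parent carries the alternative allele
  are not planted: they are undetectable under the definition of a DNM used
  here and would not count toward X;
- per-individual Poisson(`mean_coverage`) depths and Binomial alt counts
  with per-read error `base_error_rate`; likelihoods from the same read
  model the scorer assumes;
- a reference with GC-rich tracts (fraction 0.05, tract GC 75% vs 41%
  background) and repeat intervals (fraction 0.30, roughly a mammalian
  repeat load), emitted as FASTA/BED to exercise the real readers, with
  sites as an all-sites VCF (DP, AD, PL, GL; QD, MQRankSum, gap and
  deletion statistics in INFO);
- labeled artifact channels at small rates (missed parental heterozygote
  0.002, gap reads 0.005, mismap 0.002, deletion 0.002): the false-positive
  sources real pipelines face. A missed-het site regenerates the offspring
  as het and the mother as a hom-ref pileup (allele dropout); mismap sites
  gain low-fraction offspring alt reads and MQRankSum < −2.

Default scale: 10⁵ sites at `mu_true = 1e-4`, 25× coverage, 1% error. The
elevated true rate stands in for genome-scale 10⁻⁹ rates at desk-scale site
counts; the posterior machinery is scale-free in 2L(1−β)μ, so nothing else
changes. Runs are byte-identical under a fixed seed (separate deterministic
substreams for generation and artifact injection).

What passing tests show: the score, filters, FNR estimator and posterior
are internally consistent and recover a known rate with near-nominal
(≈ 90%) interval coverage under the model's own assumptions plus the four
artifact channels. What they do not show: robustness to artifact classes
the generator omits — indels, linked-site LD structure, mapping biases
correlated along the genome, depth-dependent error profiles — or to
miscalibrated base qualities in real genotyper output.

## Numerical choices and degenerate inputs

- All score arithmetic in log space; log-sum-exp normalization; posterior
  normalization tested to 10⁻¹².
- Zero-read individuals get a flat likelihood triple; an all-flat trio
  falls back to the configuration prior (the score still exists, near the
  prior mass of the DNM configuration).
- Genotype-call ties resolve toward hom-ref, the conservative direction for
  de novo screening.
- Empty datasets produce an all-zero callable summary and an empty
  candidate report rather than an error; empty donor pools raise, naming
  the offending pool.
- Candidate ranking ties break by (chrom, pos); every stochastic step takes
  an explicit seed and reports it in the provenance block.

## Known limitations

- Multi-allelic sites, indel DNMs and parental phasing of mutations are out
  of scope; sites are strictly biallelic SNVs.
- β is assumed constant across sites within a depth stratum; systematic
  regional FNR variation (e.g. mappability) is not modeled.
- The per-trio rate model has a single shared μ; inter-individual rate
  variation (e.g. parental-age effects) is not fitted.
- The quality-metric triage thresholds (QD < 4, MQRankSum < −2) are
  empirical heuristics, not calibrated error probabilities.
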