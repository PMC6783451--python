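# Methods

## Model and assumptions

`sexscan` treats sex as a two-level phenotype and asks, site by site,
whether diploid genotype is associated with it. The underlying biological
model is a young or recombination-suppressed sex-determining region in a
heterogametic system: in XY, males carry one Y-restricted haplotype, so
every sex-linked site shows males uniformly heterozygous and females
uniformly in one homozygous class ("strict sex-specific segregation");
ZW mirrors the pattern. The scan assumes unrelated individuals, diploid
biallelic genotypes, and phenotypic sexing that is itself correct —
mislabeled samples break strictness at every linked site, not just one.

Three per-site quantities are computed:

- **Exact association p.** Fisher's exact test on the 2 (sex) × 3
  (genotype class) table, by complete enumeration of tables with the
  observed margins under the multivariate hypergeometric null. The
  two-sided p sums the probabilities of all tables no more probable than
  the observed one, with relative tolerance 1e-7 when comparing
  log-space probabilities (this absorbs floating error in the sums; the
  conventional definition used by the standard association toolkits).
  Computation is in log-factorial space (`scipy.special.gammaln`) and
  cached by table, since a genome scan revisits the same small tables
  millions of times. A closed form anchors the tests: a strictly
  segregating table with unequal strata has p = 1/C(n₁+n₂, n₁) exactly;
  with equal strata the row-swapped table is equally extreme and the
  two-sided sum doubles.
- **Exact Hardy–Weinberg p**, conditioning on allele counts (sum over
  heterozygote counts of the same parity whose conditional probability
  does not exceed the observed one). The scan applies it as a filter
  (default threshold 1e-4) in a configurable stratum. The default scope
  is **females_only** under XY expectations: the homogametic sex is the
  natural control stratum, and an all-heterozygous male stratum must not
  disqualify a true sex-linked site. (At 16 females the all-het female
  configuration sits just above the 1e-4 cut, so the mirrored ZW case is
  not disqualified either.)
- **Strict segregation class** (male_het / female_het / none). The
  homozygous class may be hom-ref *or* hom-alt; requiring hom-ref would
  bake in the reference individual's sex. Both sexes must be genotyped in
  at least `min_call_fraction_per_sex` (default 0.8) of their samples.

A site is reported **sex-specific** iff p < α (default 5 × 10⁻⁸, strict
inequality, the conventional genome-wide threshold used in place of an
explicit multiple-testing correction), the HWE filter passes, call
fractions suffice, and segregation is strict. The heterogametic system is
called from the majority strict class among hits. Missing genotypes
(including half-missing diploid calls) are dropped per site per sex;
multiallelic sites are dropped, never split, because split records would
test configurations never observed as such.

## Linkage-disequilibrium blocks

Pairwise haplotype frequencies for unphased genotype pairs come from the
standard two-locus EM: all genotype-pair cells phase deterministically
except the double heterozygote, whose coupling/repulsion split is
re-estimated each iteration. Initialisation at linkage equilibrium;
convergence when the largest frequency change drops below 1e-10 (cap
1000 iterations). D, D′ = |D|/D_max, and r² follow the usual
definitions; the LOD is log₁₀ of the genotype-likelihood ratio of the
MLE against D = 0.

Confidence bounds on D′ use the grid-likelihood approach of the classic
block-finding program: the genotype likelihood is evaluated on a D′ grid
(step 0.001) with allele frequencies profiled at their MLE and the sign
of D fixed at its MLE sign, the resulting mass is normalised, and the
bounds are the 5th/95th mass quantiles (ci_mass 0.90, two-sided). Grid
step 0.001 keeps the bounds stable to within one step of a 10× finer
grid (tested). One consequence of the quantile definition worth knowing:
a pair whose MLE sits at D′ = 1 can still have an upper bound slightly
below 1 when the likelihood spike at the boundary is thin — which is
exactly why the strong-LD rule asks for CI_high ≥ 0.98 rather than = 1.

Blocks follow the confidence-interval rule with the program's published
defaults, all exposed in `LDConfig`: a pair is strong-LD if CI_low ≥ 0.70
and CI_high ≥ 0.98, strong-recombination if CI_high < 0.90; a candidate
block is a marker interval whose endpoint pair is strong-LD and in which
≥ 95% of informative pairs (strong-LD + strong-recombination) are
strong-LD; candidates are accepted greedily by descending bp span
(ties: more markers, then smaller start) without overlap. Markers need
MAF ≥ 0.05 (sex-linked sites in a balanced cohort have MAF ≈ 0.25 and are
unaffected); pairs farther apart than 500 kb are skipped to bound cost.
Block spans and all region sizes are 1-based inclusive
(end − start + 1) — the convention forced by the published tables' own
arithmetic, where every printed block size equals end − start + 1.

The pipeline runs block-finding only on scaffolds carrying more than ten
sex-specific sites, over the sex-specific region widened by 5 kb per
side. All eligible markers there participate, not only significant ones —
the published block bounds start upstream of the first significant site,
which settles that design question. The marker region is the largest
block among eligible scaffolds (tie-break: more member sex-specific
sites, then scaffold name); a "most sites first" metric is available as a
config switch. Because background markers interleave real LD blocks, the
selected block is usually narrower than the full sex-specific region;
reports therefore carry both "in region" and "in block" counts.

## In-silico PCR assay

The binding model is sequence matching, not thermodynamics: a primer
binds where its 3′-terminal 3 bases match exactly and total mismatches
are ≤ 2; every primer in the mix is tried on both strands; any convergent
plus/minus binding pair within 2,000 bp yields a product whose length is
measured between the outermost 5′ ends, inclusive. Duplicate lengths are
deduplicated per haplotype. Off-target artefact bands are out of scope.
Per-sample templates are built from the reference plus the sample's
genotypes; heterozygous sites put the alternate allele on the second
haplotype, which for a single sex-linked region matches the gametologue
structure.

Calling rules: *size dimorphism* (two distinct product lengths → male,
one → female, none → undetermined) and *presence* (target and control
product → male; control only → female; no control → undetermined —
the three-state call exists because amplification failure must be
distinguishable from true absence). Accuracy counts undetermined as
incorrect, conservatively. Under the size rule on a strictly segregating
heterozygous indel with no genotyping error, accuracy is exactly 1 by
construction; with per-call error e, a het male is miscalled with
probability e and a hom female with probability e/2 (only the flip to het
fakes a double band), which the tests assert as the exact expectation.

## Synthetic cohorts

The simulator generates the statistical structure the analysis assumes,
as a stand-in for archived re-sequencing data: 16 females + 15 males by
default, five 2-Mb scaffolds, 10⁴ background biallelic SNPs with
alt-allele frequency drawn from Beta(1, 3) truncated to [0.05, 0.5]
(truncation keeps background sites above the LD module's MAF filter) and
genotypes drawn under HWE independently of sex; a planted core of 30
sites (mean spacing 200 bp ≈ 6 kb, matching the scale of the real
candidate region) where segregation is strict by construction; and 10
flank sites where each sample receives the sex-determined genotype with
probability 1 − `flank_leak_prob` and a background draw otherwise.
`flank_leak_prob` defaults to 0.5: analysis of the leak model shows that
at 0.3 a flank site comes out fully strict by luck in ~0.5–1% of
cohorts (which would silently extend the recovered region beyond the
core), while at 0.5 the probability is below ~10⁻⁴ per site — flanks
then behave as the intended partially associated shoulder. One middle
core site is an 8-bp deletion by default, giving the size-dimorphism
assay a target. Genotyping error resamples uniformly among the two wrong
genotype classes (the simplest model that can break strictness);
missingness is applied after error. All randomness flows from one seed
through named substreams, so outputs are byte-identical per seed.

What the simulator does **not** model: background LD, relatedness,
demography, read-level error structure, reference bias, multiallelic
sites beyond none, and structural variation other than the single planted
indel. Passing recovery tests therefore show the statistical chain is
correct under its own assumptions — not that a real cohort is free of the
artefacts (assembly errors, cryptic relatedness, mis-sexed gonads) that
complicate real surveys.

## Validation choices and problem sizes

The genome-scale survey (3 × 10⁷ sites, 444 scaffolds) is replaced by
parameter recovery at 10⁴ background sites over five scaffolds — large
enough that a false positive anywhere would be seen (the per-site chance
of a background HWE table mimicking strict segregation at p < 5 × 10⁻⁸
is ≲ 10⁻¹⁰), small enough to run a 100-seed experiment in minutes. The
recovery criteria: exact region-bound recovery and planted-scaffold block
selection in ≥ 95/100 seeds, zero background false positives in
≥ 99/100. The packaged published catalogue (51 marker-region variants
with per-sex genotype counts; 15 per-scaffold summary rows) is used as a
worked example: re-running the test and classifier on those printed
configurations must reproduce the printed p-values, flags, and counts.

Degenerate inputs: an empty sex stratum is a hard error from the exact
test (and propagates out of a scan); monomorphic sites get HWE p = 1 and
association p = 1; pairs monomorphic among shared genotyped samples are
flagged uninformative rather than erroring; an empty re-scan window
returns an empty list.

## Known limitations

- The exact 2×3 enumeration is complete, not network-accelerated; it is
  fast because cohort margins are small (tens of samples) and cached —
  not suitable for thousands of samples per stratum.
- D′ confidence bounds profile allele frequencies at their MLE rather
  than maximising jointly per grid point (the reference program's
  behaviour, but an approximation all the same).
- The PCR model knows nothing of melting temperature, secondary
  structure, or competitive amplification; primer *design* beyond simple
  flank extraction is out of scope.
- The heterogametic-system call is a majority vote over strict hits; a
  genuinely mixed or polygenic system would be reported as whichever
  class dominates, with the minority visible in the per-site table.
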