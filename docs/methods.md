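# Methods

## Model and assumptions

`assortmate` tests, locus by locus, whether observed mate pairs are more or
less genetically similar than random pairing would produce. The data are a
cohort of diploid individuals genotyped at biallelic SNPs, and one or more
sets of observed (female, male) mate pairs, each set belonging to one
mating category.

Genotypes are reduced to **minor-allele dosage**: the count (0/1/2) of the
rarer allele, with the minor allele fixed once per locus from allele
frequencies over *all* genotyped individuals in the loaded cohort (not per
mating group), so the two groups are compared at the same encoding. On an
exact 0.5 frequency tie the alternate allele is designated minor; the
sharing statistic is invariant to that choice because the relabeling
d → 2 − d leaves |d₁ − d₂| unchanged. Missing genotypes are explicit
(`MISSING`) and never imputed.

The per-pair **shared-allele score** is s = 2 − |d₁ − d₂|, which equals the
number of allele classes the two genotypes share (0, 1, or 2); the test
statistic at a locus is the mean of s over pairs with both members
genotyped there. The **null** holds genotypes fixed and randomizes pairing
only: each replicate assigns every female in the pair set a male drawn
uniformly at random, *with replacement*, from the multiset of males
appearing in the pair set (males can mate multiply, and re-pairing is not
forced to be one-to-one). Replicate means obey the same both-genotyped
rule as the observed mean. The observed mean's percentile within the
replicate means — mid-rank for ties — classifies the locus as negative
(below the lower cutoff), positive (above the upper cutoff), or none. No
multiple-testing correction is applied; the tails are reported raw, so
under pure randomness about 5% of loci are flagged by construction.

An alternative null (`null_scheme="single-pairs"`), in which the null
distribution consists of single random-pair scores rather than replicate
means, is available for sensitivity analysis; it is far more dispersed and
not used by default.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `n_permutations` | 50,000 | null replicates per locus |
| `lower_cutoff` / `upper_cutoff` | 0.025 / 0.975 | percentile cutoffs (strict inequalities) |
| `min_pairs_per_locus` | 2 | fewer fully genotyped pairs → locus reported unclassified |
| `rng_seed` | 0 | base seed; per-locus streams are derived from (seed, locus ordinal), so results do not depend on processing order |

## Filter chain

The post-calling cleanup runs paralog blacklist → individual missingness →
site mean depth → site missingness, with strict threshold comparisons
("more than", "less than") throughout:

* individuals with > 20% missing genotypes removed;
* sites with mean total read depth < 5 or > 30 removed (individuals with a
  missing genotype are excluded from the mean by default; a switch counts
  them as zero depth);
* sites with > 80% missing genotypes removed;
* the paralog blacklist flags loci with heterozygosity H > 0.6 or
  read-ratio deviation D outside [−5, 7], where H is the heterozygote
  fraction among genotyped individuals and D = (a − b)/√(a + b) with a, b
  the ref/alt read counts pooled over heterozygotes. Under unbiased
  sequencing of a single locus the heterozygote read split is
  Binomial(n, ½), making D approximately standard normal; collapsed
  paralogs show up as excess H and |D|. Loci with no heterozygote reads
  get D = 0 and are judged on H alone.

Each removed site is counted by the first stage that removes it, so the
report identity `n_out = n_in − paralog − depth − missing` always holds.
The chain is a single-pass approximation of the two-pass
call/blacklist/re-call procedure used with a genotype caller. Re-running
the chain on its own output is a no-op for realistic data; the one
exception is pathological inputs where site removal pushes an individual's
missing fraction across the individual-level threshold on the second pass,
because individual missingness is evaluated before the site filters.

## Synthetic data

The generator emulates the structure of a two-generation GBS study: per
locus a minor-allele frequency q ~ U(0.05, 0.5) (the floor keeps sharing
scores informative), Hardy–Weinberg genotypes, negative-binomial total
depths (mean 15 — inside the depth-filter window — dispersion 5),
Binomial(depth, ½) heterozygote read splits, 5% per-cell missingness, and
150 females × 150 males with 150 observed pairs per mating category,
matching the scale of a moderate salmon run. Optionally the last fraction
of loci is simulated as collapsed paralogs (heterozygote rate 0.8, alt-read
fraction 0.2) to exercise the blacklist.

Assortment is injected through a weighted mating law: the probability of
observing pair (f, m) is proportional to ∏ over designated loci of
exp(±β·s), with + for positive and − for negative direction and missing
genotypes contributing a neutral factor; β = 0 everywhere reduces exactly
to uniform random pairing. Because observed pairs are unique mating
combinations, the law is sampled *without replacement*, done exactly via
Gumbel top-k over the female × male grid. This was chosen over sequential
propose/reject sampling, which targets the same distribution but stalls
when many strong loci make the weights concentrated (at 40 loci with β = 2
the implied acceptance rate is ~10⁻⁵–10⁻⁴), and over with-replacement
categorical sampling, which at those strengths collapses the pair list
onto a handful of distinct pairs.

What the generator does **not** model: linkage disequilibrium between loci
(all loci independent), population structure or relatedness, genotyping
error, locus dropout correlated with genotype (missingness is uniform),
and the parentage-inference step that produces real mate-pair tables.
Passing tests on synthetic data therefore show the statistic and its
calibration are implemented correctly under the stated model; they do not
validate robustness to structure, LD, or pedigree error in field data.

## Statistical behaviour and numerical choices

* **Calibration.** On simulated random mating (1,000 loci, 150 pairs,
  5,000 replicates) the flag rates are close to, and slightly below, the
  nominal 2.5% per tail (measured ~1.3–2.6%). The test is mildly
  conservative for two reasons: the with-replacement null is somewhat
  wider than the conditional distribution of an observed pairing (which
  uses each male slot exactly once), and mid-rank tie handling at
  low-frequency loci pulls percentiles toward 0.5. Both conventions are
  kept deliberately — they match the test as defined above and err on the
  side of fewer false flags.
* **Power.** With 20 loci per direction injected at β = 2 among 1,000
  loci, roughly 70–95% of injected loci (≈80% on average across seeds) are
  recovered in the correct direction. Failures concentrate at minor-allele
  frequencies below ~0.2: when many strong loci compete for a fixed set of
  unique pairs, the few carriers of a rare allele are exhausted and the
  realized tilt at that locus falls short of the marginal exp(±βs).
* **Percentile ties** are resolved by the mid-rank convention
  ((below + ½·equal)/n), keeping a degenerate null (e.g., a locus where
  every individual is heterozygous) at exactly 0.5. Replicate-mean
  equality is tested with an absolute tolerance of 1e−12 to absorb
  floating-point rounding of equal rationals.
* **Sparse loci.** Replicates leaving fewer than `min_pairs_per_locus`
  fully genotyped assignments are redrawn (bounded); loci whose *observed*
  pair count is below the floor are emitted unclassified with a flag
  rather than dropped, so result tables always cover the locus universe.
* **Cross-group shared percentage** uses the sum of the two groups'
  flagged counts as denominator (100·shared/(n_A + n_B)), not the union.
  The union would be the more conventional overlap measure; the sum
  convention is the one the reported percentages follow, and it is
  implemented in one place (`compare.shared_percentage`) and documented
  here prominently. Percentages are rounded half-up to two decimals.
* **Coordinates** are 1-based inclusive everywhere (VCF/GFF3 native);
  gene containment is inclusive on both ends, with no upstream or
  downstream extension, using GFF3 `gene` features only. Strand is
  ignored for containment.
* **Scale of shipped analyses.** The test suite and the reproduction
  script run the permutation scan at 5,000 replicates over 1,000 loci —
  the package's chosen desk-scale configuration; production runs default
  to 50,000 replicates.

## Known limitations

* The permutation null conditions on the male multiset of the pair set; it
  does not model uncertainty in parentage-inferred pairs.
* Filter-chain idempotence caveat described above.
* The comparison module reports raw overlap counts only; no test of
  whether overlap exceeds chance is implemented.
* Multiallelic records are skipped, not split; the sharing statistic is
  defined only for biallelic sharing classes.
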