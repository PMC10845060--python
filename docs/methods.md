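# Methods

## The problem

An "Arizona search" scans every unordered pair of profiles in a forensic STR
database and tabulates how many pairs share k alleles, how many loci match at
both alleles ("fully matching"), and how many match at exactly one allele
("partially matching"). Access to real forensic databases is tightly
restricted, so such searches are increasingly performed on genotypes
*imputed* from SNP data. This package implements the search itself and the
machinery to quantify how faithfully an imputation-based search reproduces a
search on true genotypes, in two variants:

* **Scheme 1 (called genotypes).** Each haplotype's allele is called as the
  argmax of its imputation posterior; the search then proceeds on the called
  integer genotypes exactly as on true ones.
* **Scheme 2 (expected counts).** The per-haplotype allele-probability
  vectors are used directly: for each pair and locus the exact probabilities
  of a full, partial and non-match are computed, and per-pair *expected*
  match counts are obtained by summing over loci.

## Match model

Matching at a locus is the multiset intersection of the two diploid allele
pairs: `|{a1,a2} ∩ {b1,b2}|` ∈ {0, 1, 2}, independent of phase. For two
size-2 multisets this equals the better of the two one-to-one haplotype
pairings, `max((a1==b1)+(a2==b2), (a1==b2)+(a2==b1))`, which is what the
vectorized kernels evaluate. Over L loci, k = 2m + p always holds for
integer genotypes.

For Scheme 2, let A1, A2 (and B1, B2) be the haplotype allele-probability
vectors of individuals A and B at a locus with N alleles, with the ordered
genotype i|j having probability `A1_i·A2_j`. The probability of each match
category is a double sum over A's ordered genotypes, split into the i = j and
i ≠ j cases; `locus_match_probabilities` implements those sums literally.
Expanding and collecting terms yields an O(N) inner-product form used by the
all-pairs engine (`locus_match_probabilities_fast`): with
`s_gh = Σ_i A_g,i B_h,i`, `w = Σ_i A1_i A2_i B1_i B2_i`,
`u1 = Σ_i A1_i B1_i B2_i`, `u2 = Σ_i A2_i B1_i B2_i`,
`v1 = Σ_i A1_i A2_i B1_i`, `v2 = Σ_i A1_i A2_i B2_i`:

    P_full = s11·s22 + s12·s21 − w
    P_none = 1 − s11 − s12 − s21 − s22 + s11·s22 + s12·s21
             + u1 + u2 + v1 + v2 − 3w
    P_partial = 1 − P_full − P_none

The equivalence of the literal sums, the inner-product form, and a
brute-force enumeration of all N²×N² ordered genotype pairs is asserted to
1e−12 in the test suite; the enumeration (`enumerate_locus_matches`) is the
independent oracle and plays no part in production paths.

Assuming independence of match outcomes across loci (linkage equilibrium),
the bivariate distribution π\_{m,p} of fully and partially matching locus
counts is built by the standard recursion for sums of independent trinomial
outcomes, locus by locus, stored dense on the (L+1)×(L+1) triangle. Per-pair
expected counts are computed by linearity (`e_full = Σ_l P_full^l` etc.),
which is what the all-pairs engine reports; the full per-pair π distribution
is available behind a flag (`run_search(..., full_distribution=True)`,
refused above 50,000 pairs) since expectations are the per-pair quantity a
study reports.

## Study design

A study run splits the panel into a reference fraction (default 0.6 — the
part that would inform imputation; it takes no part in the search) and a
database on which the all-pairs search runs; the reference size is
`floor(fraction·n)`, which for n = 2,504 at 60/40 gives 1,502/1,002 and
501,501 database pairs. Replicate r draws its partition from the child seed
stream `(base_seed, r)` of a `numpy` `SeedSequence`, so replicates are
mutually independent but individually reproducible, and the same splits are
shared by all schemes within a replicate. Summary statistics (median and
maximum of each variable per scheme) are computed after pooling all
replicates' per-pair records into one vector — no per-replicate averaging;
the median of an even-length vector is the mean of the two central order
statistics.

## Concordance

Pair-level agreement between an imputed search I and the true search T is
summarized, per variable, by:

* Spearman's ρ with average ranks for ties (delegated to
  `scipy.stats.spearmanr`; an independent rank-then-Pearson oracle backs it
  in the tests);
* the median and 90th percentile of |E|, E_i = I_i − T_i, using numpy's
  linear interpolation between order statistics (the 90th percentile depends
  on this convention, hence it is fixed and documented);
* the Hodges–Lehmann estimator θ̂ = median{(E_i+E_j)/2 : i < j}, the median
  of Walsh averages over *distinct* index pairs (the diagonal is excluded).
  Walsh pairs are enumerated exactly up to 5×10⁷ pairs; beyond that a seeded
  uniform subsample of 10⁷ unordered pairs is used (501,501 differences give
  ≈1.26×10¹¹ Walsh pairs — enumeration is infeasible), with a flag to force
  the exact path. On vectors of length 2,000 the subsampled estimate agrees
  with exact enumeration to well under 0.05 in the tests.

## Synthetic data

The generator produces the statistical structure the analysis assumes, not a
simulation of imputation itself:

* **Allele frequencies** per locus are symmetric Dirichlet draws
  (concentration 1.0 by default — markedly uneven vectors, as real STR loci
  show); allele counts per locus are drawn uniformly from 6–14, spanning
  typical forensic STR marker sets. Allele labels are consecutive synthetic
  repeat lengths, carried as metadata only.
* **Genotypes** are Hardy–Weinberg draws per locus, independent across loci
  (linkage equilibrium) — exactly the independence the multi-locus recursion
  assumes.
* **Posteriors** for a haplotype with true allele t are
  `λ·δ_t + (1−λ)·q`, `q ~ Dirichlet(c·f)` centered on the locus frequencies
  f with concentration c (default 20). λ = 1 gives point masses on the
  truth; λ = 0 gives posteriors independent of the truth fluctuating around
  the population frequencies, mimicking an imputation engine falling back to
  reference-panel frequencies when flanking-marker information is weak.
  The default λ = 0.9 represents a high-accuracy imputation.

What this generator does *not* emulate: per-site heterogeneity of imputation
confidence, SNP haplotypes and recombination, population structure,
relatives, genotyping error. One consequence worth knowing: because the
point-mass weight λ is constant, the argmax call equals the true allele with
certainty whenever λ > 0.5, so Scheme 1 is exactly error-free at the default
accuracy and only degrades for λ < 0.5; real imputation posteriors, whose
confidence varies across sites and individuals, produce occasional confident
miscalls that this model cannot. Passing tests on synthetic data therefore
validate the *search and concordance machinery* — not any claim about the
accuracy of a particular imputation engine on real panels.

## Numerical choices

* Probability vectors whose sum deviates from 1 by ≤ 1e−6 (format round-off)
  are renormalized; larger deviations raise. The AP reader clamps negative
  REF remainders within 1e−6 to zero before renormalizing; the AP writer
  rounds in integer micro-units and repairs any rounding overflow so its own
  files always re-read cleanly.
* Argmax ties in genotype calling break toward the smallest allele index —
  deterministic, hence reproducible runs.
* Pairs are emitted in lexicographic (i, j) order, i < j, and floats are
  written with fixed 6-decimal formatting, so identical configs give
  byte-identical outputs.
* A locus with a single allele is permitted and contributes P_full = 1.
* Per-locus match probabilities are clipped to [0, 1] against round-off
  before the complement is taken; deviations are below 1e−12.

## Problem sizes

The bundled acceptance script runs the full 2,504-individual, 18-locus study
at the 60/40 split with 2 replicate splits and 10⁷-pair Hodges–Lehmann
subsampling — large enough to pin the partition arithmetic and pooled
statistics while completing on a laptop in about a minute. The test suite
uses smaller panels (tens to hundreds of individuals) chosen as the smallest
sizes at which each property is non-trivially exercised.

## Limitations

* Match probabilities assume independence across loci; linked loci would
  need a joint model the recursion cannot express.
* The pipeline consumes imputation output (AP fields or synthetic
  posteriors); it never runs imputation, and GP (genotype-probability)
  fields are not parsed — Scheme 2 is defined on per-haplotype allele
  probabilities.
* Mixture/partial profiles, null alleles, stutter and three-allele genotypes
  are out of scope; profiles missing a locus are rejected, not skipped.
* Querying an external profile against the database (the operational
  forensic use-case) is not implemented; the analysis concerns
  within-database pairs only.
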