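# Methods

## The two-locus gamete-elimination model

The model explains distorted F2 segregation at a pair of duplicated,
functionally redundant loci segregating functional (F) and loss-of-function
(n) alleles. A gamete or zygote needs a functional copy at *at least one*
of the two loci; the doubly-null combination is selected against. Three
viability parameters and one linkage parameter describe the system:

| parameter | meaning | range | default |
|---|---|---|---|
| `tau_m` | viability of the doubly-null gamete through pollen | [0, 1] | 1 |
| `tau_f` | same through ovules | [0, 1] | 1 |
| `v` | viability of the doubly-homozygous-null zygote | [0, 1] | 1 |
| `r` | recombination fraction between the loci | [0, 0.5] | 0.5 |

The F1 is doubly heterozygous; in the reference cross the phase is
*repulsion* (each parental haplotype carries one functional and one null
allele on opposite loci), so the doubly-null haplotype is a recombinant
produced at rate `r/2`. Coupling phase is available for completeness.
Gamete frequencies before selection are `(1-r)/2` for each parental and
`r/2` for each recombinant haplotype; selection multiplies the doubly-null
haplotype by `tau_sex` and renormalizes. Zygote frequencies sum the
products of the two sex-specific gamete distributions over all 16
combinations; `v` multiplies the doubly-homozygous-null class before a
final renormalization. With `tau_m = tau_f = v = 1` the model is exactly
the Mendelian dihybrid for any `r`.

`v` is applied only to the doubly-homozygous-null zygote class: germination
failure and severe weakness are reported only for genotypes lacking a
functional copy altogether, and modelling milder vigor differences in other
classes would add parameters the 3- or 9-class data cannot identify.

**Class ordering.** The joint 3x3 matrix is indexed by the count of
functional alleles per locus (2, 1, 0). The reference cross displays
marginals in parental orientation — recurrent-parent homozygote first — and
under repulsion the recurrent parent carries the *null* allele at locus 1,
so its displayed locus-1 marginal is the reverse of functional order.
`locus_marginal(..., orientation="parental")` reproduces that display; all
arithmetic is done in functional order.

**Fitting.** `fit_transmission` maximizes the multinomial log-likelihood
over a chosen free-parameter subset (default `tau := tau_m = tau_f` and
`v`, with `r` fixed at 0.5 since the loci sit on different chromosomes).
Because zygotes do not record which gamete came from which parent, the
likelihood is symmetric in `(tau_m, tau_f)`; the pair is identifiable only
up to exchange, and marginal 3-class data carry two degrees of freedom so
at most two free parameters are accepted for them. The optimizer is a
coarse grid (step 0.01 per free parameter, vectorized) followed by
Nelder-Mead refinement clipped to the unit box — fully deterministic, with
grid ties broken toward smaller parameter values.

**Recovery study design.** The parameter-recovery experiment simulates
joint 9-class counts at n = 10,000 with truth `tau = 0.8, v = 0.2`.
Information about `v` comes only from the doubly-homozygous-null class,
whose expected frequency is roughly `(tau * r / 2)^2 * v`, so `tau` must be
substantial for `v` to be estimable; and `tau` and `v` are anticorrelated
through that same cell. An exact Fisher-information calculation at this
truth gives per-parameter standard errors of about 0.020 (`tau`) and 0.022
(`v`) and a joint probability of 0.96 that both estimates fall within
±0.05, which the 100-replicate experiment is designed to demonstrate. The
low `v` also reflects the biology being modelled — doubly-null zygotes are
described as largely inviable.

**Cross compatibility.** A cross of two pure lines is predicted
incompatible exactly when the parents differ in functionality at *both*
loci (one contributes a null at locus 1, the other at locus 2): only then
is the F1 doubly heterozygous for loss-of-function and able to produce
doubly-null recombinant gametes. With the three observed allele classes
(I: functional/functional, II: functional/null, III: null/functional) the
only incompatible pairing is II x III.

## Synonymous divergence and dating (NG86)

Pairwise Ka/Ks uses Nei-Gojobori (1986) counting with a Jukes-Cantor
multiple-hit correction — a deterministic closed-form method that an
independent oracle can check, in contrast to ML codon models. Per codon
position, the synonymous site fraction is the number of synonymous
single-base changes divided by the number of changes not creating a stop
codon (stop-creating changes are excluded from the denominator); site
counts `S` are averaged over the two sequences and `N = 3L - S`. For
codons differing at k positions, difference counts average over all k!
substitution orderings, skipping pathways through stop codons (if every
pathway is blocked, all are used). `pS = Sd/S`, and
`dS = -(3/4) ln(1 - (4/3) pS)`; the correction is undefined at `pS >= 3/4`
and a saturation error is raised. Gap- or N-containing codon columns are
dropped pairwise before counting, with the dropped count logged.

Divergence times use the molecular clock `T = Ks / (2 lambda)` with the
grass synonymous rate `lambda = 6.5e-9` substitutions/site/year by default
(overridable). The modal Ks of a distribution (e.g. of single-copy
ortholog pairs between two populations) is the argmax of a Gaussian kernel
density with Silverman bandwidth on a 512-point grid spanning the data
range; at least 10 values are required, and a zero-variance input returns
the common value directly.

## ILS vs introgression

Both incomplete lineage sorting and introgression make a gene tree
disagree with the species tree; they differ in *when* the discordant
alleles coalesce. ILS requires the coalescence to predate the species
split (an older time); introgressed alleles coalesce after it. The
decision rule compares the gene's dated coalescence `t_gene` with the
species split `t_split` under a relative tolerance band (default 0.1,
since no formal uncertainty treatment is attached to the point times):
ILS when `t_gene > t_split * 1.1`, introgression when
`t_gene < t_split * 0.9`, ambiguous between. The rule is scale-invariant,
so times may be supplied in years or MY consistently.

Quartet topologies are called from pairwise distances by the four-point
condition: among the three pairings of ingroup taxa, the sister pair
minimizes `d(x, y) + d(z, outgroup)`; the support margin is the gap to the
second-best sum, and ties resolve lexicographically with margin 0. This
deterministic distance call replaces a full ML tree search because only
the sister-pair topology feeds the downstream decision.

`ils_scan` composes the pieces: `t_split` from the Ks peak of a
single-copy ortholog cohort, `t_gene` per locus from its pairwise dS, one
time comparison per locus; saturated loci are flagged rather than dropped.

## D and fd scans

Site pattern weights use the frequency form with derived (alt) allele
frequencies `p1..p4` in P1, P2, P3, outgroup:
`abba = (1-p1) p2 p3 (1-p4)`, `baba = p1 (1-p2) p3 (1-p4)`. The outgroup
enters through `(1-p4)` rather than being assumed fixed. D sums
`(abba - baba)/(abba + baba)`; significance uses a delete-one block
jackknife (1-Mb blocks by default, >= 10 non-empty blocks; zero SE yields
a signed infinite Z).

fd is computed in windows (default 300 kb, non-overlapping; step is
configurable). A *good site* has defined frequencies in all four
populations, genotyped fraction >= 0.2, and is not monomorphic everywhere.
Windows need >= 100 good sites. The denominator recomputes the numerator
with both p2 and p3 replaced by the per-site donor `pD = max(p2, p3)`
(dynamic-donor variant); fd is reported missing when the window numerator
is <= 0, per the statistic's published domain. Outlier windows are those
at or above the 99.5th percentile (linear-interpolation quantile) of the
non-missing genome-wide fd values; fewer than 200 non-missing values give
an empty outlier set, and threshold ties beyond the nominal 0.5% are
truncated to the lexicographically first indices with a logged warning.

Because missing values are excluded, and a null window's numerator is
positive with probability ~1/2, roughly half of null windows carry no fd;
the top 0.5% of the *non-missing* distribution therefore covers only
~0.25% of all windows. The power analysis consequently measures recall of
introgressed windows against the 99.5th percentile of the truth-null
windows' fd (the matched-null calibration), while the top-0.5% rule itself
is validated on pure-null scans, where it flags ~0.5% of non-missing
windows by construction.

## Diversity, LD, association

Per-site diversity is the unbiased pairwise heterozygosity
`2k(n-k)/(n(n-1))`; window π divides the site sum by the full window
length (5 kb default), counting monomorphic and uncalled positions as
zero — the convention of the standard VCF window-π tools — with an
optional accessible-length override via `region_end`. Missing genotypes
are never imputed; they reduce per-site called-allele counts.

LD r² treats each sample's two haploid calls as independent observations
(the unphased haploid-expansion approximation; no EM haplotype-frequency
estimation), using only haplotypes called at both sites. The association
test is the 1-df allelic Pearson chi-square on the case/control x alt/ref
allele-count table without continuity correction.

## Synthetic data

The generators produce the minimal sufficient structure each estimator
consumes, with one global seed and per-generator streams derived by
SHA-256 hashing of `(seed, generator name)`; every dataset is bit-for-bit
reproducible and carries a `SimTruth` sidecar (JSON) with parameters and
truth labels.

- **F2 counts** are multinomial draws from the model's joint class
  frequencies (reference population size 226, as in the cross that
  motivated the model; n = 10,000 for recovery studies).
- **Quartet alignments** evolve sites independently under Jukes-Cantor
  down a fixed quartet shape (root at the ingroup ancestor, outgroup
  attached directly), so p-distances are JC-consistent with path lengths.
- **Admixed windows** manipulate allele frequencies directly rather than
  running a coalescent: null windows draw P1 and P2 exchangeably around a
  shared ancestral frequency (uniform on [0.05, 0.95] plus N(0, 0.05)
  noise), P3 independently from the same marginal, and the outgroup from
  Beta(1, 19) (mean 0.05); introgressed windows mix `f` of P3 into P2
  site-wise. Because D/fd consume only frequencies, this is the minimal
  structure that gives exact null calibration; it does not model linked
  drift, selection or demography, so passing tests show estimator
  correctness, not robustness to realistic genome complexity. Design
  sizes: 60 windows x 150 sites for null-Z calibration, 600 x 300 with
  introgression fraction 0.005 and f = 0.2 for power, 1000 x 200 for the
  outlier-rate check.
- **Codon pairs** draw ancestors uniformly from sense codons and apply
  Poisson((d/2) x sites) synonymous/nonsynonymous events per lineage by
  rejection sampling over single-base changes (stop-creating changes
  rejected), bounding divergence below the saturation point.
- **SNP regions** place Poisson(theta x L x a_n) segregating sites
  uniformly with derived counts ~ 1/k (the neutral frequency spectrum), so
  expected per-site π equals theta; there is no linkage or recombination
  structure.

## Numerical choices and limitations

- Probabilities are renormalized after each selection step; the model-vs-
  enumeration agreement is checked to 1e-12 over a 375-point grid against
  an exact-rational oracle.
- The chi-square goodness of fit is the plain Pearson statistic with
  upper-tail p; no continuity correction anywhere.
- Quantiles use numpy's linear interpolation; KDE bandwidth is Silverman.
- Window coordinates are 0-based half-open internally, 1-based inclusive
  in user-facing output; windows anchor at 0 and tile to the last variant.
- The four-point call assumes additive distances; very short internal
  branches give small margins and lexicographic tie-breaks.
- Times compared by `classify_discordance` carry no confidence intervals;
  the relative-tolerance band is a conservative surrogate, not a test.
- All estimators assume the JC/NG86 model family under which the
  generators simulate; real data violating those assumptions (rate
  variation, transition bias, selection) will bias dS and the dated times.
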