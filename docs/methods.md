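# Methods

This note documents the models and numerical conventions behind `sweeptx`,
the defaults and why they were chosen, and what the synthetic-data tests do
and do not demonstrate about real data.

## Data model and coordinates

All internal coordinates are 1-based closed intervals, matching VCF and GFF3;
conversion to 0-based half-open happens only when writing BED. Genotypes are
held as an `(n_variants, n_samples, 2)` int8 array of haplotype allele codes
(0 ref, ≥1 alt, −1 missing) with a per-genotype phased flag. A missing
genotype `./.` loads as missing on both haplotype slots; an unphased
heterozygote `0/1` loads but is rejected by the haplotype stage (see XP-EHH).
Gene length is the merged-exon total, falling back to the gene span when a
gene has no exon children.

## Variant QC

Retention requires, simultaneously: biallelic (exactly one ALT), calling
rate strictly above 0.90 and QUAL strictly above 30. Both thresholds follow
the conventional "> 90%" / "> 30" wording, so values exactly at the threshold
are dropped. Call rate is defined over samples — a sample counts as called
iff both haplotype slots are non-missing — and is computed across all
samples by default (`call_rate_scope="per_pop"` switches to the minimum of
the two cohort rates). Downstream scan statistics use SNPs only by default
(`snps_only=False` admits INDELs; they are retained by QC either way).
Filtering is idempotent and order-preserving.

## Window engine

Windows are 100 kb sliding by 50 kb: starts at 1, 1+step, … while the start
is at most the chromosome length, the final windows truncated at the
chromosome end, and truncated windows shorter than one step dropped (a
chromosome shorter than one step still gets a single window). A variant
belongs to a window when its position lies in the closed interval, so a
variant at a window boundary contributes to both overlapping windows. Every
per-window statistic requires `min_snps` (default 10) contributing SNPs and
is NA otherwise; NA windows are excluded from Z-transformation and
quantile/threshold computation. The default guards against noisy estimates
in sparse windows; there is no canonical published value.

## Scan statistics

**Pooled heterozygosity.** `H_P = 2 Σn_MAJ Σn_MIN / (Σn_MAJ + Σn_MIN)²`
where the sums run over a window's SNPs and `n_MAJ`/`n_MIN` count the
more/less frequent allele among called haplotypes of one population (ties at
50/50 resolve to the reference allele for determinism). `H_P ∈ [0, 0.5]`,
low in swept windows. It is computed per population; outlier calling uses
population A (the focal breed).

**F_ST.** The Weir–Cockerham (1984) two-population variance-component
estimator per SNP, computed from fully-called diploids (allele frequency,
observed heterozygosity and sample size per population). Negative estimates
are retained, not clamped; sites with zero total variance components
(monomorphic in both populations) or fewer than two called haplotypes in a
population are NA. The window statistic is the arithmetic mean of per-SNP
estimates (average-of-ratios, the convention in this pipeline family);
the alternative ratio-of-averages can be formed from the exposed per-SNP
values if desired.

**Z-transformation.** Per statistic, genome-wide across all scanned
chromosomes: `z = (x − mean)/sd` with the population (n-denominator) sd over
non-NA windows. The choice of denominator is immaterial at genome scale and
is fixed for determinism.

**XP-EHH.** At each core SNP, EHH at marker k is the probability that two
haplotypes drawn without replacement from one population are identical at
every variant from the core out to k (the core's allele is part of the
identity check; EHH at distance 0 is 1 by definition, and the curve is
non-increasing because each marker refines the partition). iHH is the
trapezoid integral of EHH over physical distance, run separately left and
right and summed, stopping where EHH first falls below 0.05 with the
crossing point linearly interpolated. Cores whose EHH has not decayed below
the cutoff within 1 Mb (`max_extent`), or before markers run out (e.g. at a
chromosome end), are unresolved (NA). XP-EHH = ln(iHH_A / iHH_B), using all
haplotypes per population at the core (no core-allele stratification — the
cross-population construction, unlike iHS). The raw log-ratio is reported
without variance standardisation: outlier calling uses an empirical
quantile of the windowed mean, so the scale does not affect flagging.
Distance is physical bp under an implicit uniform recombination assumption;
no genetic map is supported. Sites with missing data in either population
are dropped before EHH; unphased heterozygous genotypes raise an error
(pseudo-phasing is out of scope). `ihh()` also exposes no-interpolation and
gap-rescaling options matching the integration conventions of common scan
tools, used for cross-checking only.

## Outlier calling and candidate genes

For each statistic the cutoff is the order statistic such that exactly
`floor(0.05·N)` of the N analyzable windows lie strictly beyond it when
values are distinct; flagging is strictly beyond the cutoff, so ties at the
cutoff are never flagged. Directions are fixed: lower tail of `Z(H_P)` in
population A, upper tails of `Z(F_ST)` and windowed XP-EHH. Published
numeric cutoffs (e.g. −1.498 / 1.773 / 0.121) are data-derived quantiles of
a specific dataset; the package treats the quantile rule as primary and
accepts explicit numeric cutoffs for replication.

Flagged windows overlapping or book-ended (half-step sliding guarantees
overlap of consecutive windows) are merged into regions per statistic;
regions are then extended ±50 kb and intersected with gene spans (closed
intervals). Merging precedes extension (extending unmerged windows gives the
same gene set because extension is uniform, but merged regions are the
reported unit). A gene is a candidate when supported by at least
`min_tests = 2` statistics; gene-level Venn counts over the three evidence
sets are reported. The candidate set is monotone non-increasing in
`min_tests` and non-decreasing in the flank.

## Population structure

Pairwise distance is allele sharing: `d(i,j) = 1 − (1/2L) Σ s_l` over the L
co-called sites, where `s_l = 2 − |dosage_i − dosage_j| ∈ {0,1,2}`. The
classic PHYLIP-style workflows do not pin down a single SNP distance; allele
sharing is the common default for SNP-based NJ and is the documented,
configurable choice here. The NJ tree is canonical Saitou–Nei (via
scikit-bio) with negative branch lengths clamped to zero on output. PCA
mean-centres alt-dosages per site, scales by `√(p(1−p))` (the smartpca
normalisation), mean-imputes missing dosages, skips monomorphic sites, and
takes the SVD; coordinates are `U·S` and are unique up to sign.

## Differential expression

With exactly one pooled library per breed no replicate dispersion is
estimable, so significance comes from the Audic–Claverie posterior
predictive: given count x in library A, the distribution of the count in
library B is `P(y|x) = (N_B/N_A)^y (x+y)! / (x! y! (1+N_B/N_A)^{x+y+1})`,
which is a negative binomial with r = x+1 and success probability
N_A/(N_A+N_B); tails are evaluated through that form (exact and stable for
large counts). Two-sided p = min(1, 2·min(P(Y≤y), P(Y≥y))). Because the
construction conditions on the first library's count, exact exchange
symmetry under swapping libraries holds only in fully symmetric cases
(x = y with equal library sizes); this is a property of the test, not an
implementation artefact. Under a matched-mean Poisson null the p-values are
super-uniform (type-I error at 0.05 stays below 0.06 in simulation).

`log2_ratio = log2(norm_A / norm_B)` on the RPKM scale (CPM when lengths are
unavailable), with a pseudocount of 1 added to both normalised values when
either raw count is zero (configurable). "Up" means higher in population A.
BH-FDR is step-up with NA p-values excluded from m. DEGs require
FDR ≤ 0.001 and |log₂ ratio| ≥ 1 (both thresholds inclusive, matching their
"≤ / ≥" statement). "Expressed" defaults to RPKM > 0 (at least one mapped
read); a flag switches to RPKM ≥ 0.1.

## Integration and enrichment

The candidate × DEG intersection reports each shared gene with its
supporting sweep tests and DE direction. Over-representation is an
upper-tail hypergeometric per gene set, `P(X ≥ k)` for k study hits of a
K-member set in an N-gene universe with study size n, BH-corrected across
sets. Term membership comes from a user-supplied GMT; no pathway database
content ships with the package. The default background universe is all
annotated genes supplied by the caller; restricting to expressed genes is
the caller's choice, since no single convention dominates in practice.

## Synthetic data

The genotype simulator is Balding–Nichols: ancestral frequency
`p₀ ~ Beta(0.8, 0.8)` clipped to [0.05, 0.95]; each population's frequency
is an independent `Beta(p₀(1−F)/F, (1−p₀)(1−F)/F)` draw with F the target
differentiation (default 0.10, a realistic between-breed value). Haplotypes
are Bernoulli draws per site — sites are in linkage equilibrium outside
sweeps. A sweep (default: one at 5 Mb, width 300 kb, strength 0.9 on a
10-Mb chromosome) shrinks population A's minor-allele frequencies by the
strength and resamples the interval's haplotypes from
`k = max(1, round((1−strength)·2n))` founders, jointly producing low H_P,
high F_ST and extended haplotype homozygosity. Sample sizes default to
12 + 10 diploids, mirroring a small two-breed resequencing design. QUAL
values fall below 30 at a stated 5% rate, 1% of haplotype slots are missing
(3% of sites at an elevated 20%), and 1%/2% of sites are multi-allelic/
INDELs, so the QC stage has planted work. Counts: ~55% of genes are
expressed with log-normal baselines taking 80% of each library
(the remainder standing in for reads outside annotated genes), 5% of
expressed genes are DE at |log₂ fc| = 2 (split up/down), and counts are
Poisson by default (gamma-Poisson at a stated dispersion optionally) at
library sizes 12 M and 10 M. The same seed reproduces byte-identical files.

What this does **not** emulate: linkage disequilibrium outside sweeps (so
neutral XP-EHH decays faster than in real genomes and the scan's null is
cleaner than reality), demography, recombination-rate variation, genotyping
error correlated with depth, and replicate-level biological variance in the
counts (the Poisson null matches the exact test's assumption — real
two-library data are overdispersed, which is precisely why an unreplicated
two-library design cannot control FDR against biological variation).
Passing recovery tests therefore demonstrates correctness of the
implementation under its own model, not power on real data.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: a 50-Mb (5 × 10 Mb)
neutral genome (~1,000 analyzable windows) for the outlier-rate checks, a
2-Mb / 20+20-haplotype fixture (~2,000 SNPs) for the oracle-equivalence
checks, and a 10-Mb planted-sweep genome for recovery — sizes chosen so the
full pipeline exercises every code path in seconds while keeping ≥100 SNPs
per window, the same density regime as a ~1 SNP/kb resequencing panel.
Degenerate inputs are handled explicitly: empty VCF bodies, all-NA window
vectors (error for thresholds, warning + all-NA for Z-transform), zero
co-called sample pairs (NA distance with warning), monomorphic PCA input
(error), zero library sizes (error), and p-values outside [0,1] (error).
Tie-breaks are deterministic throughout (major allele to ref at 50/50,
strictly-beyond flagging at cutoffs, lowest-index NJ joins via the library's
canonical ordering).
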