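# Methods

## Scope and data model

The pipeline starts from a multi-sample diploid VCF of biallelic SNPs (the
product of an upstream variant-calling workflow) and a sample→population
map. Internally everything operates on a `GenotypePanel`: a dense
samples × sites matrix of allele indices (0 = REF, 1 = ALT, −1 = missing)
with 1-based positions, single-base alleles and a per-site phase flag.
Indels and multiallelic records are dropped on input and counted;
half-missing genotypes (e.g. `0/.`) are normalised to fully missing — the
simplest consistent rule. Phase is required only by the haplotype
statistics (XP-EHH); the frequency-based stages accept unphased input.
Coordinates are 1-based inclusive throughout; only BED export converts to
0-based half-open.

## Filtering

Two regimes, applied at different stages:

* **QC filter** (post-calling): keep sites with missing-genotype rate
  ≤ 5% and pooled minor allele frequency ≥ 5%. With 30 samples the MAF rule
  keeps exactly the alleles observed more than twice among 60 chromosomes.
* **Scan filter** (before any scan): keep sites with missing rate ≤ 5%
  *and* missing count ≤ 2. The two clauses are redundant at n = 30
  (rate 5% ⇒ 1.5 individuals) but diverge for larger panels; they are
  applied as a conjunction of keep-conditions — the stricter reading — and
  both thresholds are configurable.

Both filters are idempotent and report per-criterion removal counts.

## Allele-frequency divergence screen

For each population P, a site is divergent when P's ALT frequency is ≥ 0.6
with at least 3 called individuals and every other population's ALT
frequency is strictly < 0.3 (an undefined frequency — no called
individuals — disqualifies the site). Boundary semantics are exactly ≥ and
<. The screen evaluates the ALT allele by default; `allele="both"` also
screens the mirrored REF-allele criterion. Because the high cutoff exceeds
the low cutoff, no site can be selected for two populations (asserted).

## Fst

Per-site differentiation uses the Weir & Cockerham (1984) two-level
variance components a (among populations), b (among individuals within
populations) and c (within individuals), computed from per-population
called counts nᵢ, ALT frequencies pᵢ and observed heterozygote proportions
hᵢ. θ = a/(a+b+c) is left unclamped (negative estimates are informative
about sampling noise); a fixed difference between fully called homozygous
populations gives θ = 1 exactly. Sites where any population has zero
called individuals, or where n̄ ≤ 1, are skipped.

Windowed Fst is the **ratio of sums** Σa / Σ(a+b+c) over a window's sites
("weighted" Fst) — not the mean of per-site ratios — which downweights
low-information sites. Windows tile each chromosome from coordinate 1 at
the configured step; windows with fewer than `min_sites` (default 1)
component-bearing sites are omitted. The one-vs-rest scan contrasts each
country against the five others pooled into a single second population
(r = 2), matching a two-population run of the standard windowed-Fst tools;
averaging the five pairwise comparisons instead is a documented
alternative, not implemented.

## Nucleotide diversity

Per-site π is the unbiased heterozygosity 2k(n−k)/(n(n−1)) over the
group's called haplotypes, summed over the sites of non-overlapping
windows (25 kb default) and divided by the window length in bp, invariant
positions included — the convention of windowed-π tools. The sweep
statistic is the per-window ratio (π_ref + ε)/(π_target + ε) with the
**cold group as reference and the tropical group as target**, so ratios
≫ 1 flag diversity loss in the candidate group. This orientation is the
one consistent with sweep regions showing both large ratios and reduced
target-group diversity; the conventional subscript "(tropic/temperate)"
printed by some studies is ambiguous on this point, so the orientation is
stated here explicitly. ε (default 1e−8) keeps empty-window ratios finite;
windows where both π values are exactly 0 get ratio 1 (no evidence).

## EHH, iHH and XP-EHH

EHH at distance x from a core SNP is the probability that two haplotypes
drawn without replacement from the group are identical at every site from
the core through x: haplotypes are partitioned by their allele string and
EHH = Σ C(gⱼ,2) / C(N,2). Curves start at (0, 1), are monotone
non-increasing, and stop after the first point below the decay cutoff
(default 0.05, point included), at the chromosome end, or beyond the
maximum extension (default 1 Mb). iHH is the trapezoidal integral of both
direction curves over physical distance (bp); no genetic map is used.

XP-EHH follows the cross-population convention: each group's EHH uses all
of that group's haplotypes, unpartitioned by core allele. Per retained
site the raw score is ln(iHH_A/iHH_B); sites where either iHH is 0
(immediate decay on both arms) are dropped and counted rather than
producing ±∞. Raw scores are standardized to mean 0, SD 1 over all scored
sites genome-wide; positive standardized scores indicate longer haplotype
homozygosity in group A (the candidate group). Sites with any missing
genotype in either group are excluded from the haplotype block
(complete-case rule) so the two groups share their core sites.

Windows aggregate per-site standardized scores as the window **mean**
(the max is also emitted); the sweep rule's "> 2" cutoff applies to the
window statistic. The scan's hot loop is a numba-jitted kernel computing
iHH at every core in one pass; the readable `ehh()`/`ihh()` functions are
the reference route and an equivalence test pins the two together at
1e−12.

## Thresholds and peak calling

Outlier thresholds are nearest-rank upper quantiles: the k-th largest
window value with k = ⌈f·n⌉, so at least a fraction f of windows always
qualifies and ties at the threshold are all included — an
interpolation-free rule chosen for exact reproducibility. Quantile
thresholds use ≥; the fixed XP-EHH cutoff uses strict > 2. Thresholds are
computed per scan over that scan's own genome-wide window distribution, so
a weakly differentiated country gets a lower cutoff than the others.

The within-country peak rule requires maximal runs of ≥ 3 windows,
adjacent under the scheme's 25 kb step, all at or above the threshold; the
region is the union of member windows and the peak statistic is the member
maximum. Raising the run-length requirement never increases region count
or total span. The sweep intersection has no run-length rule — real sweep
regions as narrow as one window are legitimate — so adjacent candidate
windows merge and singletons stand.

Gene annotation attaches every GFF3 `gene` record overlapping a region by
≥ 1 bp (closed intervals; touching without sharing a base is not overlap).

## The synthetic study

The generator emulates a six-country design with five diploid samples per
country, 30,000 SNPs on a 10 Mb chromosome. Neutral structure follows the
Balding–Nichols model: ancestral frequency p ~ Uniform(0.05, 0.95) per
site, population frequency pᵢ ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with
F = 0.05 by default, haplotype alleles Bernoulli(pᵢ), two phased
haplotypes per individual. F equals the expected pairwise Fst, and the
realized genome-wide WC84 weighted Fst matches it closely (≈ 0.051 both
pairwise and with all six populations jointly, measured at seed 1). The
pooled one-vs-rest contrast is systematically lower (≈ 0.026 at F = 0.05):
pooling five independently drifted populations shrinks the between-group
frequency variance (the pool mean has variance F/5) and creates a Wahlund
heterozygote deficit that the estimator assigns to the within-group
components. This is a property of the estimator under pooling, not a
generator miscalibration.

Hard sweeps are injected by choosing one donor haplotype uniformly among
the target group's haplotypes and copying it over a fraction β (default
0.9, rounded to nearest, donor always included) of those haplotypes inside
the interval; non-target populations are untouched and the truth table
records every interval. This jointly produces the three signatures the
scans test: shifted allele frequencies, reduced target-group diversity and
one long high-frequency haplotype. The default scenario injects five
100 kb sweeps into the tropical group (Egypt + Uganda).

What the generator deliberately does not model: linkage between background
sites (sites are independent, so neutral EHH decays within a few SNPs and
the sweep is the only source of long haplotypes — a conservative
signal-to-noise setting for XP-EHH), demographic history, recombination
and mutation-rate variation, and sequencing error. Passing tests therefore
demonstrate the statistics and their wiring, not performance on real
linked genomes, where neutral LD inflates the XP-EHH null and thresholds
do more work.

A structural consequence of the scaled-down genome is worth stating: the
default scenario sweeps 5 × 100 kb = 5% of the chromosome (20 of 400
windows), while a top-1% nearest-rank threshold admits only
⌈0.01 × 400⌉ = 4 windows per statistic. The Fst top-4 and π-ratio top-4
are then noisy four-element subsets of the 20 strongly swept windows and
rarely coincide, so the triple intersection recovers only a minority of
the five sweeps (0–2 across seeds) even though each statistic individually
ranks sweep windows at the very top. When the sweep load fits the outlier
budget — one 100 kb sweep, i.e. 4 of 400 windows — the scan recovers it
reliably, with zero false positives on neutral panels and nothing called
when the groups are swapped. On real genomes (~10⁵ windows, sweeps a
negligible genome fraction) the empirical quantile approximates the
neutral tail and this saturation does not arise.

## Numerical and degenerate-case choices

* Nearest-rank quantiles, no interpolation; ties all included.
* Negative per-site and per-window Fst retained.
* Sites monomorphic across all samples have a+b+c = 0 and are excluded
  from window sums (NaN θ).
* Empty π windows are emitted with π = 0 (they carry evidence of no
  diversity); empty Fst/XP-EHH windows are omitted (they carry none).
* The last π window of a chromosome is divided by its clipped length when
  a chromosome length is supplied; otherwise the window grid extends to
  the last SNP.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; simulation, injection and every scan are
  deterministic given config + seed, and outputs are byte-identical across
  reruns.

## Problem sizes

The test suite and the acceptance script run the full default scenario
(30 samples × 30,000 sites) for end-to-end checks and smaller panels
(1,500–5,000 sites) for per-module properties; the oracle comparisons use
1,000 random sites for Fst and exhaustive pair enumeration for haplotype
fixtures up to 8 haplotypes × 10 sites. These sizes were chosen to keep
every property measurable at full precision on a single CPU.
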