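# Methods

## Data model

Genotypes are a samples × SNPs matrix of codes 0 (homozygous allele-1), 1
(heterozygous), 2 (homozygous allele-2) and −1 (missing), with a map of
(chromosome, SNP id, 1-based bp) records kept sorted by (chromosome, bp)
and breed labels carried per sample. On PED/MAP input, allele-1 of each SNP
is the first allele symbol encountered in file order. Every downstream
statistic uses only het/hom/missing states, so allele polarity is
semantically irrelevant; it matters only for the write→read round-trip,
which is exact for *canonical-polarity* datasets (each SNP's first
non-missing genotype carries allele-1 — the orientation the reader
reconstructs by definition). `GenotypeDataset.canonical_polarity()`
produces that form and the simulator emits it directly; for other data the
round-trip is exact up to per-SNP polarity.

## Quality control

Filters run in a fixed order so attrition reports are deterministic:
(1) non-autosomal/unplaced SNPs (numeric chromosome labels in
[1, `autosome_max`], default 26 — the ovine autosome count); (2) SNPs with
call rate ≤ 0.95 (strict "greater than" retained); (3) individuals with
call rate ≤ 0.90; (4) SNPs with MAF < 0.01, computed on the surviving
individuals. Computing MAF after sample removal mirrors common PLINK
practice. Call-rate comparisons are strict and the MAF bound inclusive,
following the usual reading of "greater than" versus "minimum of".

## LD pruning

Greedy windowed pruning per chromosome: the window holds all surviving
SNPs within 50 kb of its first SNP; within the window, every pair with
squared Pearson genotype correlation (0/1/2 codes over pairwise-complete
individuals; composite LD, no phasing) above 0.5 loses its lower-MAF
member (ties drop the later-bp SNP); the window start then advances 10
surviving SNPs. The kb-window/variant-step mixture is deliberate; a
`window_snps` option switches to a fixed SNP-count window for users who
prefer the other idiom. Applied only ahead of IBS/MDS — run and island
detection use the full QC'd set.

## Diversity indices

Within-breed allele frequencies by default (indices are reported per
breed; a `pooled_frequencies` flag is available). Per SNP with ``n``
non-missing individuals, expected heterozygosity uses the
small-sample-corrected estimator 2p(1−p)·2n/(2n−1); H_E and H_O are means
over SNPs with at least one call. The per-individual inbreeding
coefficient is F = (O_hom − E_hom)/(L − E_hom) over the individual's L
non-missing SNPs, with E_hom the summed corrected expected homozygosity —
the estimator pair behind PLINK's `--het`. Breed F_IS is the mean ± sample
s.d. of individual F. If an individual's informative SNPs are all
monomorphic (denominator ≈ 0, possible only in toy data) its F is set
to 0.

## IBS and classical MDS

Pairwise IBS is the mean over jointly non-missing SNPs of
(2 − |g_i − g_j|)/2; the stored distance is 1 − IBS (zero shared SNPs is an
error rather than a silent NaN). Classical (Torgerson) scaling
double-centers −½D², eigendecomposes, and scales the top-k eigenvectors by
√λ. Negative eigenvalues — non-Euclidean input — are truncated to zero
with a warning. Coordinate sign is fixed by making each column's
largest-magnitude entry positive, and columns are re-centered, so
embeddings are deterministic.

## Run detection

The seven detection parameters and their defaults:

| parameter | ROH | HRR |
|---|---|---|
| window size (SNPs) | 50 | 15 |
| opposite genotypes allowed per window | 0 | 0 |
| missing calls allowed per window | 0 | 0 |
| SNP-in-run proportion threshold | 0.05 | 0.05 |
| minimum SNPs per run | 50 | 15 |
| minimum run length | 1 Mb | 100 kb |
| maximum inter-SNP gap | 1 Mb | 1 Mb |
| minimum SNP density | 1 / 100 kb | 1 / 100 kb |

Edge handling: only windows fully contained in the chromosome count toward
a SNP's proportion (SNP *j* of *m* is contained in windows
max(0, j−w+1) … min(j, m−w)); there are no phantom windows beyond the
ends, and a chromosome with fewer SNPs than the window yields no runs. The
proportion comparison is strict (> 0.05), and the same threshold applies
in HRR mode for symmetry — note that with w = 15 a single passing window
already flags its SNPs (1/15 > 0.05). Gap splitting happens before the
SNP-count/length/density filters, since a gap invalidates contiguity
first. The density check uses span = end − start, consistent with the
length convention everywhere else. With the zero-opposite/zero-missing
defaults every SNP inside a ROH is a called homozygote and every SNP
inside an HRR a heterozygote — an asserted invariant.

A consequence of the containment rule is that a homozygous tract's first
and last ~2 SNPs fall below the 0.05 proportion (they are covered by too
few passing windows), so detected runs sit a couple of SNPs inside the
true tract. Recovery is therefore scored by base-pair Jaccard overlap
rather than exact interval equality; at ~4 kb spacing the trim is ≈ 8 kb
per side on a ≥ 1 Mb run.

`oracle_detect_runs` re-derives runs by explicit per-window and
per-containing-window enumeration with plain loops, and the equivalence
`detect_runs ≡ oracle_detect_runs` is asserted on randomized datasets in
both modes, over randomized parameter draws (small windows and minimum
lengths, so that random backgrounds actually produce runs to compare).

## Run statistics

Per individual: N (run count), L (mean run length, Mb), S (total, Mb),
F = S/genome length. The genome length defaults to the dataset's
SNP-covered autosomal span (Σ per chromosome of last − first SNP bp), with
an override for the conventional ~2.4 Gb ovine constant. Individuals with
zero runs are included in breed means with N = 0 (the self-consistent
convention: breed mean × individuals = total runs exactly); a flag
restricts the averages to run-carrying individuals, an alternative some
tabulations use. Breed L is the mean of per-individual means, not the
pooled run-length mean. Length-class edges are right-open so the five
classes partition the runs (a 2.0 Mb ROH is "2–4 Mb").

## Islands

Per-SNP occurrence counts distinct individuals of the breed whose runs
cover the SNP (closed intervals), divided by all genotyped individuals of
the breed. The "top 0.1%" cut is the nearest-rank upper quantile
(k = ⌈0.001·m⌉-th largest value) computed over **all** SNPs, with
threshold ties admitted — a deterministic, estimator-free rule. Qualifying
SNPs must also strictly exceed the frequency floor (20% ROH / 30% HRR).
Islands are maximal stretches of map-consecutive qualifying SNPs with at
least `min_island_snps` members (default 2: an island is a plurality of
adjacent SNPs). Island length is end − start; Fix% is the mean member
occurrence × 100, hence always in (100·floor, 100]. Cross-breed sharing
reports every maximal breed set (≥ 2) whose islands on one chromosome
share ≥ 1 bp, with the intersection interval; maximality means no further
breed's island overlaps the intersection. Gene annotation assigns a gene
to an island when their closed intervals share ≥ 1 bp; gene tables are
declared 1-based inclusive with a converter from 0-based half-open BED.

The package bundles reference ROH/HRR island tables (coordinates, SNP
counts, Fix% and gene lists) for four Mediterranean sheep breeds
(Barbaresca, Noticiana, Sarda, Valle del Belìce) as desk-scale validation
inputs for the interval arithmetic, overlap detection and gene counting.

## Synthetic data

The generator emulates the targeted study design: exponential inter-marker
spacings with 4 kb mean (irregular, array-like maps), per-SNP allele
frequencies uniform in [0.05, 0.95], Hardy-Weinberg genotype draws,
optional Bernoulli missingness, and planted tracts — homozygous (one
allele drawn per SNP from its frequency and doubled, so tract genotypes
respect the frequency spectrum) or heterozygous — carried by a configured
fraction of a breed, carriers drawn without replacement. Missingness
spares planted tracts by default so the zero-missing window rule does not
fragment planted runs (a flag enables uniform missingness for robustness
tests). Background SNPs are independent: no linkage disequilibrium and no
pedigree structure. That keeps the null analytically tractable (the
expected count of ≥ 50-SNP chance homozygous stretches is negligible for
mid-range frequencies) but means passing tests demonstrate correctness of
the run/island logic, not performance on realistically autocorrelated
genomes; a founder-haplotype copying mode would be the natural extension.

Recovery scoring: per carrier, the bp Jaccard between the planted interval
and the carrier's detected runs on that chromosome; precision and recall
aggregate intersection/detected and intersection/planted bp over carriers;
`island_called` records whether a same-breed island overlaps the tract. A
fingerprint (dimensions + content hash) binds run sets and truth to their
dataset.

## Pipeline

Stages run in a fixed order (ingest/simulate → QC → diversity → pruning +
IBS + MDS → ROH → HRR → summaries → islands/annotation → manifest), each
logging its input/output dimensions so QC attrition is auditable. All
tables are plain TSV/JSON with fixed float formatting; reruns under the
same config and seed are byte-identical, which is also how the CLI's
per-stage subcommands stay consistent: they recompute upstream stages in
memory rather than maintaining an artifact cache. Exit codes: 0 ok, 1 user
error, 2 internal.

## Problem sizes in tests

Unit and property tests run on datasets of up to ~50 individuals × 3,000
SNPs and 50-dataset equivalence sweeps of 200–2,000 SNPs × 5 individuals —
sizes at which the brute-force oracle is exact and the whole suite runs in
seconds while still producing non-trivial runs, islands and QC attrition.

## Known limitations

- No PLINK binary (BED/BIM/FAM) input; text PED/MAP only.
- No LD or demographic realism in the simulator (see above).
- Consecutive-SNP (window-free) run calling, F_ST, ADMIXTURE-style
  ancestry, tree building/plotting and live annotation-database queries
  are out of scope; the 1 − IBS matrix and island gene lists are exported
  for external tools.
- Agreement of the detector is claimed against this package's own
  enumeration oracle, not bit-for-bit against other sliding-window
  implementations, whose edge behavior in the first/last w−1 SNPs may
  differ.
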