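# Methods

## Coordinates, strands, and counting rules

All internal coordinates are 0-based half-open; GFF3's 1-based closed
convention is converted at the I/O boundary and nowhere else. Every read
and feature carries a strand and all counting is strand-aware by default
(CLIP libraries are stranded); `ReadIndex(ignore_strand=True)` exists for
degraded inputs. PCR-duplicate collapse is an explicit flag (default
off) recorded in the run parameters, never an implicit step.

Two deliberately different counting rules coexist:

* **Feature totals** (annotation ranking, UTR totals, site reads): a read
  overlapping the feature by ≥ 1 nt counts once for that feature; a read
  overlapping k features counts in all k, because each annotation is
  summarised independently. Multi-block features use union semantics — a
  read spanning a block junction still counts once.
* **Peak bins**: each read is assigned to exactly one bin by its
  strand-aware 5′ end (plus strand: start; minus strand: end−1), so bin
  totals are additive and nothing is double-counted within a region.

## Peak model

Bins of width 30 nt (configurable) tile each analysed region. Positive
bin counts are modelled as a zero-truncated negative binomial with mean
μ and dispersion α (variance μ + αμ²). The fit is maximum likelihood
over (log μ, log α) by Nelder–Mead on the count histogram,
method-of-moments initialised, converged when the log-likelihood changes
by < 1e-8; underdispersed input (sample variance ≤ mean, e.g. constant
counts) falls back to a zero-truncated Poisson whose mean solves
μ/(1−e^−μ) = sample mean, with a warning. Zero bins are not tested —
they cannot be peaks, and the truncated model conditions on X ≥ 1.

Each positive bin gets the upper tail P(X ≥ k | X ≥ 1);
Benjamini–Hochberg runs once across all tested bins of a run (FDR
default 0.01, recorded in the output metadata — the multiple-testing
rule is this implementation's choice); significant bins adjacent or
within `merge_gap` nt merge into one peak. Peak boundaries are then
widened to the genomic footprint of the member reads: binning by 5′ end
alone clips the bound fragment on one side (by up to a read length,
direction depending on strand), which would wrongly exclude seed sites
sitting at the peak's edge from "in peak" containment calls. A peak's
`total_reads` remains the count of 5′ ends in its merged bins; `density`
is total reads divided by the refined length.

When many regions are called together, every region with ≥ 10 positive
bins gets its own background fit and sparser regions share a pooled fit.
Per-region fitting absorbs the large expression differences between
transcripts (the same role the covariate mode plays in published CLIP
peak callers); without it, one highly expressed transcript would turn
entirely into "peak" against a transcriptome-wide background.

Because the ZTNB tail is discrete, the per-bin p-values are conservative
and so is BH on top of them: in background-only simulation the fraction
of datasets with any called peak is *bounded by* the FDR level rather
than equal to it. The calibration suite asserts that one-sided bound
(measured rates land around half the nominal level).

## Seed sites

The seed is positions 2–8 of the mature miRNA; a family is a set of
matures sharing that heptamer exactly. On the transcript sense strand,
candidate loci are anchored at matches of the reverse complement of the
positions 2–7 hexamer; each locus is promoted to the highest type its
flanks support — 8mer (seed match + A opposite position 1), 7mer-m8
(seed match), 7mer-A1 (hexamer + A), 6mer — so no locus is reported
twice. `N` never matches (conservative). Only canonical seed types are
implemented; no 3′-supplementary pairing or context scoring. Sites are
projected to genomic coordinates through the host transcript's block
structure; a site "in" a feature or peak means every projected block is
fully contained.

## Occupancy statistic

For a predicted site inside a 3′UTR, occupancy in one library is
f = (reads overlapping the site) / (reads overlapping the UTR) — a
within-UTR normalisation that cancels transcript-abundance differences
between genotypes. Comparisons use logit f. Boundary handling: zero site
reads set the NB ("no binding") flag and the logit is undefined; f = 1
is pulled to n/(n+1) (n = UTR reads) so every emitted logit is finite.

The bound-target set keeps sites with ≥ 1 read in *both* of the two
qualifying genotypes; its gene set is the union of host genes. The
paired genotype comparison is a two-sided paired t-test on logits over
sites non-NB in both libraries (two-sidedness is this package's choice);
genotype means are reported on the percentage scale over all paired
sites with NB sites counted as zero, which is also the scale of the
percent-change summary 100·(mean_a − mean_b)/mean_a, rounded half away
from zero to a whole percent. Averaging is per site; per-UTR averaging
is available via the library but is not the default estimator.

## Expression analyses

Contrast tables carry log2fc = log₂(first-named / second-named
condition) — the only convention under which "down in the mutant" means
a positive control-vs-mutant fold change — plus BH-adjusted p-values
from the upstream DE fit (the fit itself is out of scope; tables are
consumed as given). The ECDF/KS comparison is `scipy.stats.ks_2samp` of
target vs non-target log2fc, exact below 30 per group, asymptotic
otherwise, requiring ≥ 10 genes per group; direction is the sign of the
median difference. The concordance partition classifies each bound
target by strict signs (log2fc = 0 falls in neither class): down in
mutant (mutant contrast > 0), up in knockout (knockout contrast < 0),
both, and their union by inclusion–exclusion; percentages are whole
percent of the classified total, and targets missing from either table
are dropped and counted. Response gene sets use strict thresholds
(log2fc > cutoff AND padj < cutoff). The expressed-gene pre-filter drops
genes whose mean counts-per-million across all libraries falls below
2 CPM. qPCR relative expression is 2^−(Ct_target − Ct_reference) with
technical replicates averaged before the subtraction.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:
negative-binomially dispersed per-transcript read totals, reads
concentrated at seed sites, genotype-dependent site ablation, and
coherently shifting contrast tables. Each transcript lives on its own
chromosome-like contig with a random strand; mRNAs are a CDS followed by
a 3′UTR (log-normal lengths, ~600 and ~500 nt medians), lncRNAs are
single blocks (~1800 nt median). One designated lncRNA — the sponge —
carries a single 8mer for family 0 and a fixed high expression weight
(40× the mRNA median); each mRNA UTR independently receives at most one
implanted 8mer per family with probability 0.25. A few non-sponge
lncRNAs carry rRNA-repeat annotations to exercise masking.

Reads are fixed-length 30 nt. A transcript's total is NB with mean
proportional to (expression × binding weight), the normaliser fixed at
the wild-type weights so background coverage is genotype-independent;
within a transcript, half the weight (site_concentration = 0.5) sits on
its implanted sites, split equally, and the rest is uniform. Genotype
effects multiply family-0 site weights: the sponge mutant ablates the
sponge site (×0.02) and scales mRNA site weights by 1 + δ (default
δ = 0.1); the knockout ablates all family-0 sites. Site reads are placed
to cover the site fully; everything is a deterministic function of the
config seed via fixed child streams, so outputs are byte-identical
across runs.

Contrast tables draw targets from Normal(+β, σ) in the
control-vs-sponge-mutant contrast and Normal(−β, σ) in the
control-vs-knockout contrast, non-targets from Normal(0, σ), with
β = 0.25, σ = 0.5 chosen so the analytic concordance-union probability
1 − (1 − Φ(β/σ))² ≈ 0.90 matches the qualitative structure of a strong
sponge circuit. The adjusted p-values are a monotone transform of
|log2fc| (BH over nominal normal tails) — adequate for threshold
operations, not a DE model.

Default scale is 2,000 mRNAs, 100 lncRNAs, and 2×10⁵ reads per library,
which runs the full pipeline in seconds. The free noise parameters
(site_concentration = 0.5, NB dispersion = 0.1, expression spread
sdlog = 0.4, ~500 implanted family-0 sites) are set so per-site counts
are informative enough that a 10% occupancy redistribution is detectable
over the site set with high power — the sensitivity regime of a real
deeply sequenced study, reached here at desk-scale depth by
concentrating more of each transcript's reads on its sites. Two
consequences to keep in mind when interpreting green tests: synthetic
occupancy fractions (tens of percent of UTR binding per site) are far
larger than typical real-data values (a few percent), and the generator
omits sequencing error, crosslink-induced mutations, fragment-length
variation, multi-mapping, and overlapping gene models. Passing tests
demonstrate that the estimators recover planted structure under the
assumed statistical model, not that real libraries satisfy that model.

## Numerical and tie-break conventions

Rankings sort by the primary metric descending, then the secondary
metric descending (density for read ranks, reads for density ranks),
then identifier/position — fully deterministic. Percentiles are
100·rank/N over features or peaks with at least one read. Reported
percentages round half away from zero. Empty inputs yield empty tables;
a missing input file aborts a pipeline run during validation, before any
stage executes; any stage error aborts the run naming the stage. Reports
contain no wall-clock, hostname, or output-path content, so reruns and
rebuilt reports are byte-identical.

## Known limitations

No BAM/CRAM parsing (convert to BED upstream); no alignment or
adapter handling; no covariate-mode peak calling beyond the per-region
background; no cross-library peak reconciliation (libraries are pooled
before calling); no thermodynamic/conservation site scoring; no
per-site differential-binding model (the paired summary is the
endpoint); no DE fitting or enrichment analysis. The acceptance
calibration for the peak caller checks conservativeness, not exact
FDR equality, for the discreteness reason above.
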