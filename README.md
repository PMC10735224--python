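# clipcircuit

Ago2 HITS-CLIP occupancy analysis for discovering and quantifying
lncRNA:miRNA competing-endogenous-RNA ("sponge") circuits.

Argonaute-2 HITS-CLIP reads mark where miRNA-loaded Ago2 sits on the
transcriptome. When a highly expressed lncRNA carries a strong seed site
for a miRNA family, it can sequester that family and derepress the
family's mRNA targets. `clipcircuit` implements the computational side of
detecting such a circuit from stranded CLIP alignments, transcript
annotations, and per-gene expression contrasts:

1. **Annotation occupancy** — integrate reads across whole annotations,
   optionally mask rRNA repeats, and rank lncRNAs by total Ago2 binding
   (rank *r* of *N* bound annotations reported as the top 100·*r*/*N* %).
2. **Peak calling** — bin strand-aware read 5′ ends, fit a zero-truncated
   negative binomial background (mean μ, dispersion α, variance
   μ + αμ²), test each bin's upper tail P(X ≥ k | X ≥ 1), correct with
   Benjamini–Hochberg, merge significant bins, and rank peaks both by
   total reads and by density (reads/nt).
3. **Seed sites** — scan transcript sequences for canonical miRNA-family
   seed matches (8mer > 7mer-m8 > 7mer-A1 > 6mer, one type per locus) and
   map them into 3′UTRs and peaks.
4. **Site occupancy** — for each predicted site, the fraction
   *f* = (reads at site) / (reads in host 3′UTR), compared between
   genotypes on the logit scale with a paired *t*-test; sites with zero
   reads in a genotype are flagged NB ("no binding") and excluded from the
   test but counted as zero in genotype means.
5. **Derepression** — two-sample Kolmogorov–Smirnov comparison of target
   vs non-target log₂ fold-change distributions, a sign-concordance
   partition of targets across a sponge-mutant and a miRNA-knockout
   contrast, strict-threshold response gene sets, and a 2^−ΔCt qPCR
   helper.
6. **Synthetic data** — a fully seeded generator producing a
   transcriptome, three genotypes' CLIP libraries (wild type, sponge-site
   mutant, miRNA-family knockout), and matched contrast tables with known
   ground truth, so the whole pipeline is testable end to end.

The intended users are genomics analysts working with CLIP-seq who want a
reproducible, dependency-light reimplementation of this analysis pattern,
plus a simulator for validating it.

## Worked example

Simulate a small study and run the full chain:

```bash
clipcircuit simulate --outdir demo/data --config sim.yaml   # seed: 42, n_mrna: 500,
                                                            # n_lncrna: 40, depth: 100000
clipcircuit run --config run.yaml                           # paths to the files above
```

The run prints:

```
concordance_total = 132
concordance_union_pct = 92
occupancy_pct_change_ko = 83
occupancy_pct_mirna_ko = 9.374058873039655
occupancy_pct_sponge_mut = 57.24847949710987
occupancy_pct_wt = 56.11349294046419
top_lncrna = lnc0000
utr_to_lncrna_median_read_ratio = 4.9
```

Reading this: the planted sponge lncRNA (`lnc0000`) is the most bound
lncRNA; the median 3′UTR has 4.9× more reads than the median lncRNA;
mean target-site occupancy rises from 56.1% of UTR binding in wild type
to 57.2% in the sponge-site mutant (the planted redistribution,
`occupancy_summary.tsv` shows paired *t* = −2.15, p = 0.034) and
collapses to 9.4% in the knockout, an 83% reduction; and 92% of bound
target genes respond in at least one concordant direction (down in the
sponge mutant or up in the knockout). `ks_derepression.tsv` holds the
KS statistics (D = 0.23, p = 3.7×10⁻⁵ with a positive shift in the
mutant contrast; D = 0.25 with a negative shift in the knockout).

Every stage is also a subcommand (`quantify`, `peaks`, `sites`,
`occupancy`, `derepress`, `concordance`, `geneset`, `report`) operating on
BED6/GFF3/FASTA/TSV files, and every subcommand is a thin wrapper over
importable functions (`clipcircuit.rank_annotations`,
`clipcircuit.call_peaks_in_regions`, `clipcircuit.paired_occupancy_test`,
…).

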