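"""Fully synthetic CLIP + expression datasets with recoverable ground truth.

The generator emulates the statistical structure of an Ago2 HITS-CLIP /
mRNA-seq study of a lncRNA sponge circuit:

* a transcriptome of mRNAs (CDS + 3'UTR) and lncRNAs, one of which (the
  "sponge") is highly expressed and carries a single high-affinity 8mer
  site for miRNA family 0;
* stranded CLIP reads whose per-transcript totals are negative-binomially
  dispersed and which concentrate at implanted seed sites, with
  genotype-dependent effects — ``sponge_mut`` ablates the sponge site and
  redistributes a fraction ``delta`` of occupancy onto the family's mRNA
  sites; ``mirna_ko`` ablates all of the family's sites;
* per-gene expression contrasts in which the family's targets shift
  coherently (down in the sponge mutant, up in the knockout).

Every output is a deterministic function of the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import FeatureAnnotation, GenomicInterval
from .io import write_fasta, write_gff3, write_reads_bed, write_tsv
from .readsets import ReadSet

GENOTYPES = ("WT", "sponge_mut", "mirna_ko")

# fixed child-stream ids so each output is independent of the others' draws
_STREAM_TRANSCRIPTOME = 1
_STREAM_READS = {"WT": 11, "sponge_mut": 12, "mirna_ko": 13}
_STREAM_CONTRASTS = 21


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic dataset.

    Lengths are in nucleotides; ``depth_per_library`` is reads per CLIP
    library; ``site_concentration`` is the fraction of a transcript's reads
    placed at its seed sites; ``sponge_redistribution_delta`` scales mRNA
    site occupancy of family 0 in the sponge mutant by ``1 + delta``.
    """

    seed: int = 0
    n_mrna: int = 2000
    n_lncrna: int = 100
    n_mirna_families: int = 3
    site_prob_per_utr: float = 0.25
    utr_meanlog: float = 6.2
    utr_sdlog: float = 0.5
    cds_meanlog: float = 6.4
    cds_sdlog: float = 0.4
    lnc_meanlog: float = 7.5
    lnc_sdlog: float = 0.5
    expr_sdlog: float = 0.4
    lncrna_expr_scale: float = 0.125
    sponge_expression: float = 40.0
    n_rrna_repeats: int = 5
    depth_per_library: int = 200_000
    nb_dispersion: float = 0.1
    site_concentration: float = 0.5
    sponge_redistribution_delta: float = 0.1
    ablation_factor: float = 0.02
    repression_beta: float = 0.25
    noise_sigma: float = 0.5
    read_length: int = 30
    mirna_length: int = 22

    def __post_init__(self) -> None:
        for name in ("site_prob_per_utr", "site_concentration", "ablation_factor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_per_library <= 0:
            raise ValueError("depth_per_library must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @property
    def sponge_feature_id(self) -> str:
        return "lnc0000"


@dataclass
class SiteTruth:
    """One implanted seed site, in transcript and genomic coordinates."""

    transcript_id: str
    gene_id: str
    family_id: str
    family_index: int
    tx_start: int
    tx_end: int
    host_feature_id: str
    chrom: str
    g_start: int
    g_end: int
    strand: str
    is_sponge_site: bool


@dataclass
class GroundTruth:
    sponge_feature_id: str
    sites: list[SiteTruth]
    target_genes: list[str]
    expression: dict[str, float]            # transcript -> relative abundance
    tx_length: dict[str, int]
    utr_span: dict[str, tuple[int, int]]    # transcript -> (tx utr start, end)
    strand: dict[str, str]
    true_lfc: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "sponge_feature_id": self.sponge_feature_id,
            "sites": [dataclasses.asdict(s) for s in self.sites],
            "target_genes": self.target_genes,
            "expression": self.expression,
            "tx_length": self.tx_length,
            "utr_span": {k: list(v) for k, v in self.utr_span.items()},
            "strand": self.strand,
            "true_lfc": self.true_lfc,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            sponge_feature_id=d["sponge_feature_id"],
            sites=[SiteTruth(**s) for s in d["sites"]],
            target_genes=d["target_genes"],
            expression=d["expression"],
            tx_length=d["tx_length"],
            utr_span={k: tuple(v) for k, v in d["utr_span"].items()},
            strand=d["strand"],
            true_lfc=d.get("true_lfc", {}),
        )


@dataclass
class Transcriptome:
    seqs: dict[str, str]
    features: list[FeatureAnnotation]       # lncRNA / CDS / 3'UTR / rRNA repeats
    tx_features: dict[str, FeatureAnnotation]  # transcript-span annotations
    mirnas: pd.DataFrame
    truth: GroundTruth


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stream])


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.int8)


_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


def _implant(seq: np.ndarray, pos: int, motif: str) -> None:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    seq[pos:pos + len(motif)] = [idx[c] for c in motif]


def simulate_transcriptome(config: SimulationConfig) -> Transcriptome:
    """Random transcript sequences with seed sites implanted at known positions.

    One designated lncRNA carries an 8mer site for family 0 (the sponge);
    each mRNA 3'UTR independently receives at most one 8mer per family with
    probability ``site_prob_per_utr``. A handful of non-sponge lncRNAs are
    annotated with rRNA-repeat intervals for masking analyses.
    """
    rng = _rng(config, _STREAM_TRANSCRIPTOME)

    # miRNA families: two members each, identical positions 2-8
    seeds: list[str] = []
    fam_rows = []
    while len(seeds) < config.n_mirna_families:
        mat = "".join(rng.choice(list("ACGU"), config.mirna_length))
        seed = mat[1:8]
        if seed[:6] in {s[:6] for s in seeds}:
            continue  # hexamer cores must be distinct between families
        fam = f"fam{len(seeds)}"
        seeds.append(seed)
        member2 = mat[0] + seed + "".join(rng.choice(list("ACGU"), config.mirna_length - 8))
        fam_rows.append((fam, f"{fam}-a", mat))
        fam_rows.append((fam, f"{fam}-b", member2))
    mirnas = pd.DataFrame(fam_rows, columns=["family_id", "mirna_id", "sequence"])

    # 8mer motif on the target sense strand: revcomp(seed) + A
    motifs = []
    for seed in seeds:
        rc = "".join(_COMP[c] for c in reversed(seed))
        motifs.append(rc + "A")

    seqs: dict[str, str] = {}
    features: list[FeatureAnnotation] = []
    tx_features: dict[str, FeatureAnnotation] = {}
    sites: list[SiteTruth] = []
    expression: dict[str, float] = {}
    tx_length: dict[str, int] = {}
    utr_span: dict[str, tuple[int, int]] = {}
    strand_of: dict[str, str] = {}
    target_genes: set[str] = set()

    def add_tx(tx_id, gene_id, L, strand, fclass):
        chrom = f"chr_{tx_id}"
        span = GenomicInterval(chrom, 0, L, strand)
        tx_feat = FeatureAnnotation(tx_id, gene_id, fclass, (span,))
        tx_features[tx_id] = tx_feat
        tx_length[tx_id] = L
        strand_of[tx_id] = strand
        return chrom, tx_feat

    def record_site(tx_id, gene_id, fam_idx, pos, host_id, tx_feat, is_sponge):
        g = tx_feat.tx_to_genome(pos, pos + 8)[0]
        sites.append(SiteTruth(
            transcript_id=tx_id, gene_id=gene_id, family_id=f"fam{fam_idx}",
            family_index=fam_idx, tx_start=pos, tx_end=pos + 8,
            host_feature_id=host_id, chrom=g.chrom, g_start=g.start,
            g_end=g.end, strand=g.strand, is_sponge_site=is_sponge,
        ))

    # --- mRNAs: CDS then 3'UTR on the transcript
    for i in range(config.n_mrna):
        tx_id = f"mrna{i:04d}"
        gene_id = f"gene{i:04d}"
        cds_len = max(int(rng.lognormal(config.cds_meanlog, config.cds_sdlog)), 120)
        utr_len = max(int(rng.lognormal(config.utr_meanlog, config.utr_sdlog)), 60)
        L = cds_len + utr_len
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, tx_feat = add_tx(tx_id, gene_id, L, strand, "exon")
        features.append(tx_feat)  # transcript span, carries the tx->genome mapping
        utr_id = f"{tx_id}_utr3"
        features.append(FeatureAnnotation(
            f"{tx_id}_cds", gene_id, "cds", tuple(tx_feat.tx_to_genome(0, cds_len))))
        features.append(FeatureAnnotation(
            utr_id, gene_id, "three_prime_utr", tuple(tx_feat.tx_to_genome(cds_len, L))))
        utr_span[tx_id] = (cds_len, L)

        seq = _random_seq(rng, L)
        # implant at most one site per family, non-overlapping, inside the UTR
        taken: list[tuple[int, int]] = []
        for fam_idx in range(config.n_mirna_families):
            if rng.random() >= config.site_prob_per_utr:
                continue
            lo, hi = cds_len + 5, L - 13
            if hi <= lo:
                continue
            for _attempt in range(20):
                pos = int(rng.integers(lo, hi))
                if all(pos + 8 <= s or pos >= e for s, e in taken):
                    break
            else:
                continue
            taken.append((pos, pos + 8))
            _implant(seq, pos, motifs[fam_idx])
            record_site(tx_id, gene_id, fam_idx, pos, utr_id, tx_feat, False)
            if fam_idx == 0:
                target_genes.add(gene_id)
        seqs[tx_id] = "".join(_BASES[seq])
        expression[tx_id] = float(rng.lognormal(0.0, config.expr_sdlog))

    # --- lncRNAs (no CDS); lnc0000 is the sponge
    repeat_hosts = set()
    if config.n_rrna_repeats > 0:
        repeat_hosts = set(range(1, min(config.n_rrna_repeats + 1, config.n_lncrna)))
    for i in range(config.n_lncrna):
        tx_id = f"lnc{i:04d}"
        gene_id = tx_id
        L = max(int(rng.lognormal(config.lnc_meanlog, config.lnc_sdlog)), 300)
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, tx_feat = add_tx(tx_id, gene_id, L, strand, "lncRNA")
        features.append(tx_feat)
        seq = _random_seq(rng, L)
        if tx_id == config.sponge_feature_id:
            pos = L // 2
            _implant(seq, pos, motifs[0])
            record_site(tx_id, gene_id, 0, pos, tx_id, tx_feat, True)
            expression[tx_id] = config.sponge_expression
        else:
            expression[tx_id] = float(
                rng.lognormal(0.0, config.expr_sdlog) * config.lncrna_expr_scale
            )
        if i in repeat_hosts:
            rep_len = min(200, L // 4)
            rep_blocks = tx_feat.tx_to_genome(0, rep_len)
            features.append(FeatureAnnotation(
                f"rrna_rep{i:03d}", f"rrna_rep{i:03d}", "rrna_repeat", tuple(rep_blocks)))
        seqs[tx_id] = "".join(_BASES[seq])

    truth = GroundTruth(
        sponge_feature_id=config.sponge_feature_id,
        sites=sites,
        target_genes=sorted(target_genes),
        expression=expression,
        tx_length=tx_length,
        utr_span=utr_span,
        strand=strand_of,
    )
    return Transcriptome(seqs, features, tx_features, mirnas, truth)


def _site_multiplier(config: SimulationConfig, site: SiteTruth, genotype: str) -> float:
    if genotype == "WT" or site.family_index != 0:
        return 1.0
    if genotype == "sponge_mut":
        if site.is_sponge_site:
            return config.ablation_factor
        return 1.0 + config.sponge_redistribution_delta
    if genotype == "mirna_ko":
        return config.ablation_factor
    raise ValueError(f"unknown genotype {genotype!r}")


def simulate_clip_reads(
    config: SimulationConfig,
    truth: GroundTruth,
    genotype: str,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """Simulate one genotype's CLIP library as stranded fixed-length reads.

    Per-transcript totals are NB-dispersed around a mean proportional to
    transcript abundance times its (genotype-adjusted) binding weight, with
    the normaliser fixed at the WT weights so background coverage is
    genotype-independent; within a transcript, ``site_concentration`` of the
    weight sits on implanted seed sites (split equally) and the rest is
    uniform background.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}")
    if rng is None:
        rng = _rng(config, _STREAM_READS[genotype])

    tx_ids = sorted(truth.tx_length)
    n_tx = len(tx_ids)
    tx_pos = {t: i for i, t in enumerate(tx_ids)}
    L = np.array([truth.tx_length[t] for t in tx_ids], dtype=np.int64)
    expr = np.array([truth.expression[t] for t in tx_ids])
    rlen = config.read_length

    sites_by_tx: dict[int, list[SiteTruth]] = {}
    for s in truth.sites:
        sites_by_tx.setdefault(tx_pos[s.transcript_id], []).append(s)
    n_sites_tx = np.array([len(sites_by_tx.get(i, [])) for i in range(n_tx)])
    bg_w = np.where(n_sites_tx > 0, 1.0 - config.site_concentration, 1.0)

    max_k = int(n_sites_tx.max()) if n_tx else 0
    site_w = np.zeros((n_tx, max_k))
    for i, slist in sites_by_tx.items():
        base = config.site_concentration / len(slist)
        for k, s in enumerate(slist):
            site_w[i, k] = base * _site_multiplier(config, s, genotype)

    total_w = bg_w + site_w.sum(axis=1)
    normalizer = float(expr.sum())  # WT weights sum to expr by construction
    mean_reads = config.depth_per_library * expr * total_w / normalizer

    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mean_reads / shape)
        n_reads = rng.poisson(lam)
    else:
        n_reads = rng.poisson(mean_reads)

    # allocate reads to site slots by sequential binomial thinning
    remaining = n_reads.astype(np.int64)
    w_rem = total_w.copy()
    site_counts = np.zeros((n_tx, max_k), dtype=np.int64)
    for k in range(max_k):
        p = np.divide(site_w[:, k], w_rem, out=np.zeros(n_tx), where=w_rem > 0)
        c = rng.binomial(remaining, np.clip(p, 0.0, 1.0))
        site_counts[:, k] = c
        remaining -= c
        w_rem -= site_w[:, k]
    bg_counts = remaining

    chrom_names = np.array([f"chr_{t}" for t in tx_ids], dtype=object)
    strands = np.array([truth.strand[t] for t in tx_ids], dtype=object)

    parts_tx: list[np.ndarray] = []
    parts_start: list[np.ndarray] = []

    # background: uniform start over [0, L - rlen]
    tx_rep = np.repeat(np.arange(n_tx), bg_counts)
    span = np.maximum(L - rlen, 1)
    starts = np.floor(rng.random(len(tx_rep)) * span[tx_rep]).astype(np.int64)
    parts_tx.append(tx_rep)
    parts_start.append(starts)

    # site reads: start uniform over the window fully covering the site
    for i, slist in sites_by_tx.items():
        for k, s in enumerate(slist):
            c = site_counts[i, k]
            if c == 0:
                continue
            lo = max(s.tx_end - rlen, 0)
            hi = min(s.tx_start, truth.tx_length[s.transcript_id] - rlen)
            hi = max(hi, lo)
            st = lo + np.floor(rng.random(c) * (hi - lo + 1)).astype(np.int64)
            parts_tx.append(np.full(c, i, dtype=np.int64))
            parts_start.append(st)

    tx_all = np.concatenate(parts_tx)
    tx_start_all = np.concatenate(parts_start)
    # project transcript coordinates onto each transcript's chromosome
    minus = strands[tx_all] == "-"
    g_start = np.where(minus, L[tx_all] - tx_start_all - rlen, tx_start_all)
    g_start = np.maximum(g_start, 0)
    return ReadSet(
        chrom_names[tx_all], g_start, g_start + rlen, strands[tx_all]
    )


def simulate_contrasts(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene contrast tables for control-vs-sponge-mutant and control-vs-knockout.

    Target genes draw log2fc from Normal(+beta, sigma) in the mutant
    contrast (lower in the mutant under the log2(control/other) convention)
    and Normal(-beta, sigma) in the knockout contrast; non-targets from
    Normal(0, sigma). Adjusted p-values are a monotone transform of |log2fc|
    (BH over nominal normal tails), a stand-in for a full DE fit.
    """
    if rng is None:
        rng = _rng(config, _STREAM_CONTRASTS)
    genes = sorted({f"gene{i:04d}" for i in range(config.n_mrna)})
    is_target = np.array([g in set(truth.target_genes) for g in genes])
    beta, sigma = config.repression_beta, config.noise_sigma

    tables = {}
    for label, sign in (("mutant", +1.0), ("ko", -1.0)):
        mean = np.where(is_target, sign * beta, 0.0)
        lfc = rng.normal(mean, sigma)
        z = np.abs(lfc) / max(sigma / 2.0, 1e-9)
        pval = 2.0 * stats.norm.sf(z)
        _, padj, _, _ = multipletests(pval, method="fdr_bh")
        tables[label] = pd.DataFrame(
            {"gene_id": genes, "log2fc": lfc, "padj": padj}
        )
        truth.true_lfc[label] = {
            g: float(m) for g, m in zip(genes, mean)
        }
    return tables["mutant"], tables["ko"]


def write_dataset(config: SimulationConfig, outdir: str | os.PathLike) -> GroundTruth:
    """Generate and write the complete synthetic dataset to ``outdir``.

    Emits ``transcripts.fasta``, ``annotations.gff3``, ``mirnas.tsv``,
    ``reads_{WT,sponge_mut,mirna_ko}.bed``, ``contrast_{mutant,ko}.tsv`` and
    ``truth.json``. Byte-identical across runs with the same config.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    tr = simulate_transcriptome(config)
    write_fasta(tr.seqs, os.path.join(outdir, "transcripts.fasta"))
    write_gff3(tr.features, os.path.join(outdir, "annotations.gff3"))
    write_tsv(tr.mirnas, os.path.join(outdir, "mirnas.tsv"))
    for genotype in GENOTYPES:
        reads = simulate_clip_reads(config, tr.truth, genotype)
        write_reads_bed(reads, os.path.join(outdir, f"reads_{genotype}.bed"))
    mut, ko = simulate_contrasts(config, tr.truth)
    write_tsv(mut, os.path.join(outdir, "contrast_mutant.tsv"), float_format="%.8g")
    write_tsv(ko, os.path.join(outdir, "contrast_ko.tsv"), float_format="%.8g")
    tr.truth.to_json(os.path.join(outdir, "truth.json"))
    return tr.truth
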