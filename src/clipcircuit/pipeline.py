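"""End-to-end orchestration: quantify -> peaks -> sites -> occupancy -> expression.

Ties the stages into one reproducible run over a config of input paths and
stage parameters. Every stage writes a plain TSV into the output directory
and the run report echoes every parameter that can change a number, so two
runs with the same config and inputs produce byte-identical tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
import pandas as pd
import yaml

from . import __version__
from .annotate import (class_median_ratio, mask_repeat_features, rank_annotations,
                       summarize_annotations)
from .expression import concordance_partition, ecdf_ks_shift
from .io import (read_annotations, read_contrast_table, read_fasta,
                 read_mirna_table, read_reads_bed, write_tsv)
from .occupancy import (compute_site_occupancy, define_bound_target_set,
                        paired_occupancy_test, percent_change)
from .peaks import call_peaks_in_regions, rank_peaks
from .readsets import ReadIndex
from .seeds import assign_sites_to_features, families_from_table, scan_transcripts


@dataclass
class PipelineConfig:
    fasta: str
    annotations: str
    mirnas: str
    reads_wt: str
    reads_sponge_mut: str
    reads_mirna_ko: str
    contrast_mutant: str
    contrast_ko: str
    outdir: str
    bin_size: int = 30
    alpha_fdr: float = 0.01
    merge_gap: int = 0
    dedup: bool = False
    mask_rrna: bool = True
    occupancy_family: str = "fam0"
    occupancy_site_types: tuple[str, ...] = ("8mer",)
    lfc_min: float = 1.5
    padj_max: float = 0.001
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "occupancy_site_types" in raw:
            raw["occupancy_site_types"] = tuple(raw["occupancy_site_types"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("fasta", "annotations", "mirnas", "reads_wt",
                     "reads_sponge_mut", "reads_mirna_ko",
                     "contrast_mutant", "contrast_ko"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"input {name!r} not found: {path}")


@dataclass
class RunReport:
    params: dict
    stage_counts: dict[str, int] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict[str, object] = field(default_factory=dict)


def _fmt(v: object) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


#: Stage tables a complete run writes (and `rebuild_report` expects).
STAGE_TABLES = (
    "lncrna_ranking", "utr_ranking", "peak_ranking", "sites",
    "occupancy_per_site", "occupancy_summary", "ks_derepression", "concordance",
)


def generate_report(report: RunReport, outdir: str, write_tables: bool = True) -> str:
    """Write stage tables plus a deterministic plain-text summary.

    The summary contains no wall-clock, host, or output-path information;
    regenerating it from the same stage outputs is byte-identical. Table
    heads shown in the report are rendered from the TSVs on disk so a
    rebuilt report matches the original byte for byte.
    """
    os.makedirs(outdir, exist_ok=True)
    if write_tables:
        for name, df in report.tables.items():
            write_tsv(df, os.path.join(outdir, f"{name}.tsv"))
    meta = {
        "params": report.params,
        "stage_counts": report.stage_counts,
        "summary": report.summary,
    }
    with open(os.path.join(outdir, "run_meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    lines = [f"clipcircuit run report (version {__version__})", ""]
    lines.append("[parameters]")
    for k in sorted(report.params):
        if k == "outdir":
            continue  # where outputs land cannot change any number in them
        v = report.params[k]
        if isinstance(v, str) and os.sep in v:
            v = os.path.basename(v)
        lines.append(f"{k} = {_fmt(v)}")
    lines.append("")
    lines.append("[stage row counts]")
    for k in sorted(report.stage_counts):
        lines.append(f"{k} = {report.stage_counts[k]}")
    lines.append("")
    lines.append("[summary]")
    for k in sorted(report.summary):
        lines.append(f"{k} = {_fmt(report.summary[k])}")
    lines.append("")
    for name in ("lncrna_ranking", "peak_ranking"):
        path = os.path.join(outdir, f"{name}.tsv")
        if os.path.exists(path):
            head = pd.read_csv(path, sep="\t", nrows=10)
            if not head.empty:
                lines.append(f"[{name} head]")
                lines.append(head.to_string(index=False))
                lines.append("")
    text = "\n".join(lines)
    path = os.path.join(outdir, "report.txt")
    with open(path, "w") as fh:
        fh.write(text)
    return path


def rebuild_report(outdir: str) -> str:
    """Regenerate ``report.txt`` from the stage outputs already in ``outdir``.

    Fails listing the missing files when any stage table (or the run
    metadata) is absent; idempotent when everything is present.
    """
    missing = [
        f"{name}.tsv" for name in STAGE_TABLES
        if not os.path.exists(os.path.join(outdir, f"{name}.tsv"))
    ]
    if not os.path.exists(os.path.join(outdir, "run_meta.yaml")):
        missing.append("run_meta.yaml")
    if missing:
        raise FileNotFoundError(
            f"cannot rebuild report; missing stage outputs in {outdir}: "
            + ", ".join(sorted(missing))
        )
    with open(os.path.join(outdir, "run_meta.yaml")) as fh:
        meta = yaml.safe_load(fh)
    report = RunReport(
        params=meta["params"],
        stage_counts=meta["stage_counts"],
        summary=meta["summary"],
    )
    return generate_report(report, outdir, write_tables=False)


def run_full_analysis(config: PipelineConfig) -> RunReport:
    """Execute the full analysis chain and write all stage outputs.

    Stages: annotation quantification and lncRNA ranking; peak calling on
    lncRNAs; seed-site scanning and assignment; per-site occupancy with
    paired genotype tests; target-derepression KS analyses; concordance
    partition. Any stage error aborts the run with the stage named.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    params = asdict(config)
    params["occupancy_site_types"] = ",".join(config.occupancy_site_types)
    report = RunReport(params=params)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return deco

    # --- load inputs
    @stage("load")
    def loaded():
        seqs = read_fasta(config.fasta)
        features = read_annotations(config.annotations, "gff3")
        mirnas = read_mirna_table(config.mirnas)
        reads = {
            "WT": read_reads_bed(config.reads_wt, dedup=config.dedup),
            "sponge_mut": read_reads_bed(config.reads_sponge_mut, dedup=config.dedup),
            "mirna_ko": read_reads_bed(config.reads_mirna_ko, dedup=config.dedup),
        }
        return seqs, features, mirnas, reads

    seqs, features, mirnas, reads = loaded
    indexes = {g: ReadIndex(r) for g, r in reads.items()}
    for g, r in reads.items():
        report.stage_counts[f"reads_{g}"] = len(r)

    repeats = [f for f in features if f.feature_class == "rrna_repeat"]
    # unmasked features keep the full transcript->genome mapping for site projection
    unmasked_features = [f for f in features if f.feature_class != "rrna_repeat"]
    analysis_features = unmasked_features
    if config.mask_rrna and repeats:
        analysis_features = mask_repeat_features(unmasked_features, repeats)

    # --- annotation quantification (WT library)
    @stage("quantify")
    def quant():
        summaries = summarize_annotations(indexes["WT"], analysis_features)
        lnc = rank_annotations(summaries, "lncRNA")
        utr = rank_annotations(summaries, "three_prime_utr")
        try:
            ratio = class_median_ratio(summaries, "lncRNA", "three_prime_utr")
        except ValueError:
            ratio = float("nan")
        return summaries, lnc, utr, ratio

    summaries, lnc_rank, utr_rank, median_ratio = quant
    report.tables["lncrna_ranking"] = lnc_rank
    report.tables["utr_ranking"] = utr_rank
    report.stage_counts["lncrna_ranked"] = len(lnc_rank)
    report.summary["utr_to_lncrna_median_read_ratio"] = median_ratio

    # --- peak calling on lncRNA annotations (WT library)
    @stage("peaks")
    def peak_stage():
        regions = [
            (f.feature_id, f.span)
            for f in analysis_features
            if f.feature_class == "lncRNA"
        ]
        peaks = call_peaks_in_regions(
            indexes["WT"], regions, bin_size=config.bin_size,
            alpha_fdr=config.alpha_fdr, merge_gap=config.merge_gap,
        )
        return peaks, rank_peaks(peaks)

    peaks, peak_table = peak_stage
    report.tables["peak_ranking"] = peak_table
    report.stage_counts["peaks_called"] = len(peaks)

    # --- seed sites
    @stage("sites")
    def site_stage():
        families = families_from_table(mirnas)
        tx_feats = {f.feature_id: f for f in unmasked_features if f.feature_id in seqs}
        sites = scan_transcripts(seqs, families, tx_feats)
        assign_sites_to_features(sites, analysis_features, peaks)
        rows = [
            {
                "site_id": s.site_id, "family": s.family_id, "type": s.site_type,
                "transcript_id": s.transcript_id, "tx_start": s.tx_start,
                "tx_end": s.tx_end,
                "chrom": s.genomic_blocks[0].chrom if s.genomic_blocks else "",
                "g_start": s.genomic_blocks[0].start if s.genomic_blocks else -1,
                "g_end": s.genomic_blocks[-1].end if s.genomic_blocks else -1,
                "strand": s.genomic_blocks[0].strand if s.genomic_blocks else ".",
                "host_feature": s.host_feature_id or "",
                "host_gene": s.host_gene_id or "",
                "in_peak": s.in_peak,
            }
            for s in sites
        ]
        return sites, pd.DataFrame(rows)

    sites, site_table = site_stage
    report.tables["sites"] = site_table
    report.stage_counts["sites_scanned"] = len(sites)

    # --- occupancy
    @stage("occupancy")
    def occ_stage():
        utrs = {
            f.feature_id: f
            for f in analysis_features
            if f.feature_class == "three_prime_utr"
        }
        focus = [
            s for s in sites
            if s.family_id == config.occupancy_family
            and s.site_type in config.occupancy_site_types
            and s.host_feature_id in utrs
        ]
        occ = {
            g: compute_site_occupancy(indexes[g], focus, utrs, g)
            for g in ("WT", "sponge_mut", "mirna_ko")
        }
        bound = define_bound_target_set(occ, ("WT", "sponge_mut"))
        bound_ids = {s.site_id for s in bound.sites}
        occ_b = {
            g: [o for o in lst if o.site.site_id in bound_ids]
            for g, lst in occ.items()
        }
        res_mut = paired_occupancy_test(occ_b["WT"], occ_b["sponge_mut"])
        res_ko = paired_occupancy_test(occ_b["WT"], occ_b["mirna_ko"])
        rows = []
        for g, lst in occ_b.items():
            for o in lst:
                rows.append({
                    "site_id": o.site.site_id, "gene": o.site.host_gene_id,
                    "genotype": g, "site_reads": o.site_reads,
                    "utr_reads": o.utr_reads, "f": o.f,
                    "logit_f": "" if o.logit_f is None else o.logit_f,
                    "nb": o.nb_flag,
                })
        per_site = pd.DataFrame(rows).sort_values(
            ["site_id", "genotype"], kind="mergesort").reset_index(drop=True)
        return bound, res_mut, res_ko, per_site

    bound, res_mut, res_ko, per_site = occ_stage
    report.tables["occupancy_per_site"] = per_site
    report.stage_counts["bound_sites"] = bound.n_sites
    report.stage_counts["bound_genes"] = bound.n_genes
    occ_summary = pd.DataFrame([
        {
            "comparison": "WT_vs_sponge_mut",
            "mean_pct_a": res_mut.mean_pct_a, "mean_pct_b": res_mut.mean_pct_b,
            "percent_change": percent_change(res_mut.mean_pct_a, res_mut.mean_pct_b),
            "t": res_mut.t, "p": res_mut.p, "n_pairs": res_mut.n, "n_nb": res_mut.n_nb,
        },
        {
            "comparison": "WT_vs_mirna_ko",
            "mean_pct_a": res_ko.mean_pct_a, "mean_pct_b": res_ko.mean_pct_b,
            "percent_change": percent_change(res_ko.mean_pct_a, res_ko.mean_pct_b),
            "t": res_ko.t, "p": res_ko.p, "n_pairs": res_ko.n, "n_nb": res_ko.n_nb,
        },
    ])
    report.tables["occupancy_summary"] = occ_summary
    report.summary["occupancy_pct_wt"] = res_mut.mean_pct_a
    report.summary["occupancy_pct_sponge_mut"] = res_mut.mean_pct_b
    report.summary["occupancy_pct_mirna_ko"] = res_ko.mean_pct_b
    report.summary["occupancy_pct_change_ko"] = percent_change(
        res_ko.mean_pct_a, res_ko.mean_pct_b)

    # --- expression analyses
    @stage("derepress")
    def ks_stage():
        mut = read_contrast_table(config.contrast_mutant, "control_vs_sponge_mut")
        ko = read_contrast_table(config.contrast_ko, "control_vs_mirna_ko")
        targets = bound.genes
        ks_mut = ecdf_ks_shift(mut, targets)
        ks_ko = ecdf_ks_shift(ko, targets)
        ks_table = pd.DataFrame([
            {"contrast": "control_vs_sponge_mut", "D": ks_mut.D, "p": ks_mut.p,
             "n_target": ks_mut.n_target, "n_background": ks_mut.n_background,
             "shift_direction": ks_mut.shift_direction},
            {"contrast": "control_vs_mirna_ko", "D": ks_ko.D, "p": ks_ko.p,
             "n_target": ks_ko.n_target, "n_background": ks_ko.n_background,
             "shift_direction": ks_ko.shift_direction},
        ])
        return mut, ko, ks_table

    mut_table, ko_table, ks_table = ks_stage
    report.tables["ks_derepression"] = ks_table

    @stage("concordance")
    def conc_stage():
        part = concordance_partition(mut_table, ko_table, bound.genes)
        return part

    part = conc_stage
    report.tables["concordance"] = part.to_frame()
    report.summary["concordance_union_pct"] = part.pct_union
    report.summary["concordance_total"] = part.total

    if not lnc_rank.empty:
        report.summary["top_lncrna"] = str(lnc_rank.iloc[0]["feature_id"])
    generate_report(report, config.outdir)
    return report
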