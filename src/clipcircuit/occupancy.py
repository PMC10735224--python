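"""Per-site relative Ago2 occupancy within 3'UTRs and paired genotype tests.

For each predicted seed site, occupancy is the fraction ``f`` of the host
3'UTR's CLIP reads that overlap the site — a within-UTR normalisation that
cancels expression differences between genotypes. Fractions are compared
between genotypes on the logit scale with a paired t-test over sites; sites
with zero reads in a genotype are flagged NB ("no binding"), excluded from
the paired test (their logit is undefined) but included as zeros in the
reported genotype means on the percentage scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import FeatureAnnotation
from .readsets import ReadIndex, ReadSet
from .seeds import SeedSite


@dataclass
class SiteOccupancy:
    site: SeedSite
    genotype: str
    site_reads: int
    utr_reads: int
    f: float
    logit_f: float | None
    nb_flag: bool


@dataclass
class BoundTargetSet:
    """Sites with CLIP evidence in both qualifying genotypes, and their genes."""

    sites: list[SeedSite]
    genes: set[str]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class PairedOccupancyResult:
    mean_pct_a: float
    mean_pct_b: float
    t: float
    p: float
    n: int
    n_nb: int


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (68.75 -> 69)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def site_fraction(site_reads: int, utr_reads: int) -> tuple[float, float | None, bool]:
    """Occupancy fraction, its logit, and the no-binding flag.

    ``f = site_reads / utr_reads``. Zero site reads set the NB flag and
    leave the logit undefined; ``f == 1`` is pulled to ``n/(n+1)`` before
    the logit so every emitted logit is finite.
    """
    if utr_reads < 1:
        raise ValueError("utr_reads must be >= 1")
    if site_reads < 0:
        raise ValueError("site_reads must be >= 0")
    if site_reads > utr_reads:
        raise ValueError(f"site_reads ({site_reads}) > utr_reads ({utr_reads})")
    f = site_reads / utr_reads
    if site_reads == 0:
        return 0.0, None, True
    f_for_logit = utr_reads / (utr_reads + 1) if site_reads == utr_reads else f
    return f, math.log(f_for_logit / (1.0 - f_for_logit)), False


def compute_site_occupancy(
    reads: ReadSet | ReadIndex,
    sites: Sequence[SeedSite],
    utrs_by_id: Mapping[str, FeatureAnnotation],
    genotype: str,
) -> list[SiteOccupancy]:
    """Count reads at each site and in its host UTR for one genotype's library.

    Site reads are reads overlapping the site's genomic interval by >= 1 nt
    (the same overlap rule used for annotation totals); UTR reads are the
    union count over the host feature's blocks. Sites whose host UTR has no
    reads are skipped (the fraction is undefined).
    """
    index = reads if isinstance(reads, ReadIndex) else ReadIndex(reads)
    utr_cache: dict[str, int] = {}
    out: list[SiteOccupancy] = []
    for site in sites:
        host = site.host_feature_id
        if host is None or host not in utrs_by_id or not site.genomic_blocks:
            continue
        if host not in utr_cache:
            utr_cache[host] = index.count_feature(utrs_by_id[host])
        utr_reads = utr_cache[host]
        if utr_reads < 1:
            continue
        if len(site.genomic_blocks) == 1:
            gb = site.genomic_blocks[0]
            site_reads = index.count_overlapping(gb.chrom, gb.start, gb.end, gb.strand)
        else:  # site straddles a block junction: union count over its pieces
            site_reads = index.count_feature(
                FeatureAnnotation(site.site_id, site.site_id, "other", site.genomic_blocks)
            )
        site_reads = min(site_reads, utr_reads)
        f, logit_f, nb = site_fraction(site_reads, utr_reads)
        out.append(SiteOccupancy(site, genotype, site_reads, utr_reads, f, logit_f, nb))
    return out


def define_bound_target_set(
    occupancy_by_genotype: Mapping[str, Sequence[SiteOccupancy]],
    genotypes: tuple[str, str],
) -> BoundTargetSet:
    """Sites with at least one read in BOTH named genotypes, plus host genes."""
    ga, gb = genotypes
    reads_a = {o.site.site_id: o.site_reads for o in occupancy_by_genotype[ga]}
    reads_b = {o.site.site_id: o.site_reads for o in occupancy_by_genotype[gb]}
    sites = [
        o.site
        for o in occupancy_by_genotype[ga]
        if reads_a.get(o.site.site_id, 0) >= 1 and reads_b.get(o.site.site_id, 0) >= 1
    ]
    genes = {s.host_gene_id for s in sites if s.host_gene_id is not None}
    return BoundTargetSet(sites=sites, genes=genes)


def paired_occupancy_test(
    occ_a: Sequence[SiteOccupancy], occ_b: Sequence[SiteOccupancy]
) -> PairedOccupancyResult:
    """Paired t-test on logit occupancy over sites bound in both genotypes.

    Genotype means are reported on the percentage scale over *all* paired
    sites, counting NB sites as zero occupancy; the t-test itself uses only
    sites with a finite logit in both genotypes.
    """
    a_by_id = {o.site.site_id: o for o in occ_a}
    b_by_id = {o.site.site_id: o for o in occ_b}
    common = [sid for sid in a_by_id if sid in b_by_id]
    fa = np.array([a_by_id[s].f for s in common])
    fb = np.array([b_by_id[s].f for s in common])
    la, lb = [], []
    n_nb = 0
    for sid in common:
        oa, ob = a_by_id[sid], b_by_id[sid]
        if oa.nb_flag or ob.nb_flag:
            n_nb += 1
            continue
        la.append(oa.logit_f)
        lb.append(ob.logit_f)
    if len(la) < 3:
        raise ValueError(f"need >= 3 non-NB pairs for the paired test, got {len(la)}")
    la, lb = np.array(la), np.array(lb)
    if np.allclose(la, lb):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(la, lb)
    return PairedOccupancyResult(
        mean_pct_a=float(100.0 * fa.mean()),
        mean_pct_b=float(100.0 * fb.mean()),
        t=float(t),
        p=float(p),
        n=len(la),
        n_nb=n_nb,
    )


def percent_change(mean_a: float, mean_b: float) -> int:
    """Percent change from baseline ``mean_a``, rounded to the whole percent.

    Positive values mean a reduction relative to the baseline genotype
    (e.g. means of 3.2 and 1.0 give a 69% reduction).
    """
    if mean_a == 0:
        raise ValueError("zero baseline mean")
    return round_half_away(100.0 * (mean_a - mean_b) / mean_a)
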