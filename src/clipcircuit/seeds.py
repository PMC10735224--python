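"""miRNA seed definition and canonical seed-match site scanning.

The seed of a mature miRNA is nucleotides 2-8 (1-based). A target site on
the sense strand of a transcript is classified by the extent of Watson-
Crick complementarity to the seed plus the adenine opposite miRNA
position 1:

* ``8mer``     — perfect match to positions 2-8 followed by an A
* ``7mer-m8``  — perfect match to positions 2-8 (no A1)
* ``7mer-A1``  — match to positions 2-7 followed by an A
* ``6mer``     — match to positions 2-7 only

Every candidate locus (anchored at its position-2-7 hexamer match) is
reported once, at its highest-priority type. ``N`` bases never match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .intervals import FeatureAnnotation, GenomicInterval
from .peaks import Peak

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_PRIORITY = {t: i for i, t in enumerate(SITE_TYPES)}


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA or DNA string, returned as DNA."""
    return "".join(_RC[c] for c in reversed(seq.upper().replace("T", "T")))


def seed_from_mirna(mature: str) -> str:
    """The 7-nt seed: positions 2-8 (1-based) of the mature miRNA sequence."""
    mature = mature.upper()
    if len(mature) < 8:
        raise ValueError(f"mature miRNA shorter than 8 nt: {mature!r}")
    bad = set(mature) - set("ACGU")
    if bad:
        raise ValueError(f"mature sequence must be RNA (A/C/G/U), found {sorted(bad)}")
    return mature[1:8]


@dataclass
class MirnaFamily:
    """A miRNA family: members sharing an identical positions-2-8 seed."""

    family_id: str
    mature_sequences: list[str]
    seed: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.mature_sequences:
            raise ValueError("family needs at least one mature sequence")
        seeds = {seed_from_mirna(m) for m in self.mature_sequences}
        if len(seeds) != 1:
            raise ValueError(
                f"family {self.family_id}: members disagree at positions 2-8: {sorted(seeds)}"
            )
        self.seed = seeds.pop()


@dataclass
class SeedSite:
    family_id: str
    site_type: str
    transcript_id: str
    tx_start: int
    tx_end: int
    genomic_blocks: tuple[GenomicInterval, ...] = ()
    host_feature_id: str | None = None
    host_gene_id: str | None = None
    in_peak: bool = False

    @property
    def site_id(self) -> str:
        return f"{self.transcript_id}:{self.tx_start}-{self.tx_end}:{self.family_id}"


def families_from_table(df) -> list[MirnaFamily]:
    """Group a mature-miRNA table (family_id, mirna_id, sequence) into families."""
    fams = []
    for fam_id, grp in df.groupby("family_id", sort=True):
        fams.append(MirnaFamily(str(fam_id), [str(s) for s in grp["sequence"]]))
    return fams


def scan_sites(seq: str, family: MirnaFamily, transcript_id: str = "") -> list[SeedSite]:
    """Scan a sense-strand transcript sequence for seed-match sites.

    Candidate loci are anchored at matches of the reverse complement of the
    positions 2-7 hexamer; each locus is then promoted to the highest type
    its flanking bases support, so no locus is double-reported.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    rc_seed = reverse_complement(family.seed)        # pairs positions 8..2
    rc_hex = rc_seed[1:]                             # pairs positions 7..2
    m8_base = rc_seed[0]                             # complement of position 8
    L = len(seq)
    sites: list[SeedSite] = []
    start = 0
    while True:
        c = seq.find(rc_hex, start)
        if c == -1:
            break
        start = c + 1
        has_m8 = c >= 1 and seq[c - 1] == m8_base
        has_a1 = c + 6 < L and seq[c + 6] == "A"
        if has_m8 and has_a1:
            stype, s, e = "8mer", c - 1, c + 7
        elif has_m8:
            stype, s, e = "7mer-m8", c - 1, c + 6
        elif has_a1:
            stype, s, e = "7mer-A1", c, c + 7
        else:
            stype, s, e = "6mer", c, c + 6
        sites.append(SeedSite(family.family_id, stype, transcript_id, s, e))
    return sites


def scan_transcripts(
    seqs: dict[str, str],
    families: Sequence[MirnaFamily],
    features_by_tx: dict[str, FeatureAnnotation] | None = None,
) -> list[SeedSite]:
    """Scan every transcript for every family; optionally project to genome.

    ``features_by_tx`` maps transcript_id to the annotation that carries the
    transcript's genomic blocks (used to project transcript coordinates).
    """
    out: list[SeedSite] = []
    for tx_id in sorted(seqs):
        for fam in families:
            for site in scan_sites(seqs[tx_id], fam, transcript_id=tx_id):
                if features_by_tx and tx_id in features_by_tx:
                    feat = features_by_tx[tx_id]
                    site.genomic_blocks = tuple(feat.tx_to_genome(site.tx_start, site.tx_end))
                    site.host_feature_id = feat.feature_id
                    site.host_gene_id = feat.gene_id
                out.append(site)
    return out


def assign_sites_to_features(
    sites: Sequence[SeedSite],
    features: Sequence[FeatureAnnotation],
    peaks: Sequence[Peak] = (),
) -> list[SeedSite]:
    """Label each site with its containing 3'UTR/lncRNA and containing peak.

    A site counts as inside a feature or peak only when its *full* genomic
    extent (every projected block) lies within the region; a site straddling
    a peak boundary is not "in peak". Existing host labels (e.g. the scanned
    transcript) are replaced by the containing 3'UTR or lncRNA, or cleared
    when the site lies in neither.
    """
    hosts_by_chrom: dict[str, list[FeatureAnnotation]] = {}
    for f in features:
        if f.feature_class in ("three_prime_utr", "lncRNA"):
            hosts_by_chrom.setdefault(f.chrom, []).append(f)
    peaks_by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.region.chrom, []).append(p)
    for site in sites:
        if not site.genomic_blocks:
            continue
        chrom = site.genomic_blocks[0].chrom
        site.host_feature_id = None
        for f in hosts_by_chrom.get(chrom, ()):
            if all(
                any(b.contains(gb) for b in f.blocks) for gb in site.genomic_blocks
            ):
                site.host_feature_id = f.feature_id
                site.host_gene_id = f.gene_id
                break
        site.in_peak = any(
            all(p.region.contains(gb) for gb in site.genomic_blocks)
            for p in peaks_by_chrom.get(chrom, ())
        )
    return list(sites)
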