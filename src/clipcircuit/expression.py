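"""Target derepression analyses on per-gene expression contrasts.

Contrast tables carry one row per gene with ``log2fc = log2(first-named /
second-named condition)`` and a BH-adjusted p-value; the fold-change fits
themselves (DESeq2 or similar) happen upstream. This module compares the
fold-change distribution of miRNA target genes against non-targets
(ECDF/Kolmogorov-Smirnov), partitions targets by the sign of their response
in a sponge-mutant and a miRNA-knockout contrast, builds threshold gene
sets, applies the expressed-gene CPM pre-filter, and converts qPCR Ct
values to relative expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .occupancy import round_half_away


@dataclass
class KsResult:
    D: float
    p: float
    n_target: int
    n_background: int
    shift_direction: int  # sign of median(target) - median(background)


@dataclass
class ConcordancePartition:
    """Counts of bound targets by response sign in the two contrasts.

    ``n_down_in_mutant``: log2fc(control vs mutant) > 0 (lower in mutant);
    ``n_up_in_ko``: log2fc(control vs ko) < 0 (higher in knockout);
    ``n_both``: both; ``n_union`` by inclusion-exclusion. Percentages are
    whole percent of ``total``, rounded half away from zero.
    """

    total: int
    n_down_in_mutant: int
    n_up_in_ko: int
    n_both: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.n_both > min(self.n_down_in_mutant, self.n_up_in_ko):
            raise ValueError("n_both exceeds a marginal count")
        if max(self.n_down_in_mutant, self.n_up_in_ko) > self.total:
            raise ValueError("marginal count exceeds total")

    @property
    def n_union(self) -> int:
        return self.n_down_in_mutant + self.n_up_in_ko - self.n_both

    def _pct(self, n: int) -> int:
        return round_half_away(100.0 * n / self.total)

    @property
    def pct_union(self) -> int:
        return self._pct(self.n_union)

    @property
    def pct_down_in_mutant(self) -> int:
        return self._pct(self.n_down_in_mutant)

    @property
    def pct_up_in_ko(self) -> int:
        return self._pct(self.n_up_in_ko)

    @property
    def pct_both(self) -> int:
        return self._pct(self.n_both)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("total", self.total, 100),
                ("down_in_mutant", self.n_down_in_mutant, self.pct_down_in_mutant),
                ("up_in_ko", self.n_up_in_ko, self.pct_up_in_ko),
                ("both", self.n_both, self.pct_both),
                ("union", self.n_union, self.pct_union),
                ("dropped", self.n_dropped, 0),
            ],
            columns=["category", "count", "percent"],
        )


def ecdf_ks_shift(table: pd.DataFrame, target_genes: set[str]) -> KsResult:
    """Two-sample KS test of target vs non-target log2 fold changes.

    Background is every gene in the table not in the target set. Uses the
    exact two-sample distribution when either group has fewer than 30
    genes, the asymptotic one otherwise. Requires >= 10 genes per group.
    """
    in_target = table["gene_id"].isin(target_genes)
    tgt = table.loc[in_target, "log2fc"].to_numpy(dtype=float)
    bg = table.loc[~in_target, "log2fc"].to_numpy(dtype=float)
    if len(tgt) < 10 or len(bg) < 10:
        raise ValueError(
            f"need >= 10 genes per group, got {len(tgt)} targets / {len(bg)} background"
        )
    method = "exact" if min(len(tgt), len(bg)) < 30 else "asymp"
    res = stats.ks_2samp(tgt, bg, method=method)
    direction = int(np.sign(np.median(tgt) - np.median(bg)))
    return KsResult(
        D=float(res.statistic), p=float(res.pvalue),
        n_target=len(tgt), n_background=len(bg), shift_direction=direction,
    )


def concordance_partition(
    table_mutant: pd.DataFrame, table_ko: pd.DataFrame, targets: set[str]
) -> ConcordancePartition:
    """Partition target genes by response sign in the two contrasts.

    Sign rules are strict (a log2fc of exactly 0 falls in neither circle).
    Targets missing from either table are dropped and counted in
    ``n_dropped``.
    """
    if not targets:
        raise ValueError("empty target set")
    lfc_mut = table_mutant.set_index("gene_id")["log2fc"]
    lfc_ko = table_ko.set_index("gene_id")["log2fc"]
    present = [g for g in targets if g in lfc_mut.index and g in lfc_ko.index]
    n_dropped = len(targets) - len(present)
    down = lfc_mut.loc[present] > 0
    up = lfc_ko.loc[present] < 0
    return ConcordancePartition(
        total=len(present),
        n_down_in_mutant=int(down.sum()),
        n_up_in_ko=int(up.sum()),
        n_both=int((down.to_numpy() & up.to_numpy()).sum()),
        n_dropped=n_dropped,
    )


def build_response_gene_set(
    reference_table: pd.DataFrame, lfc_min: float = 1.5, padj_max: float = 0.001
) -> set[str]:
    """Genes with ``log2fc > lfc_min`` and ``padj < padj_max`` (both strict)."""
    sel = (reference_table["log2fc"] > lfc_min) & (reference_table["padj"] < padj_max)
    return set(reference_table.loc[sel, "gene_id"])


def cpm_filter(counts: pd.DataFrame, min_mean_cpm: float = 2.0) -> pd.DataFrame:
    """Drop lowly expressed genes from a raw count table.

    ``counts`` has genes as rows and sample libraries as columns. Genes with
    a mean counts-per-million across all samples below ``min_mean_cpm`` are
    removed — the expressed-gene universe used by the ECDF analyses.
    """
    cpm = counts / counts.sum(axis=0) * 1e6
    return counts.loc[cpm.mean(axis=1) >= min_mean_cpm]


def qpcr_expression(
    ct_target: float | Sequence[float], ct_reference: float | Sequence[float]
) -> float:
    """Relative qPCR expression ``2**-(Ct_target - Ct_reference)``.

    Technical replicates (passed as sequences) are averaged before the
    delta-Ct subtraction.
    """
    ct_t = float(np.mean(np.asarray(ct_target, dtype=float)))
    ct_r = float(np.mean(np.asarray(ct_reference, dtype=float)))
    return float(2.0 ** (-(ct_t - ct_r)))
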