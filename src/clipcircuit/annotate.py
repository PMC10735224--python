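"""Annotation-level occupancy: summed reads, repeat masking, ranking.

Quantifies Argonaute occupancy by integrating CLIP reads across whole
feature annotations (a read overlapping a feature by >= 1 nt counts once;
a read spanning k features contributes to all k, since each feature is
summarised independently). Ranks are computed within a feature class among
features with at least one read, and the percentile reported is
``100 * rank / N_positive`` — "top X%" among bound annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import FeatureAnnotation, subtract_intervals
from .readsets import ReadIndex, ReadSet


@dataclass
class AnnotationSummary:
    feature_id: str
    gene_id: str
    feature_class: str
    total_reads: int
    length_nt: int

    @property
    def density(self) -> float:
        return self.total_reads / self.length_nt


def sum_reads_over_annotation(reads: ReadSet | ReadIndex, feature: FeatureAnnotation) -> int:
    """Count same-strand reads overlapping any block of ``feature`` by >= 1 nt."""
    index = reads if isinstance(reads, ReadIndex) else ReadIndex(reads)
    return index.count_feature(feature)


def summarize_annotations(
    reads: ReadSet | ReadIndex, features: Sequence[FeatureAnnotation]
) -> list[AnnotationSummary]:
    index = reads if isinstance(reads, ReadIndex) else ReadIndex(reads)
    return [
        AnnotationSummary(
            f.feature_id, f.gene_id, f.feature_class, index.count_feature(f), f.length
        )
        for f in features
    ]


def mask_repeat_features(
    features: Sequence[FeatureAnnotation], repeats: Sequence[FeatureAnnotation]
) -> list[FeatureAnnotation]:
    """Remove rRNA-repeat intervals from every feature's blocks.

    Features left with zero length are dropped. Masking can only remove
    sequence, so the post-mask read total is <= the pre-mask total for any
    read set.
    """
    for r in repeats:
        if r.feature_class != "rrna_repeat":
            raise ValueError(f"repeat feature {r.feature_id} has class {r.feature_class}")
    repeat_blocks = [b for r in repeats for b in r.blocks]
    out: list[FeatureAnnotation] = []
    for f in features:
        kept = subtract_intervals(list(f.blocks), repeat_blocks)
        if kept:
            out.append(f.with_blocks(kept))
    return out


def _ranked_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Sort positives by (reads desc, density desc, feature_id) and attach ranks."""
    pos = df[df["total_reads"] > 0].copy()
    pos["density"] = pos["total_reads"] / pos["length_nt"]
    pos = pos.sort_values(
        by=["total_reads", "density", "feature_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    n_positive = len(pos)
    pos["rank"] = np.arange(1, n_positive + 1)
    pos["percentile_top"] = 100.0 * pos["rank"] / n_positive
    return pos


def rank_annotations(
    summaries: Sequence[AnnotationSummary], class_filter: str | None = None
) -> pd.DataFrame:
    """Rank annotations of one class by total reads.

    Only features with ``total_reads > 0`` are ranked (and returned): the
    percentile denominator is the count of bound annotations. Ties break by
    descending density, then feature_id, so the order is deterministic.
    """
    rows = [
        {
            "feature_id": s.feature_id,
            "gene_id": s.gene_id,
            "feature_class": s.feature_class,
            "length_nt": s.length_nt,
            "total_reads": s.total_reads,
        }
        for s in summaries
        if class_filter is None or s.feature_class == class_filter
    ]
    df = pd.DataFrame(
        rows,
        columns=["feature_id", "gene_id", "feature_class", "length_nt", "total_reads"],
    )
    if df.empty:
        df["density"] = pd.Series(dtype=float)
        df["rank"] = pd.Series(dtype=int)
        df["percentile_top"] = pd.Series(dtype=float)
        return df
    return _ranked_frame(df)


def class_median_ratio(
    summaries: Sequence[AnnotationSummary], class_a: str, class_b: str
) -> float:
    """``median(total_reads of class_b) / median(total_reads of class_a)``.

    Medians are taken over features with at least one read; e.g. with
    class_a=lncRNA and class_b=three_prime_utr a value of 7.8 means the
    median lncRNA has 7.8x fewer reads than the median 3'UTR.
    """
    a = [s.total_reads for s in summaries if s.feature_class == class_a and s.total_reads > 0]
    b = [s.total_reads for s in summaries if s.feature_class == class_b and s.total_reads > 0]
    if not a or not b:
        raise ValueError("both classes need at least one feature with reads")
    med_a = float(np.median(a))
    if med_a == 0:
        raise ValueError("zero median in denominator class")
    return float(np.median(b)) / med_a
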