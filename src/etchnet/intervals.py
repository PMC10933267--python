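"""Genomic interval operations: peak annotation, enhancer overlap,
peak-set comparison.

Coordinates are BED-style: 0-based, half-open ``[start, end)``. Peaks
are annotated by the distance from their midpoint to the nearest
transcription start site (TSS), signed negative when the peak lies
upstream of the TSS relative to the gene's strand. Categories follow
the promoter windows used for ChIP-seq peak annotation: a proximal
promoter is 0-1 kb from a TSS, a distal promoter window extends to
3 kb, peaks overlapping an annotated gene body fall into that category,
and everything else is intergenic.

Peak-set comparison follows the "closest with distance 0" convention:
two peaks are shared iff they overlap by at least one base (touching
half-open intervals do not overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

CATEGORY_PROXIMAL = "promoter_0_1kb"
CATEGORY_DISTAL = "promoter_1_3kb"
CATEGORY_GENE_BODY = "gene_body"
CATEGORY_INTERGENIC = "intergenic"

DEFAULT_WINDOWS = (1000, 3000)  # |distance| cutoffs, ordered


def _validate_bed(frame: pd.DataFrame, what: str) -> None:
    if frame.empty:
        return
    if not ((frame["start"] >= 0) & (frame["start"] < frame["end"])).all():
        raise ValueError(f"{what}: intervals must satisfy 0 <= start < end")


def _trees(frame: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for rec in frame.itertuples():
        trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end)
    return trees


def annotate_peaks(peaks: pd.DataFrame, tss: pd.DataFrame,
                   features: pd.DataFrame | None = None,
                   windows: Sequence[int] = DEFAULT_WINDOWS,
                   use_summit: bool = False) -> tuple[pd.DataFrame, dict]:
    """Annotate peaks with nearest-TSS distance and feature category.

    Parameters
    ----------
    peaks : BED-like frame (chrom, start, end[, name][, summit]).
    tss : frame with gene_id, chrom, tss_position, strand.
    features : optional BED-like gene-body annotation.
    windows : ordered |distance| cutoffs for the promoter categories.
    use_summit : measure from a ``summit`` column instead of the midpoint.

    Returns the annotated table plus category proportions (percent,
    summing to 100). Peaks on chromosomes absent from the TSS table are
    intergenic with a ``no_tss`` flag.
    """
    if tss.empty:
        raise ValueError("TSS table must be non-empty")
    if list(windows) != sorted(windows):
        raise ValueError("windows must be ordered")
    _validate_bed(peaks, "peaks")

    tss_by_chrom = {}
    for chrom, group in tss.groupby("chrom"):
        g = group.sort_values("tss_position")
        tss_by_chrom[chrom] = (g["tss_position"].to_numpy(),
                               g["gene_id"].to_numpy(),
                               g["strand"].to_numpy())
    feature_trees = _trees(features) if features is not None else {}

    rows = []
    for rec in peaks.itertuples():
        if use_summit:
            point = int(rec.summit)
        else:
            point = (rec.start + rec.end) // 2
        name = getattr(rec, "name", None) or f"{rec.chrom}:{rec.start}"
        no_tss = rec.chrom not in tss_by_chrom
        gene_id, distance = None, None
        if not no_tss:
            positions, genes, strands = tss_by_chrom[rec.chrom]
            i = int(np.searchsorted(positions, point))
            candidates = [j for j in (i - 1, i) if 0 <= j < len(positions)]
            j = min(candidates, key=lambda j: abs(point - positions[j]))
            gene_id = genes[j]
            raw = point - positions[j]
            # negative = upstream of the TSS on the gene's strand
            distance = int(raw) if strands[j] == "+" else -int(raw)

        if no_tss:
            category = CATEGORY_INTERGENIC
        elif abs(distance) <= windows[0]:
            category = CATEGORY_PROXIMAL
        elif abs(distance) <= windows[1]:
            category = CATEGORY_DISTAL
        else:
            tree = feature_trees.get(rec.chrom)
            if tree is not None and tree.overlap(rec.start, rec.end):
                category = CATEGORY_GENE_BODY
            else:
                category = CATEGORY_INTERGENIC
        rows.append((rec.chrom, rec.start, rec.end, name, gene_id,
                     distance, category, no_tss))

    annotated = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "name", "nearest_gene", "tss_distance",
        "category", "no_tss"])
    if annotated.empty:
        return annotated, {}
    proportions = (annotated["category"].value_counts(normalize=True)
                   * 100.0).to_dict()
    return annotated, proportions


def enhancer_overlap(peaks: pd.DataFrame,
                     enhancers: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Flag peaks sharing >= 1 base with an enhancer; report the proportion.

    Half-open arithmetic: an enhancer abutting a peak does not overlap.
    Raises on an empty peak set (the proportion would be undefined).
    """
    if peaks.empty:
        raise ValueError("empty peak set: overlap proportion is undefined")
    _validate_bed(peaks, "peaks")
    _validate_bed(enhancers, "enhancers")
    trees = _trees(enhancers)
    flags = [
        bool(trees.get(rec.chrom) and
             trees[rec.chrom].overlap(rec.start, rec.end))
        for rec in peaks.itertuples()
    ]
    out = peaks.copy()
    out["enhancer_overlap"] = flags
    return out, 100.0 * sum(flags) / len(flags)


def compare_peak_sets(set_a: pd.DataFrame,
                      set_b: pd.DataFrame) -> dict:
    """Shared/exclusive peak counts between two peak sets.

    A peak in A is shared iff it overlaps (>= 1 bp) at least one peak in
    B, and vice versa; a peak overlapping several partners is counted
    once on its own side, so the two shared counts may differ and both
    are reported.
    """
    _validate_bed(set_a, "set A")
    _validate_bed(set_b, "set B")
    trees_b = _trees(set_b)
    trees_a = _trees(set_a)

    def shared_count(frame, trees):
        return sum(
            bool(trees.get(rec.chrom) and
                 trees[rec.chrom].overlap(rec.start, rec.end))
            for rec in frame.itertuples())

    shared_a = shared_count(set_a, trees_b)
    shared_b = shared_count(set_b, trees_a)
    return {
        "a_total": len(set_a),
        "b_total": len(set_b),
        "a_shared": shared_a,
        "b_shared": shared_b,
        "a_only": len(set_a) - shared_a,
        "b_only": len(set_b) - shared_b,
    }
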