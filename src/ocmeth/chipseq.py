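"""ChIP-seq peak overlap with CpG windows and predicted/observed set overlap.

Peaks are plain BED intervals (0-based, half-open).  A CpG is "bound" when
its 500-bp window — the same window construction used for motif scanning —
intersects at least one peak by one or more base pairs (bedtools-intersect
default semantics).  Fractions are reported per cohort (hypo/hyper/other)
and per stratum (promoter vs distal, where distal = gene body + 3'UTR +
intergenic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .coords import window_bounds
from .diffmeth import CATEGORY_PROMOTER

logger = logging.getLogger(__name__)

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A BED-style half-open interval; ``0 <= start < end``."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")


def read_bed(path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file, validate, and sort by (chrom, start).

    Raises ``ValueError`` for non-integer coordinates or ``start >= end``.
    Writing the result back with :func:`write_bed` and re-reading is
    bit-exact for the retained columns.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"BED line {lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name, score, strand))
            except ValueError as exc:
                raise ValueError(f"BED line {lineno}: {exc}") from exc
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def write_bed(intervals, path) -> None:
    """Write intervals as 6-column BED (integer scores stay integers)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


def _peak_trees(peaks) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in peaks:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def window_overlap(
    cpgs: pd.DataFrame, peaks, window: int = 500
) -> tuple[pd.DataFrame, pd.Series]:
    """Fraction of CpGs whose window intersects >= 1 peak, per cohort/stratum.

    ``cpgs`` needs columns ``chrom``, ``pos`` (1-based), ``cohort`` and
    ``category``.  The window is the 0-based half-open ``window``-bp
    interval centered on the CpG; overlap requires an intersection of
    positive length.  CpGs on chromosomes absent from the peak set count in
    the denominator (with a logged notice).  Returns the summary table
    (cohort, stratum, n, n_hit, fraction) and the per-CpG boolean hit
    series indexed like ``cpgs``.
    """
    trees = _peak_trees(peaks)
    unknown = set(cpgs["chrom"]) - set(trees)
    if unknown and len(trees):
        logger.info("window_overlap: no peaks on %s", sorted(unknown))
    hits = []
    for row in cpgs.itertuples(index=False):
        start, end = window_bounds(int(row.pos), window)
        tree = trees.get(row.chrom)
        hits.append(bool(tree.overlap(max(start, 0), end)) if tree else False)
    hit_series = pd.Series(hits, index=cpgs.index, name="peak_hit")
    stratum = pd.Series(
        ["promoter" if c == CATEGORY_PROMOTER else "distal" for c in cpgs["category"]],
        index=cpgs.index,
    )
    rows = []
    for cohort in sorted(cpgs["cohort"].unique()):
        for strat in ("promoter", "distal"):
            mask = (cpgs["cohort"] == cohort) & (stratum == strat)
            n = int(mask.sum())
            n_hit = int(hit_series[mask].sum())
            rows.append(
                {
                    "cohort": cohort,
                    "stratum": strat,
                    "n": n,
                    "n_hit": n_hit,
                    "fraction": n_hit / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows), hit_series


def set_overlap(set_a, set_b, denominator: str = "union") -> dict:
    """Venn counts and overlap percentage between two identifier sets.

    ``denominator`` is ``"union"`` (Jaccard, the default), ``"a"`` or
    ``"b"`` — the alternatives cover reporting the intersection relative to
    one prediction set.
    """
    a, b = set(set_a), set(set_b)
    inter = a & b
    union = a | b
    denom = {"union": len(union), "a": len(a), "b": len(b)}[denominator]
    return {
        "n_a_only": len(a - b),
        "n_b_only": len(b - a),
        "n_common": len(inter),
        "overlap_pct": 100.0 * len(inter) / denom if denom else 0.0,
    }
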