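"""Maxgap clustering of differentially methylated probes into regions.

Within each (chromosome, direction) stratum probes are sorted by position
and greedily chained: a new cluster starts whenever the gap to the previous
probe exceeds ``maxgap`` (500 bp by default).  Hypo- and hypermethylated
probes never merge.  Every input probe belongs to exactly one cluster;
singletons are reported.
"""

from __future__ import annotations

import pandas as pd


def cluster_dmps(dmps: pd.DataFrame, maxgap: int = 500) -> pd.DataFrame:
    """Group DMPs into DMRs by the maximum-gap rule.

    ``dmps`` needs columns ``probe``, ``chrom``, ``pos`` (1-based) and
    ``direction``.  A gap exactly equal to ``maxgap`` still joins (<= rule).
    Returns a table with columns (chrom, start, end, n_cpgs, direction,
    probes) where start/end are the first/last member positions (1-based
    inclusive) and ``probes`` is a semicolon-joined, position-ordered list.
    """
    if maxgap <= 0:
        raise ValueError("maxgap must be positive")
    required = {"probe", "chrom", "pos", "direction"}
    if not required.issubset(dmps.columns):
        raise ValueError(f"cluster_dmps needs columns {sorted(required)}")
    if dmps.duplicated(subset=["probe"]).any() or dmps.duplicated(
        subset=["chrom", "pos"]
    ).any():
        raise ValueError("duplicate (probe, position) entries")
    rows = []
    ordered = dmps.sort_values(["chrom", "direction", "pos"], kind="mergesort")
    for (chrom, direction), grp in ordered.groupby(["chrom", "direction"], sort=True):
        positions = grp["pos"].to_numpy()
        probes = grp["probe"].to_numpy()
        start_idx = 0
        for i in range(1, len(positions) + 1):
            if i == len(positions) or positions[i] - positions[i - 1] > maxgap:
                members = probes[start_idx:i]
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(positions[start_idx]),
                        "end": int(positions[i - 1]),
                        "n_cpgs": int(i - start_idx),
                        "direction": direction,
                        "probes": ";".join(map(str, members)),
                    }
                )
                start_idx = i
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_cpgs", "direction", "probes"]
    )
    return out.sort_values(
        ["chrom", "start", "direction"], kind="mergesort"
    ).reset_index(drop=True)


def filter_dmrs(dmrs: pd.DataFrame, min_cpgs: int) -> pd.DataFrame:
    """Keep clusters with at least ``min_cpgs`` member probes (order kept)."""
    if min_cpgs < 1:
        raise ValueError("min_cpgs must be >= 1")
    return dmrs[dmrs["n_cpgs"] >= min_cpgs].reset_index(drop=True)


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Convert 1-based inclusive DMR bounds to 0-based half-open BED rows."""
    return pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"] - 1,
            "end": dmrs["end"],
            "name": [
                f"DMR_{c}_{s}_{d}"
                for c, s, d in zip(dmrs["chrom"], dmrs["start"], dmrs["direction"])
            ],
            "score": dmrs["n_cpgs"],
            "strand": ".",
        }
    )
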