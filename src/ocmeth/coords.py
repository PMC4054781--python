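"""Coordinate conventions shared across modules.

Manifest probe positions are 1-based; BED intervals and CpG windows are
0-based half-open.  Centralizing the conversion keeps the motif-scanning
windows and the ChIP-seq overlap windows identical by construction.
"""

from __future__ import annotations


def window_bounds(pos_1based: int, window_len: int = 500) -> tuple[int, int]:
    """0-based half-open window of ``window_len`` bp centered on a CpG.

    A 1-based position ``p`` maps to 0-based coordinate ``p - 1``; the
    window is ``[p - 1 - window_len//2, p - 1 + window_len//2)``.  Negative
    starts are the caller's responsibility to truncate against the contig.
    """
    center = pos_1based - 1
    half = window_len // 2
    return center - half, center + half
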