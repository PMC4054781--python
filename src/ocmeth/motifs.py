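"""PWM motif scanning at exact score p-values and window enrichment.

Position frequency matrices (TRANSFAC flat format) are converted to log2
odds matrices against a background model.  Score thresholds for a target
p-value are computed exactly by dynamic programming over the discretized
score distribution (0.001-bit granularity, scores rounded down), windows
are scanned on both strands, and per-motif over-representation in a
foreground window cohort versus a background cohort is tested with a
two-tailed Fisher exact test (BH-corrected, significant at q <= 0.25).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .coords import window_bounds
from .diffmeth import bh_fdr

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}
GRANULARITY = 0.001  # bits; scores are floored onto this grid
_N_SCORE = -(2**40)  # any placement covering an N can never reach a threshold


# ---------------------------------------------------------------------------
# PFM / PWM
# ---------------------------------------------------------------------------

@dataclass
class Pfm:
    """A position frequency matrix: 4 x L non-negative counts (A,C,G,T rows)."""

    motif_id: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError("PFM must be a 4 x L matrix with L >= 1")
        if np.any(self.counts < 0):
            raise ValueError("PFM counts must be non-negative")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError("every PFM column must have a positive total")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass
class Pwm:
    """Log2-odds scoring matrix derived from a PFM.

    ``matrix[b, j] = log2(((count + pc) / (total + 4 pc)) / background[b])``.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray
    pseudocount: float

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def int_matrix(self, granularity: float = GRANULARITY) -> np.ndarray:
        """Scores floored onto the granularity grid, as integers."""
        return np.floor(self.matrix / granularity).astype(np.int64)

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())


def pfm_to_pwm(pfm: Pfm, background=None, pseudocount: float = 0.25) -> Pwm:
    """Convert counts to log2 odds against the background (uniform default)."""
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or np.any(background <= 0):
        raise ValueError("background must be 4 positive frequencies")
    if not math.isclose(background.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("background frequencies must sum to 1")
    totals = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudocount) / (totals + 4.0 * pseudocount)
    matrix = np.log2(probs / background[:, None])
    return Pwm(pfm.motif_id, matrix, background, pseudocount)


def estimate_background(sequences) -> np.ndarray:
    """0-order base frequencies from supplied sequences (N ignored)."""
    counts = np.zeros(4)
    for seq in sequences:
        for b, i in BASE_INDEX.items():
            counts[i] += seq.upper().count(b)
    if counts.sum() == 0:
        raise ValueError("no A/C/G/T bases in supplied sequences")
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# TRANSFAC flat-file I/O
# ---------------------------------------------------------------------------

def read_transfac(text: str) -> list[Pfm]:
    """Parse TRANSFAC flat-format matrices.

    Records carry ``ID``/``NA`` header lines, numbered count rows
    (``01  a c g t  consensus``, the trailing consensus letter optional),
    and end with ``//``.  An optional ``P0`` column-header line is skipped.
    Raises ``ValueError`` naming the offending line for malformed rows and
    for a record without terminator.
    """
    pfms: list[Pfm] = []
    motif_id = None
    rows: list[list[float]] | None = None
    open_record = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tag = line.split(None, 1)[0]
        if tag == "//":
            if open_record:
                if rows:
                    pfms.append(Pfm(motif_id or f"motif_{len(pfms) + 1}",
                                    np.array(rows, dtype=float).T))
                motif_id, rows, open_record = None, None, False
            continue
        open_record = True
        if tag in {"ID", "AC"}:
            motif_id = motif_id or line.split(None, 1)[1].strip()
            continue
        if tag in {"NA", "DE", "BF", "XX", "P0", "PO", "CC", "BA"}:
            if tag == "NA" and motif_id is None and len(line.split(None, 1)) > 1:
                motif_id = line.split(None, 1)[1].strip()
            continue
        if tag.isdigit():
            fields = line.split()
            values = fields[1:5]
            if len(values) < 4:
                raise ValueError(
                    f"TRANSFAC line {lineno}: expected 4 counts, got {len(values)}: {raw!r}"
                )
            try:
                counts = [float(v) for v in values]
            except ValueError as exc:
                raise ValueError(f"TRANSFAC line {lineno}: non-numeric count in {raw!r}") from exc
            if any(c < 0 for c in counts):
                raise ValueError(f"TRANSFAC line {lineno}: negative count in {raw!r}")
            if rows is None:
                rows = []
            rows.append(counts)
            continue
        # unknown two-letter tags are tolerated (TRANSFAC carries many)
    if open_record:
        raise ValueError("TRANSFAC record missing '//' terminator")
    return pfms


def write_transfac(pfms: list[Pfm]) -> str:
    """Serialize PFMs in the flat format accepted by :func:`read_transfac`."""
    chunks = []
    for pfm in pfms:
        lines = [f"ID {pfm.motif_id}", f"NA {pfm.motif_id}", "P0 A C G T"]
        for j in range(pfm.length):
            a, c, g, t = (float(v) for v in pfm.counts[:, j])
            lines.append(
                f"{j + 1:02d} {a!r} {c!r} {g!r} {t!r} {pfm.consensus[j]}"
            )
        lines.append("//")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + ("\n" if chunks else "")


# ---------------------------------------------------------------------------
# exact score p-values
# ---------------------------------------------------------------------------

@dataclass
class ScoreThreshold:
    """Smallest discretized score whose background p-value is <= the cutoff.

    ``attained`` is False when even the maximum achievable score has
    p > cutoff; the threshold is then the maximum score itself.
    """

    motif_id: str
    threshold_int: int
    granularity: float
    p_value: float
    attained: bool

    @property
    def threshold(self) -> float:
        return self.threshold_int * self.granularity


def score_distribution(int_matrix: np.ndarray, background: np.ndarray):
    """Exact distribution of the total discretized score of a random L-mer.

    Bases are drawn i.i.d. from ``background``.  Returns ``(probs, lo)``
    where ``probs[i]`` is the probability of integer score ``lo + i``.
    """
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(int_matrix.shape[1]):
        col = int_matrix[:, j]
        clo, chi = int(col.min()), int(col.max())
        new = np.zeros(len(cur) + (chi - clo))
        for b in range(4):
            off = int(col[b]) - clo
            new[off : off + len(cur)] += background[b] * cur
        cur = new
        cur_lo += clo
    return cur, cur_lo


def score_threshold(
    pwm: Pwm, p_cutoff: float, granularity: float = GRANULARITY
) -> ScoreThreshold:
    """Exact-DP threshold for ``P(score >= t) <= p_cutoff``."""
    if not 0.0 < p_cutoff <= 1.0:
        raise ValueError("p_cutoff must lie in (0, 1]")
    im = pwm.int_matrix(granularity)
    probs, lo = score_distribution(im, pwm.background)
    # survival function; clip float accumulation noise at the mathematical cap
    sf = np.minimum(np.cumsum(probs[::-1])[::-1], 1.0)
    achievable = probs > 0
    candidates = np.nonzero((sf <= p_cutoff) & achievable)[0]
    if candidates.size == 0:
        top = int(np.nonzero(achievable)[0][-1])
        return ScoreThreshold(pwm.motif_id, lo + top, granularity, float(sf[top]), False)
    i = int(candidates[0])
    return ScoreThreshold(pwm.motif_id, lo + i, granularity, float(sf[i]), True)


# ---------------------------------------------------------------------------
# window scanning
# ---------------------------------------------------------------------------

def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N, ...) -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _placement_scores(codes: np.ndarray, score_rows: np.ndarray) -> np.ndarray:
    L = score_rows.shape[1]
    if codes.size < L:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return score_rows[windows, np.arange(L)].sum(axis=1)


def scan_sequence(seq: str, pwm: Pwm, threshold: ScoreThreshold | float) -> list[tuple]:
    """All placements scoring at or above the threshold, both strands.

    Returns a list of ``(offset, strand, score_bits)`` tuples; offsets are
    0-based on the forward strand (for minus-strand matches, the offset of
    the leftmost covered base).  Positions containing N never match.  A
    sequence shorter than the motif yields no matches (a miss, not an
    error).
    """
    granularity = getattr(threshold, "granularity", GRANULARITY)
    tint = (
        threshold.threshold_int
        if isinstance(threshold, ScoreThreshold)
        else int(round(float(threshold) / granularity))
    )
    im = pwm.int_matrix(granularity)
    score_rows = np.vstack([im, np.full((1, pwm.length), _N_SCORE, dtype=np.int64)])
    codes = encode_sequence(seq)
    L = pwm.length
    hits = []
    fwd = _placement_scores(codes, score_rows)
    for off in np.nonzero(fwd >= tint)[0]:
        hits.append((int(off), "+", float(fwd[off] * granularity)))
    rc_codes = np.array([COMPLEMENT.get(int(c), 4) for c in codes[::-1]], dtype=np.int8)
    rev = _placement_scores(rc_codes, score_rows)
    n = codes.size
    for off in np.nonzero(rev >= tint)[0]:
        hits.append((int(n - L - off), "-", float(rev[off] * granularity)))
    return sorted(hits)


def scan_windows(
    windows, pwm: Pwm, threshold: ScoreThreshold | float
) -> pd.DataFrame:
    """Scan a mapping/list of windows; one row per window with hit status.

    ``windows`` is either a mapping ``id -> sequence`` or an iterable of
    objects with ``probe`` and ``sequence`` attributes.  Returns a table
    (window, hit, n_matches, best_score, offsets, strands).
    """
    if isinstance(windows, dict):
        items = windows.items()
    else:
        items = [(w.probe, w.sequence) for w in windows]
    rows = []
    for wid, seq in items:
        matches = scan_sequence(seq, pwm, threshold)
        rows.append(
            {
                "window": wid,
                "motif": pwm.motif_id,
                "hit": bool(matches),
                "n_matches": len(matches),
                "best_score": max((m[2] for m in matches), default=np.nan),
                "offsets": ";".join(str(m[0]) for m in matches),
                "strands": ";".join(m[1] for m in matches),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CpG windows
# ---------------------------------------------------------------------------

@dataclass
class CpgWindow:
    """A window of up to ``window_len`` bp centered on a CpG probe."""

    probe: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    sequence: str
    cohort: str  # hypo | hyper | other
    truncated: bool = field(default=False)


def build_windows(
    manifest: pd.DataFrame,
    dmps: pd.DataFrame,
    sequences,
    window_len: int = 500,
) -> list[CpgWindow]:
    """Construct CpG window cohorts for every probe in the manifest.

    ``sequences`` is either a mapping ``probe -> window sequence`` (already
    extracted) or a mapping ``chrom -> contig sequence`` to slice from.
    Cohorts: probes called hypo, probes called hyper, and all remaining
    probes as ``other`` (the enrichment background); the three cohorts
    partition the manifest.  Windows running off a contig end are truncated
    and flagged.
    """
    direction = dict(zip(dmps["probe"], dmps["direction"])) if len(dmps) else {}
    per_probe = manifest["probe"].iloc[0] in sequences if len(manifest) else True
    out = []
    for row in manifest.itertuples(index=False):
        start, end = window_bounds(int(row.pos), window_len)
        cohort = direction.get(row.probe, "other")
        truncated = False
        if per_probe:
            if row.probe not in sequences:
                raise KeyError(f"no sequence for probe {row.probe}")
            seq = sequences[row.probe]
            if len(seq) < end - start:
                truncated = True
        else:
            if row.chrom not in sequences:
                raise KeyError(f"no sequence for contig {row.chrom}")
            contig = sequences[row.chrom]
            s = max(0, start)
            e = min(len(contig), end)
            truncated = (s != start) or (e != end)
            seq = contig[s:e]
            start, end = s, e
        out.append(CpgWindow(row.probe, row.chrom, start, end, seq, cohort, truncated))
    return out


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Margins fixed; the p-value sums hypergeometric probabilities that are
    less than or equal to that of the observed table.  The comparison uses
    exact integer weights (no floating-point tie tolerance).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    weights = [math.comb(r1, x) * math.comb(n - r1, c1 - x) for x in range(lo, hi + 1)]
    obs = weights[a - lo]
    num = sum(w for w in weights if w <= obs)
    return float(Fraction(num, math.comb(n, c1)))


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio with Haldane-Anscombe 0.5 correction on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def enrich(fore_hits, back_hits, motif_id: str = "") -> dict:
    """2x2 enrichment of hit windows in foreground vs background cohorts."""
    fore_hits = np.asarray(fore_hits, dtype=bool)
    back_hits = np.asarray(back_hits, dtype=bool)
    if fore_hits.size < 1 or back_hits.size < 1:
        raise ValueError("both cohorts must be non-empty")
    a = int(fore_hits.sum())
    b = int(fore_hits.size - a)
    c = int(back_hits.sum())
    d = int(back_hits.size - c)
    return {
        "motif": motif_id,
        "fg_hit": a,
        "fg_miss": b,
        "bg_hit": c,
        "bg_miss": d,
        "odds_ratio": odds_ratio(a, b, c, d),
        "p": fisher_two_tailed(a, b, c, d),
    }


def enrichment_table(per_motif_hits: dict, fdr_max: float = 0.25) -> pd.DataFrame:
    """BH-corrected enrichment across motifs.

    ``per_motif_hits`` maps motif id to ``(foreground_hits, background_hits)``
    boolean arrays.  Significance is declared at ``q <= fdr_max`` (0.25 by
    default).
    """
    rows = [enrich(f, b, m) for m, (f, b) in per_motif_hits.items()]
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
        table["significant"] = table["q"] <= fdr_max
        table = table.sort_values(["q", "p"], kind="mergesort").reset_index(drop=True)
    return table
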