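"""Expression summarization, differential calls, and methylation integration.

Expression enters as background-corrected log2 intensities on a 0/5/20-day
osteoclastogenesis time course.  Probe-level values are summarized per gene
with Tukey median polish, quantile normalized, IQR-filtered, and tested
with the unpaired moderated t shared with the methylation stage.  Called
genes are intersected with the hypo-/hypermethylated gene sets and the
methylation-expression relationship is summarized as per-region OLS slopes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diffmeth import iqr_filter, quantile_normalize, two_group_moderated_t

logger = logging.getLogger(__name__)

JOINT_CLASSES = (
    "hypo_up",
    "hypo_down",
    "hyper_up",
    "hyper_down",
    "methylation_only",
    "expression_only",
)


def median_polish(matrix, tol: float = 1e-6, max_iter: int = 10):
    """Tukey median polish of a 2-D array.

    Alternating row/column median sweeps until the total absolute change of
    one full sweep falls below ``tol`` or ``max_iter`` sweeps have run.
    Returns ``(overall, row_effects, col_effects, residuals)``.
    """
    resid = np.array(matrix, dtype=float)
    if resid.ndim != 2 or resid.size == 0:
        raise ValueError("median_polish expects a non-empty 2-D matrix")
    nr, nc = resid.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    for _ in range(max_iter):
        delta = 0.0
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row += rmed
        delta += np.abs(rmed).sum()
        cmed_of_row = np.median(row)
        row -= cmed_of_row
        overall += cmed_of_row
        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col += cmed
        delta += np.abs(cmed).sum()
        rmed_of_col = np.median(col)
        col -= rmed_of_col
        overall += rmed_of_col
        if delta < tol:
            break
    return overall, row, col, resid


def median_polish_summarize(probe_matrix) -> np.ndarray:
    """Per-sample gene value: overall effect plus column (sample) effect."""
    overall, _, col, _ = median_polish(probe_matrix)
    return overall + col


def summarize_genes(
    probe_values: pd.DataFrame, probe_to_gene: pd.Series
) -> pd.DataFrame:
    """Median-polish probe-level log2 values into a gene x sample matrix."""
    genes, rows = [], []
    for gene, idx in probe_values.groupby(probe_to_gene).groups.items():
        rows.append(median_polish_summarize(probe_values.loc[idx].to_numpy()))
        genes.append(gene)
    return pd.DataFrame(rows, index=genes, columns=probe_values.columns)


def timepoint_samples(expr: pd.DataFrame, day: int) -> list[str]:
    """Columns named ``d<day>_<rep>`` for the requested timepoint."""
    prefix = f"d{day}_"
    cols = [c for c in expr.columns if c.startswith(prefix)]
    if not cols:
        raise ValueError(f"no samples for day {day}")
    return cols


def call_de(
    expr: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    iqr_threshold: float = 0.50,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    p_max: float = 0.01,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Call differential expression of group B relative to group A.

    Quantile normalization and IQR filtering precede the two-group
    moderated t.  Fold-change comparisons are strict (``FC > fc_up`` /
    ``< fc_down``); both raw p and BH q thresholds must be met.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    norm = quantile_normalize(expr[list(group_a) + list(group_b)])
    kept = iqr_filter(norm, iqr_threshold)
    sub = norm.loc[kept]
    mod = two_group_moderated_t(sub, group_a, group_b)
    log2fc = mod.mean_diff
    called = (
        (mod.p < p_max)
        & (mod.q < fdr_max)
        & ((log2fc > np.log2(fc_up)) | (log2fc < np.log2(fc_down)))
    )
    out = pd.DataFrame(
        {
            "gene": sub.index[called],
            "log2FC": log2fc[called],
            "FC": 2.0 ** log2fc[called],
            "p": mod.p[called],
            "q": mod.q[called],
            "direction": np.where(log2fc[called] > 0, "up", "down"),
        }
    )
    return out.sort_values("gene", kind="mergesort").reset_index(drop=True)


def integrate(meth_gene_sets: dict, de_records: pd.DataFrame) -> dict:
    """Joint classification of methylation- and expression-called genes.

    Gene identifiers are matched exactly after case-folding.  Genes in both
    the hypo and hyper methylation sets contribute to every relevant joint
    class; class counts sum to the size of the union of called genes.
    Returns a dict with per-class gene sets and counts.
    """
    hypo = {str(g).casefold() for g in meth_gene_sets.get("hypo", set())}
    hyper = {str(g).casefold() for g in meth_gene_sets.get("hyper", set())}
    up = {str(g).casefold() for g in de_records.loc[de_records["direction"] == "up", "gene"]}
    down = {
        str(g).casefold() for g in de_records.loc[de_records["direction"] == "down", "gene"]
    }
    meth = hypo | hyper
    expr = up | down
    classes = {
        "hypo_up": hypo & up,
        "hypo_down": hypo & down,
        "hyper_up": hyper & up,
        "hyper_down": hyper & down,
        "methylation_only": meth - expr,
        "expression_only": expr - meth,
    }
    counts = {k: len(v) for k, v in classes.items()}
    return {"classes": classes, "counts": counts, "n_union": len(meth | expr)}


def region_slopes(points: pd.DataFrame, min_points: int = 3) -> pd.DataFrame:
    """OLS slope of expression change on methylation change, per category.

    ``points`` needs columns ``category``, ``delta_beta`` and ``log2fc``
    (one row per differentially methylated CpG with a matched expression
    change).  Categories with fewer than ``min_points`` points are skipped
    with a logged notice; zero variance in delta-beta is an error.
    """
    rows = []
    for category, grp in points.groupby("category", sort=True):
        if len(grp) < min_points:
            logger.info(
                "region_slopes: skipping %s (%d < %d points)",
                category, len(grp), min_points,
            )
            continue
        x = grp["delta_beta"].to_numpy(dtype=float)
        y = grp["log2fc"].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"zero variance in delta-beta for category {category}")
        res = sps.linregress(x, y)
        rows.append(
            {
                "category": category,
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r": float(res.rvalue),
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows, columns=["category", "slope", "intercept", "r", "n"])
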