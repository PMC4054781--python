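"""Deterministic quantitation of qPCR readouts.

Three assay families are covered: relative expression (delta-Cq against a
reference gene), the glucosyltransferase-protection 5hmC assay (glucosylated
5hmC resists MspI cleavage at CCGG; the protected fraction is read out by
qPCR against input, with the untreated/no-GT sample defining 0%), and
ChIP-qPCR percent-input with optional IgG background subtraction.
Replicates are always aggregated on the linear quantity scale, never on the
Cq scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def _check_efficiency(efficiency: float) -> None:
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("amplification efficiency must be in (1, 2]")


def relative_quantity(cq_target, cq_reference, efficiency: float = 2.0) -> float:
    """``efficiency ** (cq_reference - cq_target)``, replicates averaged.

    Scalars or replicate arrays are accepted; arrays are converted to
    quantities per replicate and averaged on the quantity scale.
    """
    _check_efficiency(efficiency)
    ct = np.atleast_1d(np.asarray(cq_target, dtype=float))
    cr = np.atleast_1d(np.asarray(cq_reference, dtype=float))
    if np.any(ct <= 0) or np.any(cr <= 0):
        raise ValueError("Cq values must be positive")
    q = efficiency ** (np.mean(cr) - ct)
    return float(np.mean(q))


def hydroxymethyl_percent(q_gt_over_input, q_nogt_over_input) -> float:
    """Percent 5hmC: ``100 * (GT/input - noGT/input)``, clamped to [0, 100].

    Both arguments are relative quantities of the MspI-digested sample
    versus undigested input; the no-GT arm defines the 0% baseline.  A
    negative difference (expected under noise near 0%) clamps to 0 with a
    warning.
    """
    qg = float(np.mean(q_gt_over_input))
    qn = float(np.mean(q_nogt_over_input))
    if qg < 0 or qn < 0:
        raise ValueError("input-normalized quantities must be non-negative")
    pct = 100.0 * (qg - qn)
    if pct < 0:
        warnings.warn("negative 5hmC difference clamped to 0", stacklevel=2)
    return float(np.clip(pct, 0.0, 100.0))


def chip_percent_input(
    cq_bound,
    cq_input,
    input_fraction: float,
    efficiency: float = 2.0,
    cq_igg=None,
) -> float:
    """ChIP signal as percent of input chromatin.

    ``percent = 100 * input_fraction * efficiency ** (cq_input - cq_bound)``.
    When ``cq_igg`` is supplied, the IgG percent-input (same input and
    fraction) is subtracted with a floor at 0.
    """
    _check_efficiency(efficiency)
    if not 0.0 < input_fraction <= 1.0:
        raise ValueError("input_fraction must be in (0, 1]")
    cb = np.atleast_1d(np.asarray(cq_bound, dtype=float))
    ci = np.atleast_1d(np.asarray(cq_input, dtype=float))
    if np.any(cb <= 0) or np.any(ci <= 0):
        raise ValueError("Cq values must be positive")
    pct = 100.0 * input_fraction * float(np.mean(efficiency ** (np.mean(ci) - cb)))
    if cq_igg is not None:
        cg = np.atleast_1d(np.asarray(cq_igg, dtype=float))
        igg_pct = 100.0 * input_fraction * float(np.mean(efficiency ** (np.mean(ci) - cg)))
        pct = max(0.0, pct - igg_pct)
    return pct


def significance_stars(p: float) -> str:
    """Figure-legend star coding: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def timecourse_summary(
    measurements: pd.DataFrame,
    value_col: str = "value",
    time_col: str = "timepoint",
    compare: tuple | None = None,
) -> dict:
    """Mean +- SD per timepoint plus a Welch t-test between two timepoints.

    ``compare`` is a pair of timepoint labels (defaults to the two smallest
    timepoints present).  Each compared group needs >= 2 replicates.
    Returns per-timepoint summaries and the Welch ``t``, ``p`` and star
    code.  Results are invariant to replicate ordering.
    """
    grouped = measurements.groupby(time_col)[value_col]
    summary = grouped.agg(["mean", "std", "count"]).reset_index()
    times = sorted(measurements[time_col].unique())
    if compare is None:
        if len(times) < 2:
            raise ValueError("need at least two timepoints to compare")
        compare = (times[0], times[1])
    g0 = measurements.loc[measurements[time_col] == compare[0], value_col].to_numpy()
    g1 = measurements.loc[measurements[time_col] == compare[1], value_col].to_numpy()
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each compared timepoint needs >= 2 replicates")
    res = stats.ttest_ind(g0, g1, equal_var=False)
    return {
        "summary": summary,
        "compare": compare,
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "stars": significance_stars(float(res.pvalue)),
    }


# ---------------------------------------------------------------------------
# long-format Cq tables
# ---------------------------------------------------------------------------

def quantify_hmc(table: pd.DataFrame) -> pd.DataFrame:
    """5hmC percentages from a long-format Cq table.

    Expects rows with ``assay == "hmc"`` and, per (target, timepoint,
    replicate), treatments ``GT``, ``noGT`` and ``input``.  Quantities are
    computed per replicate, averaged on the quantity scale, and converted
    with :func:`hydroxymethyl_percent`.
    """
    sub = table[table["assay"] == "hmc"]
    rows = []
    for (target, tp), grp in sub.groupby(["target", "timepoint"], sort=True):
        eff = float(grp["efficiency"].iloc[0])
        piv = grp.pivot_table(index="replicate", columns="treatment", values="cq")
        q_gt = eff ** (piv["input"] - piv["GT"])
        q_nogt = eff ** (piv["input"] - piv["noGT"])
        per_rep = 100.0 * (q_gt - q_nogt)
        rows.append(
            {
                "target": target,
                "timepoint": tp,
                "pct_5hmC": hydroxymethyl_percent(q_gt.to_numpy(), q_nogt.to_numpy()),
                "replicate_sd": float(per_rep.std(ddof=1)) if len(per_rep) > 1 else 0.0,
                "n_replicates": int(len(per_rep)),
            }
        )
    return pd.DataFrame(rows)


def quantify_expression(table: pd.DataFrame, reference: str = "REF") -> pd.DataFrame:
    """Relative expression against a reference target, per target/timepoint."""
    sub = table[table["assay"] == "expression"]
    rows = []
    for (target, tp), grp in sub.groupby(["target", "timepoint"], sort=True):
        if target == reference:
            continue
        eff = float(grp["efficiency"].iloc[0])
        ref = table[
            (table["assay"] == "expression")
            & (table["target"] == reference)
            & (table["timepoint"] == tp)
        ]
        if ref.empty:
            raise ValueError(f"no reference Cq rows for timepoint {tp}")
        rq = relative_quantity(grp["cq"].to_numpy(), ref["cq"].to_numpy(), eff)
        rows.append({"target": target, "timepoint": tp, "relative_quantity": rq})
    return pd.DataFrame(rows)


def quantify_chip(table: pd.DataFrame, input_fraction: float = 0.1) -> pd.DataFrame:
    """Percent-input per (antibody target, timepoint), IgG subtracted if present."""
    sub = table[table["assay"] == "chip"]
    rows = []
    for (target, tp), grp in sub.groupby(["target", "timepoint"], sort=True):
        eff = float(grp["efficiency"].iloc[0])
        piv = grp.pivot_table(index="replicate", columns="treatment", values="cq")
        igg = piv["IgG"].to_numpy() if "IgG" in piv.columns else None
        pct = chip_percent_input(
            piv["bound"].to_numpy(), piv["input"].to_numpy(), input_fraction, eff, igg
        )
        rows.append({"target": target, "timepoint": tp, "percent_input": pct})
    return pd.DataFrame(rows)
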