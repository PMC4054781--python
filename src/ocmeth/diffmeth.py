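"""Paired differential-methylation calling on bead-array beta values.

The workflow mirrors the standard limma-style analysis of 450K-type data:
beta values are mapped to M-values (``log2(beta/(1-beta))``), quantile
normalized, variance-filtered by inter-quartile range, and tested with an
empirical-Bayes moderated paired t-statistic.  Probes passing fold-change
(on the beta scale), raw-p, and Benjamini-Hochberg FDR thresholds are
reported as differentially methylated probes (DMPs), annotated to genomic
region categories, and summarized at the gene level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

#: beta values are clamped to [BETA_EPS, 1 - BETA_EPS] before the logit,
#: bounding |M| at about 10 and avoiding infinities at 0/1.
BETA_EPS = 1e-3

PROMOTER_TAGS = frozenset({"TSS1500", "TSS200", "5'UTR", "1stExon"})
BODY_TAGS = frozenset({"Body"})
UTR3_TAGS = frozenset({"3'UTR"})

CATEGORY_PROMOTER = "promoter"
CATEGORY_BODY = "gene_body"
CATEGORY_UTR3 = "3utr"
CATEGORY_INTERGENIC = "intergenic"


# ---------------------------------------------------------------------------
# scale transforms
# ---------------------------------------------------------------------------

def beta_to_m(beta):
    """Map methylation proportions to M-values, ``log2(b/(1-b))``.

    Values are clamped to ``[BETA_EPS, 1 - BETA_EPS]`` first so the logit is
    finite everywhere.  Accepts scalars, arrays, or DataFrames; raises
    ``ValueError`` for values outside [0, 1].
    """
    arr = np.asarray(beta, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or np.any(np.isnan(arr)):
        raise ValueError("beta values must lie in [0, 1]")
    clamped = np.clip(arr, BETA_EPS, 1.0 - BETA_EPS)
    m = np.log2(clamped / (1.0 - clamped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (exact on the open clamped interval)."""
    arr = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + 2.0 ** (-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(b, index=m.index)
    if np.isscalar(m):
        return float(b)
    return b


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to a common reference distribution.

    The reference is the row-wise mean of the per-column sorted values.
    After normalization every column's sorted values equal the reference.
    Ties within a column receive the mean of the reference values at their
    tied ranks.  Missing values are rejected.
    """
    values = np.asarray(matrix, dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile_normalize: missing values are not supported")
    if values.ndim != 2:
        raise ValueError("quantile_normalize expects a 2-D matrix")
    n, k = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(k):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # group runs of equal values; each run gets the mean reference value
        new_group = np.r_[True, sorted_col[1:] != sorted_col[:-1]]
        group_id = np.cumsum(new_group) - 1
        sums = np.bincount(group_id, weights=reference)
        counts = np.bincount(group_id)
        out[order, j] = (sums / counts)[group_id]
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def iqr_filter(matrix: pd.DataFrame, threshold: float = 0.50) -> pd.Index:
    """Keep probes whose IQR is at least the ``threshold`` quantile of IQRs.

    IQRs and the quantile cutoff both use linear interpolation; the
    comparison is inclusive, so ties at the cutoff are kept and
    ``threshold=0`` keeps everything.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("iqr_filter threshold must be in [0, 1]")
    values = np.asarray(matrix, dtype=float)
    if values.shape[0] < 1:
        raise ValueError("iqr_filter requires at least one probe")
    q75, q25 = np.percentile(values, [75, 25], axis=1)
    iqrs = q75 - q25
    cutoff = np.quantile(iqrs, threshold)
    keep = iqrs >= cutoff
    if isinstance(matrix, pd.DataFrame):
        return matrix.index[keep]
    return np.nonzero(keep)[0]


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------

def trigamma_inverse(x: float) -> float:
    """Solve ``trigamma(y) = x`` for ``y > 0`` by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma_inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-10:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed sample variances.

    Returns ``(prior_df, prior_var)``; ``prior_df`` is ``inf`` when the
    spread of ``log(s2)`` is no larger than expected from chi-square
    sampling alone.  Zero variances are excluded from the fit.  Raises if
    every variance is zero (the hyperparameter fit is undefined).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all residual variances are zero; eBayes prior undefined")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    if e.size > 1:
        evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    else:
        evar = -1.0
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * trigamma_inverse(evar)
    s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


@dataclass
class ModeratedStats:
    """Per-probe moderated-t results for a single contrast.

    ``mean_diff`` is on the M scale (OC minus MO for the paired design).
    ``post_var`` follows the shrinkage identity
    ``(d0*s0^2 + d*s^2) / (d0 + d)`` and the t reference has ``d + d0``
    degrees of freedom (normal when ``d0`` is infinite).
    """

    probe_ids: pd.Index
    mean_diff: np.ndarray
    s2: np.ndarray
    df_residual: float
    prior_df: float
    prior_var: float
    post_var: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray = field(default=None)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_diff": self.mean_diff,
                "s2": self.s2,
                "post_var": self.post_var,
                "t": self.t,
                "p": self.p,
                "q": self.q,
            },
            index=self.probe_ids,
        )


def _moderate(mean, s2, df, stdev_unscaled, prior_df=None):
    mean = np.asarray(mean, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if prior_df is not None and prior_df == 0:
        d0, s0 = 0.0, np.nan
        post = s2.copy()
    else:
        d0, s0 = fit_f_dist(s2, df)
        if np.isinf(d0):
            post = np.full_like(s2, s0)
        else:
            post = (d0 * s0 + df * s2) / (d0 + df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (np.sqrt(post) * stdev_unscaled)
    df_total = df + d0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return d0, s0, post, t, p


def validate_design(design: pd.DataFrame, samples) -> pd.DataFrame:
    """Check a (sample, donor, condition) design against matrix columns."""
    required = {"sample", "donor", "condition"}
    if not required.issubset(design.columns):
        raise ValueError(f"design needs columns {sorted(required)}")
    if set(design["sample"]) != set(samples):
        raise ValueError("design samples do not match matrix columns")
    bad = set(design["condition"]) - {"MO", "OC"}
    if bad:
        raise ValueError(f"unknown conditions in design: {sorted(bad)}")
    counts = design.groupby(["donor", "condition"]).size()
    if (counts != 1).any():
        raise ValueError("each donor must appear exactly once per condition")
    return design


def paired_moderated_t(
    m_matrix: pd.DataFrame, design: pd.DataFrame, prior_df: float | None = None
) -> ModeratedStats:
    """Moderated paired t-test of OC versus MO M-values.

    Per probe the paired differences ``d_i = M(OC_i) - M(MO_i)`` across
    donors give a mean and a sample variance with ``n_pairs - 1`` residual
    df; the variance prior is moment-matched on ``log s^2``.  Passing
    ``prior_df=0`` disables shrinkage, recovering the classical paired t.
    """
    design = validate_design(design, m_matrix.columns)
    donors = sorted(design["donor"].unique())
    if len(donors) < 2:
        raise ValueError("paired test requires at least 2 complete donor pairs")
    by = design.set_index(["donor", "condition"])["sample"]
    diffs = np.column_stack(
        [
            m_matrix[by[(d, "OC")]].to_numpy(dtype=float)
            - m_matrix[by[(d, "MO")]].to_numpy(dtype=float)
            for d in donors
        ]
    )
    n = len(donors)
    mean = diffs.mean(axis=1)
    s2 = diffs.var(axis=1, ddof=1)
    df = n - 1
    d0, s0, post, t, p = _moderate(mean, s2, df, 1.0 / np.sqrt(n), prior_df)
    q = bh_fdr(p)
    return ModeratedStats(m_matrix.index, mean, s2, df, d0, s0, post, t, p, q)


def two_group_moderated_t(
    m_matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    prior_df: float | None = None,
) -> ModeratedStats:
    """Unpaired moderated t of group B minus group A (pooled variance)."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = m_matrix[list(group_a)].to_numpy(dtype=float)
    b = m_matrix[list(group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    mean = b.mean(axis=1) - a.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    df = na + nb - 2
    s2 = ss / df
    c = np.sqrt(1.0 / na + 1.0 / nb)
    d0, s0, post, t, p = _moderate(mean, s2, df, c, prior_df)
    q = bh_fdr(p)
    return ModeratedStats(m_matrix.index, mean, s2, df, d0, s0, post, t, p, q)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DMP calling and annotation
# ---------------------------------------------------------------------------

def group_mean_betas(beta: pd.DataFrame, design: pd.DataFrame):
    """Per-probe mean beta for the MO and OC arms."""
    design = validate_design(design, beta.columns)
    mo = design.loc[design["condition"] == "MO", "sample"]
    oc = design.loc[design["condition"] == "OC", "sample"]
    return beta[list(mo)].mean(axis=1), beta[list(oc)].mean(axis=1)


def call_dmps(
    beta: pd.DataFrame,
    design: pd.DataFrame,
    mod_stats: ModeratedStats,
    fc_hyper: float = 2.0,
    fc_hypo: float = 0.5,
    p_max: float = 0.01,
    fdr_max: float = 0.05,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Call differentially methylated probes.

    Fold change is the ratio of group-mean beta values (OC over MO);
    comparisons are inclusive (``FC >= fc_hyper`` / ``<= fc_hypo``) by
    default, and both the raw p and the BH q threshold must be met.
    Returns a probe-id-sorted table so the result is invariant to input
    ordering.
    """
    if not beta.index.equals(mod_stats.probe_ids):
        raise ValueError("beta matrix and statistics cover different probes")
    mean_mo, mean_oc = group_mean_betas(beta, design)
    assert (mean_mo > 0).all(), "mean MO beta must be positive after clamping"
    fc = mean_oc / mean_mo
    stats_df = mod_stats.as_frame()
    if inclusive:
        hyper = fc >= fc_hyper
        hypo = fc <= fc_hypo
    else:
        hyper = fc > fc_hyper
        hypo = fc < fc_hypo
    sig = (stats_df["p"] <= p_max) & (stats_df["q"] <= fdr_max)
    called = sig & (hyper | hypo)
    out = pd.DataFrame(
        {
            "probe": beta.index[called],
            "beta_MO": mean_mo[called].to_numpy(),
            "beta_OC": mean_oc[called].to_numpy(),
            "FC": fc[called].to_numpy(),
            "delta_beta": (mean_oc - mean_mo)[called].to_numpy(),
            "p": stats_df.loc[called, "p"].to_numpy(),
            "q": stats_df.loc[called, "q"].to_numpy(),
            "direction": np.where(hyper[called], "hyper", "hypo"),
        }
    )
    return out.sort_values("probe", kind="mergesort").reset_index(drop=True)


def probe_category(gene_field: str, region_field: str) -> str:
    """Derive one region category per probe with promoter precedence.

    ``gene_field``/``region_field`` are semicolon-joined parallel lists in
    the style of the 450K manifest; an empty gene list means intergenic.
    """
    genes = [g for g in str(gene_field).split(";") if g] if gene_field else []
    if not genes:
        return CATEGORY_INTERGENIC
    tags = [t for t in str(region_field).split(";") if t]
    tagset = set(tags)
    if tagset & PROMOTER_TAGS:
        return CATEGORY_PROMOTER
    if tagset & BODY_TAGS:
        return CATEGORY_BODY
    if tagset & UTR3_TAGS:
        return CATEGORY_UTR3
    return CATEGORY_INTERGENIC


def annotate_dmps(dmps: pd.DataFrame, manifest: pd.DataFrame):
    """Attach region categories and gene lists to called DMPs.

    Returns ``(annotated, category_fractions, gene_sets)`` where
    ``category_fractions`` has one row per direction summing to 1 over the
    four categories, and ``gene_sets`` maps ``hypo``/``hyper`` to the set of
    genes with at least one DMP of that direction (a gene may appear in
    both).
    """
    man = manifest.set_index("probe")
    missing = set(dmps["probe"]) - set(man.index)
    if missing:
        raise KeyError(f"probes missing from manifest: {sorted(missing)[:5]}")
    sub = man.loc[dmps["probe"]]
    annotated = dmps.copy()
    annotated["chrom"] = sub["chrom"].to_numpy()
    annotated["pos"] = sub["pos"].to_numpy()
    annotated["genes"] = sub["gene"].fillna("").to_numpy()
    annotated["category"] = [
        probe_category(g, r)
        for g, r in zip(sub["gene"].fillna(""), sub["region"].fillna(""))
    ]
    categories = [CATEGORY_PROMOTER, CATEGORY_BODY, CATEGORY_UTR3, CATEGORY_INTERGENIC]
    rows = {}
    gene_sets = {"hypo": set(), "hyper": set()}
    for direction, grp in annotated.groupby("direction"):
        counts = grp["category"].value_counts()
        total = len(grp)
        rows[direction] = [counts.get(c, 0) / total for c in categories]
        for genes in grp["genes"]:
            gene_sets[direction].update(g for g in str(genes).split(";") if g)
    fractions = pd.DataFrame(rows, index=categories).T
    return annotated, fractions, gene_sets


def set_enrichment(
    query_genes: set, annotation_sets: dict, universe: set, fdr_max: float = 0.05
) -> pd.DataFrame:
    """One-sided Fisher over-representation of each annotation set.

    A generic gene-set test (hypergeometric upper tail) with BH correction
    across sets; usable with any user-supplied annotation (GO terms,
    pathways, ...).
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & set(universe)
    if not set(query_genes) <= set(universe):
        raise ValueError("query genes must be a subset of the universe")
    m = len(universe)
    nq = len(query)
    names, ps, ks, ns = [], [], [], []
    for name, members in annotation_sets.items():
        members = set(members) & set(universe)
        k = len(query & members)
        p = stats.hypergeom.sf(k - 1, m, len(members), nq)
        names.append(name)
        ps.append(min(1.0, float(p)))
        ks.append(k)
        ns.append(len(members))
    q = bh_fdr(ps) if names else np.array([])
    return pd.DataFrame(
        {
            "set": names,
            "n_set": ns,
            "n_query": nq,
            "overlap": ks,
            "p": ps,
            "q": q,
            "significant": q < fdr_max if names else [],
        }
    )


def concordance(array_beta, pyro_percent):
    """OLS of pyrosequencing %-methylation on 100x array beta.

    Returns ``(r2, slope, intercept)``; used to check platform agreement.
    """
    x = 100.0 * np.asarray(array_beta, dtype=float)
    y = np.asarray(pyro_percent, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("concordance needs equal-length vectors of size >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in array betas")
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.slope), float(res.intercept)


def dmp_workflow(
    beta: pd.DataFrame,
    design: pd.DataFrame,
    iqr_threshold: float = 0.50,
    fc_hyper: float = 2.0,
    fc_hypo: float = 0.5,
    p_max: float = 0.01,
    fdr_max: float = 0.05,
    inclusive: bool = True,
):
    """Full DMP stage: M transform, quantile normalize, IQR filter, test, call.

    Statistics run on normalized, filtered M-values; fold changes and
    delta-beta are reported on the normalized betas mapped back through the
    logistic.  Returns ``(dmp_table, mod_stats, kept_probes)``.
    """
    if beta.isna().any().any():
        raise ValueError("missing beta values are rejected, not imputed")
    m = beta_to_m(beta)
    m_norm = quantile_normalize(m)
    kept = iqr_filter(m_norm, iqr_threshold)
    m_kept = m_norm.loc[kept]
    mod = paired_moderated_t(m_kept, design)
    beta_norm = m_to_beta(m_kept)
    dmps = call_dmps(
        beta_norm, design, mod,
        fc_hyper=fc_hyper, fc_hypo=fc_hypo,
        p_max=p_max, fdr_max=fdr_max, inclusive=inclusive,
    )
    return dmps, mod, kept
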