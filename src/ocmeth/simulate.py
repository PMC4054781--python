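"""Synthetic data generator with recorded ground truth.

Emulates the study design of a monocyte-to-osteoclast (MO/OC)
differentiation methylome experiment: donor-paired 450K-style beta
matrices with planted hypo-/hypermethylated CpGs, a 0/5/20-day expression
time course coupled to the methylation truth, 500-bp CpG window sequences
with planted transcription-factor motifs, ChIP-seq-style peak calls over a
known subset of windows, and qPCR Cq tables encoding a transient 5hmC rise.
Every generator is a pure function of (config, seed): identical inputs give
bit-identical outputs.

The noise model is logit-normal (Gaussian on the M scale, where the
downstream statistics operate).  Donor pairing is a random intercept shared
by the MO and OC sample of a donor, so the paired test is strictly more
powerful than an unpaired one.  Planted hypomethylated probes start mostly
methylated and hypermethylated probes mostly unmethylated, so the planted
logit shift is a biologically meaningful beta change able to cross the
fold-change thresholds.  80% of probes sit >1 kb apart; 20% come in bursts
of 3-12 probes within 500 bp so maxgap clustering has non-trivial truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .chipseq import GenomicInterval
from .motifs import BASES, Pfm

_BETA_CLIP = 1e-12

# qPCR forward-model constants: fixed input Cq levels and the no-GT
# (MspI-sensitive) background fraction of the 5hmC assay.
_HMC_INPUT_CQ = 24.0
_HMC_NOGT_RATIO = 0.1
_EXPR_REF_CQ = 20.0
_CHIP_INPUT_CQ = 24.0
_CHIP_INPUT_FRACTION = 0.1
_CHIP_IGG_PCT = 0.02

#: default 5hmC trajectories (% 5hmC per day): a transient rise-then-fall at
#: rapidly demethylated regions, one region primed high, one flat control.
HMC_TRAJECTORIES = {
    "ACP5_prom": {0: 5.0, 2: 40.0, 5: 25.0, 20: 10.0},
    "TM4SF19_prom": {0: 3.0, 2: 30.0, 5: 22.0, 20: 8.0},
    "TM7SF4_prom": {0: 35.0, 2: 32.0, 5: 25.0, 20: 18.0},
    "CTRL_flat": {0: 1.0, 2: 1.0, 5: 1.0, 20: 1.0},
}

#: relative expression (vs a reference gene) for the qRT-PCR panel.
EXPR_TRAJECTORIES = {
    "ACP5": {0: 1.0, 2: 4.0, 5: 12.0, 20: 15.0},
    "CTSK": {0: 1.0, 2: 3.0, 5: 8.0, 20: 10.0},
    "CX3CR1": {0: 1.0, 2: 0.6, 5: 0.3, 20: 0.2},
}

#: ChIP percent-input (after IgG subtraction) at 0 and 2 days.
CHIP_TRAJECTORIES = {
    "PU1_ACP5": {0: 0.625, 2: 1.8},
    "TET2_ACP5": {0: 0.2, 2: 0.9},
    "DNMT3B_ACP5": {0: 0.8, 2: 0.3},
}


def default_motifs() -> list[Pfm]:
    """Built-in synthetic PFMs: the planted ETS-core motif plus decoys.

    These are synthetic stand-ins constructed from the factors' published
    consensus sequences (TRANSFAC matrices are licensed and not shipped):
    strong consensus counts (18 of 20) with the remainder spread evenly.
    """

    def from_consensus(motif_id: str, consensus: str) -> Pfm:
        counts = np.full((4, len(consensus)), 2.0 / 3.0)
        for j, base in enumerate(consensus):
            counts[BASES.index(base), j] = 18.0
        return Pfm(motif_id, counts)

    return [
        from_consensus("PU1_LIKE", "AAAGAGGAAG"),
        from_consensus("AP1_LIKE", "ATGACTCATC"),
        from_consensus("NFKB_LIKE", "GGGACTTTCC"),
        from_consensus("CEBP_LIKE", "ATTGCGCAAT"),
        from_consensus("MEF2_LIKE", "CTATTTATAG"),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_probes: int = 20000
    n_pairs: int = 3
    frac_hypo: float = 0.025
    frac_hyper: float = 0.025
    effect_logit: float = 2.0
    noise_sd_logit: float = 0.3
    donor_sd_logit: float = 0.5
    n_genes: int = 4000
    de_coupling: float = 0.62
    de_bg_rate: float = 0.02
    body_coupling_factor: float = 1.0
    n_expr_reps: int = 3
    expr_noise_sd: float = 0.3
    day5_fraction: float = 0.95
    window_len: int = 500
    gc: float = 0.5
    motif_rate_fg: float = 0.5
    motif_rate_bg: float = 0.05
    peak_rate_fg: float = 0.25
    peak_rate_bg: float = 0.05
    cq_noise_sd: float = 0.15
    n_chroms: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.n_probes <= 0 or self.n_pairs <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        if self.n_expr_reps < 2:
            raise ValueError("need at least 2 expression replicates per timepoint")
        for name in (
            "frac_hypo", "frac_hyper", "de_coupling", "de_bg_rate",
            "body_coupling_factor", "gc", "motif_rate_fg", "motif_rate_bg",
            "peak_rate_fg", "peak_rate_bg", "day5_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_hypo + self.frac_hyper > 1.0:
            raise ValueError("frac_hypo + frac_hyper must not exceed 1")
        for name in ("noise_sd_logit", "donor_sd_logit", "expr_noise_sd", "cq_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.window_len <= 0:
            raise ValueError("window_len must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def to_flat(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_flat(cls, text: str) -> "SimulationConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown config key: {key}")
            caster = int if types[key] == "int" else float
            kwargs[key] = caster(value)
        return cls(**kwargs)


@dataclass
class TruthLabels:
    """Planted ground truth recorded alongside the generated data."""

    probe_direction: pd.Series  # probe -> hypo | hyper | null
    gene_meth_direction: pd.Series  # gene -> hypo | hyper | null
    gene_has_promoter_dmp: pd.Series  # gene -> bool
    gene_expr_direction: pd.Series = None  # gene -> up | down | null
    gene_expr_effects: pd.DataFrame = None  # gene, log2fc_day5, log2fc_day20
    window_motif: pd.Series = None  # probe -> bool (motif planted)
    motif_instances: pd.DataFrame = None  # probe, offset, strand
    window_peak: pd.Series = None  # probe -> bool (peak planted)
    hmc_trajectories: pd.DataFrame = None  # region, timepoint, pct


@dataclass
class MethylationData:
    beta: pd.DataFrame  # probes x samples (both arms)
    design: pd.DataFrame  # sample, donor, condition
    manifest: pd.DataFrame  # probe, chrom, pos, gene, region
    truth: TruthLabels

    @property
    def beta_mo(self) -> pd.DataFrame:
        mo = self.design.loc[self.design["condition"] == "MO", "sample"]
        return self.beta[list(mo)]

    @property
    def beta_oc(self) -> pd.DataFrame:
        oc = self.design.loc[self.design["condition"] == "OC", "sample"]
        return self.beta[list(oc)]


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def _planted_count(frac: float, n: int) -> int:
    return int(round(frac * n))


def _make_manifest(config: SimulationConfig, rng: np.random.Generator):
    """Probe coordinates, burst structure, and gene/region annotation."""
    n = config.n_probes
    per_chrom = [n // config.n_chroms] * config.n_chroms
    for i in range(n % config.n_chroms):
        per_chrom[i] += 1
    probes, chroms, positions, block_ids, is_burst = [], [], [], [], []
    block_counter = 0
    probe_counter = 0
    for ci, quota in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = 1000
        placed = 0
        while placed < quota:
            if rng.random() < 0.2 and quota - placed >= 3:
                size = min(int(rng.integers(3, 13)), quota - placed)
                burst = True
            else:
                size = 1
                burst = False
            for k in range(size):
                probes.append(f"cg{probe_counter:07d}")
                chroms.append(chrom)
                positions.append(pos)
                block_ids.append(block_counter)
                is_burst.append(burst)
                probe_counter += 1
                placed += 1
                if k < size - 1:
                    pos += int(rng.integers(30, 61))
            pos += int(rng.integers(1001, 5001))
            block_counter += 1
    manifest = pd.DataFrame(
        {
            "probe": probes,
            "chrom": chroms,
            "pos": positions,
            "block": block_ids,
            "burst": is_burst,
        }
    )
    # group isolated probes into multi-probe gene blocks of 1-4
    gene_block = np.empty(len(manifest), dtype=int)
    gb = 0
    i = 0
    blocks = manifest["block"].to_numpy()
    bursts = manifest["burst"].to_numpy()
    while i < len(manifest):
        if bursts[i]:
            j = i
            while j < len(manifest) and blocks[j] == blocks[i]:
                j += 1
        else:
            j = min(i + int(rng.integers(1, 5)), len(manifest))
            # do not swallow a following burst into a single-probe gene block
            for k in range(i, j):
                if bursts[k]:
                    j = k
                    break
            j = max(j, i + 1)
        gene_block[i:j] = gb
        gb += 1
        i = j
    manifest["gene_block"] = gene_block

    promoter_tags = np.array(["TSS200", "TSS1500", "5'UTR", "1stExon"])
    genes = np.full(len(manifest), "", dtype=object)
    regions = np.full(len(manifest), "", dtype=object)
    gene_counter = 0
    for _, idx in manifest.groupby("gene_block").groups.items():
        idx = np.asarray(idx)
        genic = rng.random() < 0.7 and gene_counter < config.n_genes
        if not genic:
            continue
        gene = f"GENE{gene_counter:05d}"
        gene_counter += 1
        if bursts[idx[0]]:
            u = rng.random()
            if u < 0.6:
                tags = rng.choice(promoter_tags, size=len(idx))
            elif u < 0.9:
                tags = np.full(len(idx), "Body")
            else:
                tags = np.full(len(idx), "3'UTR")
        else:
            tags = rng.choice(
                np.array(["TSS200", "TSS1500", "Body", "Body", "Body", "3'UTR"]),
                size=len(idx),
            )
        genes[idx] = gene
        regions[idx] = tags
    manifest["gene"] = genes
    manifest["region"] = regions
    return manifest


def _plant_directions(config, manifest, rng) -> pd.Series:
    """Assign hypo/hyper labels block-wise so genes stay direction-consistent."""
    n_hypo = _planted_count(config.frac_hypo, config.n_probes)
    n_hyper = _planted_count(config.frac_hyper, config.n_probes)
    direction = pd.Series("null", index=manifest["probe"], name="direction")
    block_groups = list(manifest.groupby("gene_block").groups.items())
    order = rng.permutation(len(block_groups))
    quotas = [("hypo", n_hypo), ("hyper", n_hyper)]
    qi = 0
    for oi in order:
        if qi >= len(quotas):
            break
        label, remaining = quotas[qi]
        if remaining == 0:
            qi += 1
            if qi >= len(quotas):
                break
            label, remaining = quotas[qi]
        _, idx = block_groups[oi]
        take = min(len(idx), remaining)
        chosen = manifest.loc[np.asarray(idx)[:take], "probe"]
        direction.loc[chosen] = label
        quotas[qi] = (label, remaining - take)
    if quotas and any(r > 0 for _, r in quotas):
        raise ValueError("not enough probes to plant the requested fractions")
    return direction


def generate_methylation(
    config: SimulationConfig, baseline_logit: float | None = None
) -> MethylationData:
    """Donor-paired MO/OC beta matrices with planted direction labels.

    ``baseline_logit`` overrides the per-probe baseline with a constant
    (used for calibration checks); by default baselines come from a
    two-component logit-normal mixture for null probes and from
    methylated/unmethylated starting points for planted hypo/hyper probes.
    """
    rng = _rng(config, 1)
    manifest = _make_manifest(config, rng)
    direction = _plant_directions(config, manifest, rng)
    n = config.n_probes
    d = direction.to_numpy()
    if baseline_logit is not None:
        base = np.full(n, float(baseline_logit))
    else:
        comp = rng.random(n) < 0.5
        base = np.where(
            comp, rng.normal(-2.5, 0.8, n), rng.normal(2.5, 0.8, n)
        )
        # planted probes start where a +-effect_logit shift is a meaningful
        # beta change: hypo probes mostly methylated, hyper mostly not, with
        # baselines kept clear of the region where the shifted fold change
        # could never cross the 2 / 0.5 thresholds even noise-free
        base = np.where(d == "hypo", rng.normal(0.8, 0.4, n), base)
        base = np.where(d == "hyper", rng.normal(-1.5, 0.4, n), base)
    shift = np.where(d == "hypo", -config.effect_logit, 0.0) + np.where(
        d == "hyper", config.effect_logit, 0.0
    )
    columns, names, design_rows = [], [], []
    for j in range(config.n_pairs):
        donor = rng.normal(0.0, config.donor_sd_logit, n)
        mo = base + donor + rng.normal(0.0, config.noise_sd_logit, n)
        oc = base + donor + shift + rng.normal(0.0, config.noise_sd_logit, n)
        columns += [mo, oc]
        names += [f"MO_D{j + 1}", f"OC_D{j + 1}"]
        design_rows += [
            {"sample": f"MO_D{j + 1}", "donor": f"D{j + 1}", "condition": "MO"},
            {"sample": f"OC_D{j + 1}", "donor": f"D{j + 1}", "condition": "OC"},
        ]
    beta = pd.DataFrame(
        np.clip(expit(np.column_stack(columns)), _BETA_CLIP, 1.0 - _BETA_CLIP),
        index=pd.Index(manifest["probe"], name="probe"),
        columns=names,
    )
    design = pd.DataFrame(design_rows)

    all_genes = pd.Index([f"GENE{i:05d}" for i in range(config.n_genes)], name="gene")
    gene_dir = pd.Series("null", index=all_genes)
    promoter = pd.Series(False, index=all_genes)
    promoter_tags = {"TSS200", "TSS1500", "5'UTR", "1stExon"}
    planted = pd.DataFrame(
        {
            "gene": manifest["gene"].to_numpy(),
            "region": manifest["region"].to_numpy(),
            "dir": direction.to_numpy(),
        }
    )
    planted = planted[(planted["dir"] != "null") & (planted["gene"] != "")]
    for gene, grp in planted.groupby("gene"):
        gene_dir[gene] = grp["dir"].iloc[0]
        promoter[gene] = bool(set(grp["region"]) & promoter_tags)
    truth = TruthLabels(
        probe_direction=direction,
        gene_meth_direction=gene_dir,
        gene_has_promoter_dmp=promoter,
    )
    manifest = manifest[["probe", "chrom", "pos", "gene", "region"]].copy()
    return MethylationData(beta, design, manifest, truth)


def generate_expression(config: SimulationConfig, truth: TruthLabels) -> pd.DataFrame:
    """0/5/20-day log2 expression matrix coupled to the methylation truth.

    A methylation-labeled gene changes concordantly (hypo->up, hyper->down)
    with probability ``de_coupling`` (scaled by ``body_coupling_factor``
    for genes without a promoter-region planted probe); otherwise — and for
    all unlabeled genes — the label is drawn from a small background rate in
    each direction, so that at ``de_coupling=0`` expression labels are
    independent of methylation labels.  Planted genes realize
    ``day5_fraction`` of their total log2 change by day 5.
    """
    rng = _rng(config, 2)
    genes = truth.gene_meth_direction.index
    labels = pd.Series("null", index=genes)
    effects = np.zeros(len(genes))
    for i, gene in enumerate(genes):
        meth = truth.gene_meth_direction[gene]
        coupled = False
        if meth in ("hypo", "hyper"):
            p = config.de_coupling
            if not truth.gene_has_promoter_dmp[gene]:
                p *= config.body_coupling_factor
            if rng.random() < p:
                labels.iloc[i] = "up" if meth == "hypo" else "down"
                coupled = True
        if not coupled:
            u = rng.random()
            if u < config.de_bg_rate:
                labels.iloc[i] = "up"
            elif u < 2 * config.de_bg_rate:
                labels.iloc[i] = "down"
        if labels.iloc[i] != "null":
            mag = rng.uniform(1.5, 3.5)
            effects[i] = mag if labels.iloc[i] == "up" else -mag
    baseline = rng.normal(7.0, 1.0, len(genes))
    day_effect = {0: 0.0, 5: config.day5_fraction, 20: 1.0}
    cols, names = [], []
    for day in (0, 5, 20):
        for r in range(config.n_expr_reps):
            cols.append(
                baseline
                + effects * day_effect[day]
                + rng.normal(0.0, config.expr_noise_sd, len(genes))
            )
            names.append(f"d{day}_{r + 1}")
    expr = pd.DataFrame(np.column_stack(cols), index=genes, columns=names)
    truth.gene_expr_direction = labels
    truth.gene_expr_effects = pd.DataFrame(
        {
            "gene": genes,
            "log2fc_day5": effects * config.day5_fraction,
            "log2fc_day20": effects,
        }
    )
    return expr


def _sample_motif_instance(pfm: Pfm, rng: np.random.Generator) -> str:
    probs = (pfm.counts + 0.25) / (pfm.counts.sum(axis=0) + 1.0)
    return "".join(
        BASES[rng.choice(4, p=probs[:, j] / probs[:, j].sum())]
        for j in range(pfm.length)
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_windows_and_sequences(
    config: SimulationConfig,
    manifest: pd.DataFrame,
    truth: TruthLabels,
    pfm: Pfm | None = None,
) -> dict[str, str]:
    """Window sequences with motif instances planted at cohort rates.

    Background bases are i.i.d. at the configured GC content.  A motif
    instance sampled from the PFM is embedded at a random offset and strand
    with probability ``motif_rate_fg`` in foreground (planted hypo/hyper)
    windows and ``motif_rate_bg`` elsewhere.  Flags, offsets and strands are
    recorded in the truth labels.
    """
    if pfm is None:
        pfm = default_motifs()[0]
    if pfm.length > config.window_len:
        raise ValueError("motif longer than window")
    rng = _rng(config, 3)
    base_p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    lookup = np.array(list(BASES), dtype="U1")
    codes = rng.choice(4, size=(len(manifest), config.window_len), p=base_p)
    backgrounds = ["".join(row) for row in lookup[codes]]
    seqs: dict[str, str] = {}
    planted = pd.Series(False, index=manifest["probe"])
    inst_rows = []
    fg = set(truth.probe_direction.index[truth.probe_direction != "null"])
    for i, probe in enumerate(manifest["probe"]):
        seq = backgrounds[i]
        rate = config.motif_rate_fg if probe in fg else config.motif_rate_bg
        if rng.random() < rate:
            instance = _sample_motif_instance(pfm, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                instance = _revcomp(instance)
            offset = int(rng.integers(0, config.window_len - pfm.length + 1))
            seq = seq[:offset] + instance + seq[offset + pfm.length :]
            planted[probe] = True
            inst_rows.append({"probe": probe, "offset": offset, "strand": strand})
        seqs[probe] = seq
    truth.window_motif = planted
    truth.motif_instances = pd.DataFrame(
        inst_rows, columns=["probe", "offset", "strand"]
    )
    return seqs


def generate_peaks(
    config: SimulationConfig, manifest: pd.DataFrame, truth: TruthLabels
) -> list[GenomicInterval]:
    """ChIP-seq-style peaks placed over a known subset of CpG windows.

    Each selected CpG receives one peak guaranteed to overlap its 500-bp
    window by at least one base; selection probability is ``peak_rate_fg``
    for planted (hypo/hyper) probes and ``peak_rate_bg`` otherwise.
    """
    rng = _rng(config, 4)
    fg = set(truth.probe_direction.index[truth.probe_direction != "null"])
    flagged = pd.Series(False, index=manifest["probe"])
    peaks = []
    counter = 0
    for row in manifest.itertuples(index=False):
        rate = config.peak_rate_fg if row.probe in fg else config.peak_rate_bg
        if rng.random() >= rate:
            continue
        center = row.pos - 1 + int(rng.integers(-200, 201))
        half = int(rng.integers(75, 201))
        start = max(0, center - half)
        end = center + half
        peaks.append(
            GenomicInterval(row.chrom, start, end, f"PEAK_{counter:06d}", 0, ".")
        )
        flagged[row.probe] = True
        counter += 1
    truth.window_peak = flagged
    return sorted(peaks, key=lambda iv: (iv.chrom, iv.start, iv.end))


def generate_qpcr(
    config: SimulationConfig, noise_sd: float | None = None
) -> tuple[pd.DataFrame, TruthLabels]:
    """Long-format Cq tables for the 5hmC, expression and ChIP assays.

    Cq values are back-computed from the target trajectories under 100%
    efficiency and perturbed with Gaussian Cq noise of SD ``noise_sd``
    (``config.cq_noise_sd`` by default); with zero noise the quantitation
    functions recover the trajectories exactly.
    """
    if noise_sd is None:
        noise_sd = config.cq_noise_sd
    rng = _rng(config, 5)
    n_reps = 3
    rows = []

    def noisy(cq: float) -> float:
        return float(cq + rng.normal(0.0, noise_sd)) if noise_sd > 0 else float(cq)

    hmc_rows = []
    for region, traj in HMC_TRAJECTORIES.items():
        for tp, pct in traj.items():
            hmc_rows.append({"region": region, "timepoint": tp, "pct_5hmC": pct})
            q_nogt = _HMC_NOGT_RATIO
            q_gt = q_nogt + pct / 100.0
            for rep in range(1, n_reps + 1):
                for treatment, q in (("GT", q_gt), ("noGT", q_nogt), ("input", 1.0)):
                    cq = _HMC_INPUT_CQ - np.log2(q)
                    rows.append(
                        {
                            "assay": "hmc",
                            "target": region,
                            "sample": f"{region}_d{tp}_r{rep}",
                            "timepoint": tp,
                            "treatment": treatment,
                            "replicate": rep,
                            "cq": noisy(cq),
                            "efficiency": 2.0,
                        }
                    )
    for target, traj in EXPR_TRAJECTORIES.items():
        for tp, rq in traj.items():
            for rep in range(1, n_reps + 1):
                for name, cq in (
                    (target, _EXPR_REF_CQ - np.log2(rq)),
                    ("REF", _EXPR_REF_CQ),
                ):
                    rows.append(
                        {
                            "assay": "expression",
                            "target": name,
                            "sample": f"{name}_d{tp}_r{rep}",
                            "timepoint": tp,
                            "treatment": "none",
                            "replicate": rep,
                            "cq": noisy(cq),
                            "efficiency": 2.0,
                        }
                    )
    for target, traj in CHIP_TRAJECTORIES.items():
        for tp, pct in traj.items():
            raw_ratio = (pct + _CHIP_IGG_PCT) / (100.0 * _CHIP_INPUT_FRACTION)
            igg_ratio = _CHIP_IGG_PCT / (100.0 * _CHIP_INPUT_FRACTION)
            for rep in range(1, n_reps + 1):
                for treatment, cq in (
                    ("bound", _CHIP_INPUT_CQ - np.log2(raw_ratio)),
                    ("IgG", _CHIP_INPUT_CQ - np.log2(igg_ratio)),
                    ("input", _CHIP_INPUT_CQ),
                ):
                    rows.append(
                        {
                            "assay": "chip",
                            "target": target,
                            "sample": f"{target}_d{tp}_r{rep}",
                            "timepoint": tp,
                            "treatment": treatment,
                            "replicate": rep,
                            "cq": noisy(cq),
                            "efficiency": 2.0,
                        }
                    )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(hmc_rows)
    return table, truth


@dataclass
class SimulationResult:
    config: SimulationConfig
    beta: pd.DataFrame
    design: pd.DataFrame
    manifest: pd.DataFrame
    expression: pd.DataFrame
    sequences: dict
    peaks: list
    qpcr: pd.DataFrame
    truth: TruthLabels


def simulate_all(config: SimulationConfig, pfm: Pfm | None = None) -> SimulationResult:
    """Run every generator and collect all inputs plus ground truth."""
    meth = generate_methylation(config)
    expr = generate_expression(config, meth.truth)
    seqs = generate_windows_and_sequences(config, meth.manifest, meth.truth, pfm)
    peaks = generate_peaks(config, meth.manifest, meth.truth)
    qpcr_table, hmc_truth = generate_qpcr(config)
    meth.truth.hmc_trajectories = hmc_truth
    return SimulationResult(
        config, meth.beta, meth.design, meth.manifest, expr, seqs, peaks,
        qpcr_table, meth.truth,
    )
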