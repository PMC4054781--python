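"""End-to-end orchestration of the analysis stages.

Stages run in dependency order: ``simulate -> dmp -> dmr -> integrate ->
motifs -> chip -> assays -> report``.  Every output file is recorded with a
sha256 content hash in a run manifest, so a rerun with the same config and
seed reproduces every hash.  Log lines (stage, level, timestamp) go to
standard error; no timestamps are written into hashed outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import pandas as pd

from . import chipseq, diffmeth, dmr, expression, io, motifs, qpcr
from .simulate import SimulationConfig, default_motifs, simulate_all

logger = logging.getLogger("ocmeth.pipeline")

STAGE_ORDER = ("simulate", "dmp", "dmr", "integrate", "motifs", "chip", "assays")


class ConfigError(ValueError):
    """Configuration is inconsistent (CLI exit code 3)."""


class MissingInputError(FileNotFoundError):
    """A referenced input file does not exist (CLI exit code 2)."""


@dataclass
class PipelineConfig:
    """Paths, stage toggles, and stage parameters.

    Defaults are the study's stated parameters: FC 2/0.5, p 0.01, FDR 0.05,
    maxgap 500, window 500, motif p 0.00002 (cohorts) / 0.00001
    (background), enrichment FDR 0.25.
    """

    outdir: str = "ocmeth_run"
    seed: int = 0
    stages: str = "simulate,dmp,dmr,integrate,motifs,chip,assays"
    # input paths (filled automatically when the simulate stage runs)
    beta: str = ""
    design: str = ""
    manifest: str = ""
    expression: str = ""
    sequences: str = ""
    peaks: str = ""
    qpcr: str = ""
    motif_file: str = ""  # TRANSFAC flat file; empty = built-in synthetic set
    dmp_table: str = ""  # allows running later stages from a saved table
    truth_probes: str = ""
    truth_genes: str = ""
    # analysis parameters
    iqr_threshold: float = 0.50
    fc_hyper: float = 2.0
    fc_hypo: float = 0.5
    p_max: float = 0.01
    fdr_max: float = 0.05
    maxgap: int = 500
    min_cpgs: int = 10
    window_len: int = 500
    motif_p_fg: float = 2e-5
    motif_p_bg: float = 1e-5
    enrich_fdr: float = 0.25
    # simulation sizes (only used by the simulate stage)
    n_probes: int = 20000
    n_pairs: int = 3
    frac_hypo: float = 0.025
    frac_hyper: float = 0.025
    de_coupling: float = 0.62

    def stage_list(self) -> list[str]:
        requested = [s.strip() for s in self.stages.split(",") if s.strip()]
        unknown = set(requested) - set(STAGE_ORDER)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        return [s for s in STAGE_ORDER if s in requested]

    def to_flat(self) -> str:
        return "\n".join(f"{f.name} = {getattr(self, f.name)}" for f in fields(self)) + "\n"

    @classmethod
    def from_flat(cls, text: str) -> "PipelineConfig":
        defaults = cls()
        kwargs = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, sep, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not sep or not hasattr(defaults, key):
                raise ConfigError(f"unknown config line: {raw!r}")
            current = getattr(defaults, key)
            caster = type(current)
            kwargs[key] = caster(value)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(config: PipelineConfig, attr: str, stage: str) -> Path:
    value = getattr(config, attr)
    if not value:
        raise ConfigError(
            f"stage '{stage}' needs '{attr}' (enable an earlier stage or set the path)"
        )
    path = Path(value)
    if not path.exists():
        raise MissingInputError(f"stage '{stage}': input file not found: {path}")
    return path


class PipelineRun:
    """Mutable state threaded through the stages of one run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = io.ensure_dir(config.outdir)
        self.outputs: dict[str, str] = {}
        self.summary: dict = {"seed": config.seed}

    def record(self, path: Path) -> None:
        self.outputs[str(path.relative_to(self.outdir))] = _sha256(path)

    # ------------------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config
        sim_cfg = SimulationConfig(
            n_probes=cfg.n_probes,
            n_pairs=cfg.n_pairs,
            frac_hypo=cfg.frac_hypo,
            frac_hyper=cfg.frac_hyper,
            de_coupling=cfg.de_coupling,
            window_len=cfg.window_len,
            seed=cfg.seed,
        )
        sim = simulate_all(sim_cfg)
        indir = io.ensure_dir(self.outdir / "inputs")
        io.write_matrix(sim.beta, indir / "beta.tsv", "probe")
        io.write_table(sim.design, indir / "design.tsv")
        io.write_table(sim.manifest, indir / "manifest.tsv")
        io.write_matrix(sim.expression, indir / "expression.tsv", "gene")
        io.write_fasta(sim.sequences, indir / "windows.fasta")
        chipseq.write_bed(sim.peaks, indir / "peaks.bed")
        io.write_table(sim.qpcr, indir / "qpcr.tsv")
        truth_probes = sim.truth.probe_direction.rename("direction").reset_index()
        truth_probes.columns = ["probe", "direction"]
        truth_probes["motif_planted"] = sim.truth.window_motif.to_numpy()
        truth_probes["peak_planted"] = sim.truth.window_peak.to_numpy()
        io.write_table(truth_probes, indir / "truth_probes.tsv")
        truth_genes = pd.DataFrame(
            {
                "gene": sim.truth.gene_meth_direction.index,
                "meth_direction": sim.truth.gene_meth_direction.to_numpy(),
                "expr_direction": sim.truth.gene_expr_direction.to_numpy(),
            }
        )
        io.write_table(truth_genes, indir / "truth_genes.tsv")
        (indir / "sim_config.txt").write_text(sim_cfg.to_flat())
        for name in (
            "beta.tsv", "design.tsv", "manifest.tsv", "expression.tsv",
            "windows.fasta", "peaks.bed", "qpcr.tsv", "truth_probes.tsv",
            "truth_genes.tsv", "sim_config.txt",
        ):
            self.record(indir / name)
        cfg.beta = str(indir / "beta.tsv")
        cfg.design = str(indir / "design.tsv")
        cfg.manifest = str(indir / "manifest.tsv")
        cfg.expression = str(indir / "expression.tsv")
        cfg.sequences = str(indir / "windows.fasta")
        cfg.peaks = str(indir / "peaks.bed")
        cfg.qpcr = str(indir / "qpcr.tsv")
        cfg.truth_probes = str(indir / "truth_probes.tsv")
        cfg.truth_genes = str(indir / "truth_genes.tsv")

    # ------------------------------------------------------------------
    def stage_dmp(self) -> None:
        cfg = self.config
        beta = io.read_matrix(_require(cfg, "beta", "dmp"))
        design = io.read_table(_require(cfg, "design", "dmp"))
        manifest = io.read_table(_require(cfg, "manifest", "dmp"))
        manifest["gene"] = manifest["gene"].fillna("")
        manifest["region"] = manifest["region"].fillna("")
        dmps, mod, kept = diffmeth.dmp_workflow(
            beta, design,
            iqr_threshold=cfg.iqr_threshold,
            fc_hyper=cfg.fc_hyper, fc_hypo=cfg.fc_hypo,
            p_max=cfg.p_max, fdr_max=cfg.fdr_max,
        )
        annotated, fractions, gene_sets = diffmeth.annotate_dmps(dmps, manifest)
        path = self.outdir / "dmp_table.tsv"
        io.write_table(annotated, path)
        self.record(path)
        cfg.dmp_table = str(path)
        self.summary["dmp"] = {
            "n_probes_tested": int(len(kept)),
            "n_dmps": int(len(dmps)),
            "n_hypo": int((dmps["direction"] == "hypo").sum()),
            "n_hyper": int((dmps["direction"] == "hyper").sum()),
            "category_fractions": {
                direction: {c: round(v, 4) for c, v in row.items()}
                for direction, row in fractions.iterrows()
            },
            "n_hypo_genes": len(gene_sets["hypo"]),
            "n_hyper_genes": len(gene_sets["hyper"]),
        }
        if cfg.truth_probes:
            truth = io.read_table(cfg.truth_probes).set_index("probe")["direction"]
            called = annotated.set_index("probe")["direction"]
            planted = truth[truth != "null"]
            tp = sum(called.get(p, "") == d for p, d in planted.items())
            fp = sum(truth.get(p, "null") == "null" for p in called.index)
            self.summary["dmp"]["sensitivity"] = tp / len(planted) if len(planted) else 0.0
            self.summary["dmp"]["empirical_fdr"] = fp / len(called) if len(called) else 0.0

    def _load_dmps(self, stage: str) -> pd.DataFrame:
        path = _require(self.config, "dmp_table", stage)
        table = io.read_table(path)
        table["genes"] = table.get("genes", pd.Series("", index=table.index)).fillna("")
        return table

    # ------------------------------------------------------------------
    def stage_dmr(self) -> None:
        cfg = self.config
        dmps = self._load_dmps("dmr")
        regions = dmr.cluster_dmps(dmps, maxgap=cfg.maxgap)
        large = dmr.filter_dmrs(regions, cfg.min_cpgs) if len(regions) else regions
        path = self.outdir / "dmr_table.tsv"
        io.write_table(regions, path)
        self.record(path)
        self.summary["dmr"] = {
            "n_dmrs": int(len(regions)),
            "n_multi_cpg": int((regions["n_cpgs"] >= 2).sum()) if len(regions) else 0,
            f"n_ge_{cfg.min_cpgs}_cpgs": int(len(large)),
            "max_cpgs": int(regions["n_cpgs"].max()) if len(regions) else 0,
        }

    # ------------------------------------------------------------------
    def stage_integrate(self) -> None:
        cfg = self.config
        dmps = self._load_dmps("integrate")
        expr = io.read_matrix(_require(cfg, "expression", "integrate"))
        gene_sets = {"hypo": set(), "hyper": set()}
        for direction, grp in dmps.groupby("direction"):
            for genes in grp["genes"]:
                gene_sets[direction].update(g for g in str(genes).split(";") if g)
        d0 = expression.timepoint_samples(expr, 0)
        d20 = expression.timepoint_samples(expr, 20)
        de = expression.call_de(
            expr, d0, d20,
            iqr_threshold=cfg.iqr_threshold,
            fc_up=cfg.fc_hyper, fc_down=cfg.fc_hypo,
            p_max=cfg.p_max, fdr_max=cfg.fdr_max,
        )
        de_path = self.outdir / "de_table.tsv"
        io.write_table(de, de_path)
        self.record(de_path)
        result = expression.integrate(gene_sets, de)
        joint = pd.DataFrame(
            sorted(
                (
                    {"joint_class": k, "gene": g}
                    for k, genes in result["classes"].items()
                    for g in genes
                ),
                key=lambda r: (r["joint_class"], r["gene"]),
            ),
            columns=["joint_class", "gene"],
        )
        jpath = self.outdir / "integration.tsv"
        io.write_table(joint, jpath)
        self.record(jpath)
        # per-CpG points: delta beta vs the gene's log2FC, by region category
        de_fc = dict(zip(de["gene"].str.casefold(), de["log2FC"]))
        points = []
        for row in dmps.itertuples(index=False):
            for gene in str(row.genes).split(";"):
                key = gene.casefold()
                if gene and key in de_fc:
                    points.append(
                        {
                            "category": row.category,
                            "delta_beta": row.delta_beta,
                            "log2fc": de_fc[key],
                        }
                    )
        slopes = expression.region_slopes(pd.DataFrame(points, columns=["category", "delta_beta", "log2fc"]))
        spath = self.outdir / "slopes.tsv"
        io.write_table(slopes, spath)
        self.record(spath)
        n_hypo = len(gene_sets["hypo"])
        n_hyper = len(gene_sets["hyper"])
        counts = result["counts"]
        self.summary["integration"] = {
            "n_de_up": int((de["direction"] == "up").sum()),
            "n_de_down": int((de["direction"] == "down").sum()),
            "joint_counts": counts,
            "hypo_up_fraction": counts["hypo_up"] / n_hypo if n_hypo else 0.0,
            "hyper_down_fraction": counts["hyper_down"] / n_hyper if n_hyper else 0.0,
            "slopes": {r["category"]: round(r["slope"], 4) for _, r in slopes.iterrows()},
        }

    # ------------------------------------------------------------------
    def stage_motifs(self) -> None:
        cfg = self.config
        dmps = self._load_dmps("motifs")
        manifest = io.read_table(_require(cfg, "manifest", "motifs"))
        seqs = io.read_fasta(_require(cfg, "sequences", "motifs"))
        if cfg.motif_file:
            pfms = motifs.read_transfac(Path(cfg.motif_file).read_text())
        else:
            pfms = default_motifs()
        windows = motifs.build_windows(manifest, dmps, seqs, cfg.window_len)
        cohorts = {"hypo": [], "hyper": [], "other": []}
        for w in windows:
            cohorts[w.cohort].append(w)
        enrichments = {}
        hit_ids: dict[str, set] = {}
        for pfm in pfms:
            pwm = motifs.pfm_to_pwm(pfm)
            thr_fg = motifs.score_threshold(pwm, cfg.motif_p_fg)
            thr_bg = motifs.score_threshold(pwm, cfg.motif_p_bg)
            bg_scan = motifs.scan_windows(cohorts["other"], pwm, thr_bg)
            bg_hits = bg_scan["hit"].to_numpy()
            for cohort in ("hypo", "hyper"):
                if not cohorts[cohort]:
                    continue
                scan = motifs.scan_windows(cohorts[cohort], pwm, thr_fg)
                enrichments.setdefault(cohort, {})[pfm.motif_id] = (
                    scan["hit"].to_numpy(), bg_hits
                )
                hit_ids.setdefault(pfm.motif_id, set()).update(
                    scan.loc[scan["hit"], "window"]
                )
        self.summary["motifs"] = {}
        self._motif_targets = hit_ids
        for cohort, per_motif in enrichments.items():
            table = motifs.enrichment_table(per_motif, cfg.enrich_fdr)
            path = self.outdir / f"enrichment_{cohort}.tsv"
            io.write_table(table, path)
            self.record(path)
            self.summary["motifs"][cohort] = {
                "n_windows": len(cohorts[cohort]),
                "top_motif": table.iloc[0]["motif"] if len(table) else None,
                "significant": list(table.loc[table["significant"], "motif"]),
                "hit_pct": {
                    r["motif"]: round(100.0 * r["fg_hit"] / (r["fg_hit"] + r["fg_miss"]), 2)
                    for _, r in table.iterrows()
                },
            }

    # ------------------------------------------------------------------
    def stage_chip(self) -> None:
        cfg = self.config
        dmps = self._load_dmps("chip")
        manifest = io.read_table(_require(cfg, "manifest", "chip"))
        peaks = chipseq.read_bed(_require(cfg, "peaks", "chip"))
        manifest["gene"] = manifest["gene"].fillna("")
        manifest["region"] = manifest["region"].fillna("")
        direction = dict(zip(dmps["probe"], dmps["direction"]))
        cpgs = pd.DataFrame(
            {
                "probe": manifest["probe"],
                "chrom": manifest["chrom"],
                "pos": manifest["pos"],
                "cohort": [direction.get(p, "other") for p in manifest["probe"]],
                "category": [
                    diffmeth.probe_category(g, r)
                    for g, r in zip(manifest["gene"], manifest["region"])
                ],
            }
        )
        overlap, hit_series = chipseq.window_overlap(cpgs, peaks, cfg.window_len)
        path = self.outdir / "peak_overlap.tsv"
        io.write_table(overlap, path)
        self.record(path)
        self.summary["chip"] = {
            "fractions": {
                f"{r['cohort']}_{r['stratum']}": round(r["fraction"], 4)
                for _, r in overlap.iterrows()
            }
        }
        motif_targets = getattr(self, "_motif_targets", None)
        if motif_targets:
            # predicted targets of the lead motif (first in the PFM file,
            # insertion order) vs peak-supported DMP windows
            first = next(iter(motif_targets))
            dmp_probes = set(dmps["probe"])
            predicted = motif_targets[first] & dmp_probes
            bound = set(cpgs.loc[hit_series & cpgs["probe"].isin(dmp_probes), "probe"])
            venn = chipseq.set_overlap(bound, predicted)
            vpath = self.outdir / "venn.tsv"
            io.write_table(pd.DataFrame([{"motif": first, **venn}]), vpath)
            self.record(vpath)
            self.summary["chip"]["venn"] = {"motif": first, **venn}

    # ------------------------------------------------------------------
    def stage_assays(self) -> None:
        cfg = self.config
        table = io.read_table(_require(cfg, "qpcr", "assays"))
        hmc = qpcr.quantify_hmc(table)
        expr = qpcr.quantify_expression(table)
        chip = qpcr.quantify_chip(table)
        for name, df in (("hmc", hmc), ("expression", expr), ("chip", chip)):
            path = self.outdir / f"assay_{name}.tsv"
            io.write_table(df, path)
            self.record(path)
        self.summary["assays"] = {
            "hmc_peak_pct": round(float(hmc["pct_5hmC"].max()), 3) if len(hmc) else None,
            "n_hmc_regions": int(hmc["target"].nunique()) if len(hmc) else 0,
            "n_expression_targets": int(expr["target"].nunique()) if len(expr) else 0,
            "n_chip_targets": int(chip["target"].nunique()) if len(chip) else 0,
        }


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages; return the run manifest dict.

    Raises ``ConfigError`` / ``MissingInputError`` before any stage runs if
    the requested stages cannot be satisfied; a stage exception mid-run
    still writes the partial manifest.
    """
    stages = config.stage_list()
    state = PipelineRun(config)
    # upfront dependency validation
    deps = {
        "dmp": ["beta", "design", "manifest"],
        "dmr": ["dmp_table"],
        "integrate": ["dmp_table", "expression"],
        "motifs": ["dmp_table", "manifest", "sequences"],
        "chip": ["dmp_table", "manifest", "peaks"],
        "assays": ["qpcr"],
    }
    provided_later = set()
    if "simulate" in stages:
        provided_later |= {
            "beta", "design", "manifest", "expression", "sequences", "peaks", "qpcr",
        }
    if "dmp" in stages:
        provided_later.add("dmp_table")
    for stage in stages:
        for attr in deps.get(stage, []):
            if attr in provided_later:
                continue
            if not getattr(config, attr):
                raise ConfigError(
                    f"stage '{stage}' depends on '{attr}': enable the producing "
                    "stage or provide the path"
                )
            if not Path(getattr(config, attr)).exists():
                raise MissingInputError(
                    f"stage '{stage}': input file not found: {getattr(config, attr)}"
                )
    methods = {
        "simulate": state.stage_simulate,
        "dmp": state.stage_dmp,
        "dmr": state.stage_dmr,
        "integrate": state.stage_integrate,
        "motifs": state.stage_motifs,
        "chip": state.stage_chip,
        "assays": state.stage_assays,
    }
    try:
        for stage in stages:
            logger.info("stage %s: start", stage)
            methods[stage]()
            logger.info("stage %s: done", stage)
    finally:
        summary_path = state.outdir / "summary.json"
        summary_path.write_text(json.dumps(state.summary, indent=2, sort_keys=True))
        state.record(summary_path)
        manifest = {
            "config": asdict(config),
            "stages": stages,
            "files": state.outputs,
        }
        (state.outdir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
    return manifest


def report(outdir) -> str:
    """Human-readable summary of a completed run (reads summary.json)."""
    outdir = Path(outdir)
    summary_path = outdir / "summary.json"
    if not summary_path.exists():
        raise MissingInputError(f"no summary.json under {outdir}")
    try:
        summary = json.loads(summary_path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"corrupt summary: {exc}") from exc
    lines = [f"ocmeth run summary ({outdir})", "=" * 40]
    dmp = summary.get("dmp")
    if dmp:
        lines.append(
            f"DMPs: {dmp['n_dmps']} ({dmp['n_hypo']} hypo / {dmp['n_hyper']} hyper) "
            f"of {dmp['n_probes_tested']} tested probes"
        )
        if "sensitivity" in dmp:
            lines.append(
                f"  vs truth: sensitivity {dmp['sensitivity']:.3f}, "
                f"empirical FDR {dmp['empirical_fdr']:.3f}"
            )
        for direction, fr in dmp.get("category_fractions", {}).items():
            pretty = ", ".join(f"{k} {100 * v:.1f}%" for k, v in fr.items())
            lines.append(f"  {direction} by region: {pretty}")
    dmr_s = summary.get("dmr")
    if dmr_s:
        lines.append(
            f"DMRs: {dmr_s['n_dmrs']} total, {dmr_s['n_multi_cpg']} with >=2 CpGs, "
            f"largest {dmr_s['max_cpgs']} CpGs"
        )
    elif dmp is not None and dmp.get("n_dmps", 0) == 0:
        lines.append("DMRs: none (zero DMPs)")
    integ = summary.get("integration")
    if integ:
        jc = integ["joint_counts"]
        lines.append(
            f"Expression: {integ['n_de_up']} up / {integ['n_de_down']} down; "
            f"hypo+up {jc['hypo_up']}, hyper+down {jc['hyper_down']}"
        )
        lines.append(
            f"  hypo genes overexpressed: {100 * integ['hypo_up_fraction']:.1f}%; "
            f"hyper genes repressed: {100 * integ['hyper_down_fraction']:.1f}%"
        )
        if integ.get("slopes"):
            pretty = ", ".join(f"{k}: {v:+.2f}" for k, v in integ["slopes"].items())
            lines.append(f"  methylation-expression slopes: {pretty}")
    mot = summary.get("motifs")
    if mot:
        for cohort, info in sorted(mot.items()):
            lines.append(
                f"Motifs ({cohort}, {info['n_windows']} windows): top {info['top_motif']}, "
                f"significant: {', '.join(info['significant']) or 'none'}"
            )
    elif dmp is not None and dmp.get("n_dmps", 0) == 0:
        lines.append("Motif enrichment: skipped (no differentially methylated windows)")
    chip_s = summary.get("chip")
    if chip_s:
        pretty = ", ".join(f"{k} {100 * v:.1f}%" for k, v in chip_s["fractions"].items())
        lines.append(f"Peak overlap: {pretty}")
        if "venn" in chip_s:
            v = chip_s["venn"]
            lines.append(
                f"  peak-vs-motif overlap ({v['motif']}): {v['n_common']} common, "
                f"{v['overlap_pct']:.1f}% of union"
            )
    assays = summary.get("assays")
    if assays:
        lines.append(
            f"Assays: {assays['n_hmc_regions']} 5hmC regions (peak "
            f"{assays['hmc_peak_pct']}%), {assays['n_expression_targets']} expression "
            f"targets, {assays['n_chip_targets']} ChIP targets"
        )
    return "\n".join(lines)
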