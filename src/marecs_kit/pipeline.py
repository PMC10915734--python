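"""End-to-end orchestration: simulate -> QC -> detect -> phase -> liftover ->
CNV -> linkage, with config validation and a machine-readable run report.

Stages communicate only through standard formats (FASTQ/SAM/VCF/TSV), so each
can also be run standalone on user data via the CLI."""

from __future__ import annotations

import dataclasses
import difflib
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import __version__, cnvcall, linkhmm, phaser, scenarios, svscan
from .liftover import lift_haplotype, lift_position, read_chain
from .linkhmm import HMMParams
from .phaser import PhaseConfig
from .svscan import FilterConfig, QCConfig

log = logging.getLogger("marecs")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    scenario: str = "pedigree1"
    seed: int | None = None
    out_dir: str = "marecs_run"
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    qc: QCConfig = field(default_factory=QCConfig)
    detect: FilterConfig = field(default_factory=FilterConfig)
    detect_position_tol: int = 50
    detect_dr_margin: int = 200
    phase: PhaseConfig = field(default_factory=PhaseConfig)
    cnv: cnvcall.CNVConfig = field(default_factory=cnvcall.CNVConfig)
    linkage: HMMParams = field(default_factory=HMMParams)


_SECTION_TYPES = {
    "simulate": dict,
    "qc": QCConfig,
    "detect": FilterConfig,
    "phase": PhaseConfig,
    "cnv": cnvcall.CNVConfig,
    "linkage": HMMParams,
}
_TOP_KEYS = {"scenario", "seed", "out_dir", "log_level"} | set(_SECTION_TYPES)
_SIMULATE_KEYS = {"depth", "error_rate", "mean_read_length", "n_embryos"}


def _reject_unknown(given: dict, allowed: set[str], where: str) -> list[str]:
    errors = []
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"{where}: unknown key {key!r}{suffix}")
    return errors


def validate_config(source: str | dict) -> PipelineConfig:
    """Parse and normalize a YAML config (path or pre-parsed mapping); defaults
    are injected, unknown keys rejected with a suggestion, and every offending
    key reported in one pass."""
    if isinstance(source, str):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")

    errors = _reject_unknown(raw, _TOP_KEYS, "top level")
    cfg = PipelineConfig()
    for key in ("scenario", "out_dir", "log_level"):
        if key in raw:
            if not isinstance(raw[key], str):
                errors.append(f"{key}: expected a string")
            else:
                setattr(cfg, key, raw[key])
    if "seed" in raw:
        if not isinstance(raw["seed"], int) or isinstance(raw["seed"], bool):
            errors.append("seed: expected an integer")
        else:
            cfg.seed = raw["seed"]

    for section, typ in _SECTION_TYPES.items():
        given = raw.get(section) or {}
        if not isinstance(given, dict):
            errors.append(f"{section}: expected a mapping")
            continue
        if typ is dict:
            errors += _reject_unknown(given, _SIMULATE_KEYS, section)
            cfg.simulate = {k: v for k, v in given.items() if k in _SIMULATE_KEYS}
            continue
        allowed = {f.name for f in dataclasses.fields(typ)} - {"karyotype_whitelist"}
        errors += _reject_unknown(given, allowed, section)
        try:
            setattr(
                cfg, section, typ(**{k: v for k, v in given.items() if k in allowed})
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"{section}: {exc}")

    if cfg.scenario and cfg.seed is None:
        errors.append("seed: mandatory for simulation runs")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def phase_candidate(
    candidate: svscan.SVCandidate,
    sam_path: str,
    reference: dict[str, bytes],
    cfg: PhaseConfig,
    read_whitelist: set[str] | None = None,
) -> phaser.PhasedHaplotype:
    """Het calling + seed + extend + side assessment for one retained SV."""
    snps: list[phaser.HetSNP] = []
    regions: dict[str, list[int]] = {}
    for chrom, pos in (candidate.breakpointA, candidate.breakpointB):
        regions.setdefault(chrom, []).append(pos)
    for chrom, positions in regions.items():
        lo = max(1, min(positions) - cfg.window_bp)
        hi = min(len(reference[chrom]), max(positions) + cfg.window_bp)
        stream = (
            r
            for r in svscan.read_sam(sam_path)
            if read_whitelist is None or r.query_name in read_whitelist
        )
        snps += phaser.call_het_snps(stream, (chrom, lo, hi), reference[chrom], cfg)
    phased = phaser.seed_phase(candidate, snps, cfg)
    phaser.extend_phase(phased)
    phaser.assess_sides(phased, cfg)
    return phased


def usable_ranges_from_sides(phased: phaser.PhasedHaplotype) -> list[tuple[str, int, int]]:
    ranges = []
    for (end, side), (usable, _n) in phased.side_flags.items():
        if not usable:
            continue
        chrom, bp = phased.endA if end == "A" else phased.endB
        if side == "upstream":
            ranges.append((chrom, bp - phased.window_bp, bp - 1))
        else:
            ranges.append((chrom, bp + 1, bp + phased.window_bp))
    return ranges


def _load_reference(path: str) -> dict[str, bytes]:
    ref = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    ref[name] = "".join(chunks).upper().encode()
                name, chunks = line[1:].split()[0], []
            else:
                chunks.append(line)
    if name is not None:
        ref[name] = "".join(chunks).upper().encode()
    return ref


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig | str | dict) -> dict:
    """Execute all stages in order on the configured scenario; returns the run
    report (also written as JSON + a human-readable summary). Deterministic for
    a fixed config and seed."""
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict = {
        "tool": "marecs-kit",
        "version": __version__,
        "seed": cfg.seed,
        "scenario": cfg.scenario,
        "config": {
            "simulate": cfg.simulate,
            "qc": dataclasses.asdict(cfg.qc),
            "detect": dataclasses.asdict(cfg.detect),
            "phase": dataclasses.asdict(cfg.phase),
            "cnv": dataclasses.asdict(cfg.cnv),
            "linkage": dataclasses.asdict(cfg.linkage),
        },
        "stages": {},
    }

    # --- simulate -----------------------------------------------------------
    log.info("[simulate] building scenario %s (seed %s)", cfg.scenario, cfg.seed)
    if cfg.scenario != "pedigree1":
        raise ConfigError(f"unknown scenario {cfg.scenario!r} (available: pedigree1)")
    sim_dir = os.path.join(cfg.out_dir, "sim")
    run = scenarios.pedigree1(cfg.seed, sim_dir, **cfg.simulate)
    report["stages"]["simulate"] = {
        "outputs": dict(run.paths),
        "n_het_sites": len(run.genome.het_sites),
        "planted_sv": dataclasses.asdict(run.sv),
    }

    # --- read QC -------------------------------------------------------------
    log.info("[qc] filtering reads")
    qc_fastq = os.path.join(cfg.out_dir, "reads.qc.fastq")
    kept = svscan.qc_reads(run.paths["fastq"], qc_fastq, cfg.qc)
    report["stages"]["qc"] = {"kept_reads": len(kept), "output": qc_fastq}

    # --- SV detection --------------------------------------------------------
    log.info("[detect] scanning split alignments")
    candidates, retained, reasons = svscan.detect(
        run.paths["sam"], cfg.detect, cfg.detect_position_tol, cfg.detect_dr_margin,
        read_whitelist=kept,
    )
    sv_vcf = os.path.join(cfg.out_dir, "svs.vcf")
    rej_tsv = os.path.join(cfg.out_dir, "sv_rejections.tsv")
    svscan.write_sv_vcf(retained, run.genome.ref_lengths, sv_vcf)
    svscan.write_rejection_tsv(candidates, reasons, rej_tsv)
    report["stages"]["detect"] = {
        "candidates": len(candidates),
        "retained": [
            {
                "sv_type": c.sv_type,
                "chromA": c.breakpointA[0], "posA": c.breakpointA[1],
                "chromB": c.breakpointB[0], "posB": c.breakpointB[1],
                "DV": c.dv, "DR": c.dr, "length": c.length,
            }
            for c in retained
        ],
        "vcf": sv_vcf,
        "rejections": rej_tsv,
    }
    if not retained:
        raise RuntimeError("detect stage retained no SV; cannot phase")

    # --- phasing -------------------------------------------------------------
    log.info("[phase] building breakpoint haplotypes")
    target = retained[0]
    reference = _load_reference(run.paths["reference"])
    phased = phase_candidate(target, run.paths["sam"], reference, cfg.phase, kept)
    phased_vcf = os.path.join(cfg.out_dir, "phased.vcf")
    sides_tsv = os.path.join(cfg.out_dir, "phase_sides.tsv")
    phaser.write_phased_vcf(phased, run.genome.ref_lengths, phased_vcf)
    phaser.write_sides_tsv(phased, sides_tsv)
    report["stages"]["phase"] = {
        "breakpoint_id": phased.breakpoint_id,
        "assigned_snps": len(phased.assignments),
        "sides": {
            f"{end}_{side}": {"usable": usable, "snps": n}
            for (end, side), (usable, n) in sorted(phased.side_flags.items())
        },
        "vcf": phased_vcf,
    }

    # --- liftover ------------------------------------------------------------
    log.info("[liftover] converting phased haplotypes to array coordinates")
    cmap = read_chain(run.paths["chain"])
    lifted_vcf = os.path.join(cfg.out_dir, "phased.array.vcf")
    drops_tsv = os.path.join(cfg.out_dir, "liftover_drops.tsv")
    n_lifted, n_dropped = lift_haplotype(cmap, phased_vcf, lifted_vcf, drops_tsv)
    bp_chrom, bp_pos = target.breakpointB  # arm-side anchor
    lifted_bp = lift_position(cmap, bp_chrom, bp_pos)
    if not lifted_bp.mapped:
        raise RuntimeError(f"anchor breakpoint {bp_chrom}:{bp_pos} unmappable: {lifted_bp.reason}")
    report["stages"]["liftover"] = {
        "lifted": n_lifted,
        "dropped": n_dropped,
        "anchor_breakpoint": {
            "source": f"{bp_chrom}:{bp_pos}",
            "array": f"{lifted_bp.chrom}:{lifted_bp.pos}",
        },
        "vcf": lifted_vcf,
    }

    # --- CNV screen ----------------------------------------------------------
    log.info("[cnv] screening chromosomal copy numbers")
    counts = cnvcall.read_bincounts_tsv(run.paths["bins"])
    screen = cnvcall.screen_embryos(counts, cfg.cnv)
    karyotypes = {e: k for e, (k, _s, _r) in screen.items()}
    kary_tsv = os.path.join(cfg.out_dir, "karyotypes.tsv")
    with open(kary_tsv, "w") as fh:
        fh.write("embryo\tkaryotype\n")
        for e in sorted(karyotypes):
            fh.write(f"{e}\t{karyotypes[e]}\n")
    report["stages"]["cnv"] = {"karyotypes": karyotypes, "tsv": kary_tsv}

    # --- linkage -------------------------------------------------------------
    log.info("[linkage] HMM haplotype linkage on euploid embryos")
    usable_src = usable_ranges_from_sides(phased)
    usable_array = []
    for chrom, lo, hi in usable_src:
        a = lift_position(cmap, chrom, max(1, lo))
        b = lift_position(cmap, chrom, hi)
        if a.mapped and b.mapped:
            usable_array.append((a.chrom, a.pos, b.pos))
    other = linkhmm.read_genotype_tsv(run.paths["other_parent"])
    other_array = {}
    for (chrom, pos), gt in other.items():
        res = lift_position(cmap, chrom, pos)
        if res.mapped:
            other_array[(res.chrom, res.pos)] = gt
    parental = linkhmm.read_parental_vcf(
        lifted_vcf,
        breakpoint=(lifted_bp.chrom, lifted_bp.pos),
        other_parent=other_array,
        usable_ranges=usable_array,
    )
    embryos = linkhmm.read_embryo_tsv(run.paths["embryos"])
    euploid = {e for e, k in karyotypes.items() if k == "46,XN"}
    results = []
    decisions = {}
    for embryo in sorted(embryos, key=lambda e: e.embryo_id):
        if embryo.embryo_id not in euploid:
            decisions[embryo.embryo_id] = "excluded (aneuploid)"
            continue
        res = linkhmm.analyze_embryo(parental, embryo, cfg.linkage)
        results.append(res)
        decisions[embryo.embryo_id] = res.decision
    linkage_json = os.path.join(cfg.out_dir, "linkage.json")
    ribbon_txt = os.path.join(cfg.out_dir, "haplotype_ribbon.txt")
    linkhmm.write_linkage_report(results, linkage_json)
    with open(ribbon_txt, "w") as fh:
        fh.write(linkhmm.format_ribbon(parental, results, max_rows=60) + "\n")
    report["stages"]["linkage"] = {
        "decisions": decisions,
        "informative_snps": {r.embryo_id: r.informative_count for r in results},
        "report": linkage_json,
        "ribbon": ribbon_txt,
    }

    # --- report --------------------------------------------------------------
    report_path = os.path.join(cfg.out_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    summary_path = os.path.join(cfg.out_dir, "summary.txt")
    with open(summary_path, "w") as fh:
        fh.write(format_summary(report))
    report["report_path"] = report_path
    return report


def format_summary(report: dict) -> str:
    lines = [
        f"marecs-kit {report['version']} — scenario {report['scenario']} (seed {report['seed']})",
        "",
        "Retained structural variants:",
    ]
    for sv in report["stages"]["detect"]["retained"]:
        lines.append(
            f"  {sv['sv_type']} {sv['chromA']}:{sv['posA']} — {sv['chromB']}:{sv['posB']}"
            f"  DV={sv['DV']} DR={sv['DR']} len={sv['length']}"
        )
    lines.append("")
    lines.append("Breakpoint sides:")
    for side, info in report["stages"]["phase"]["sides"].items():
        lines.append(
            f"  {side}: {'usable' if info['usable'] else 'unusable'} ({info['snps']} phased SNPs)"
        )
    lines.append("")
    lines.append("Embryos:")
    cnv = report["stages"]["cnv"]["karyotypes"]
    link = report["stages"]["linkage"]["decisions"]
    for e in sorted(cnv):
        lines.append(f"  {e}: CNV {cnv[e]}; linkage {link.get(e, '-')}")
    return "\n".join(lines) + "\n"
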