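"""Stage-two linkage: infer which carrier-parent haplotype an embryo inherited
around the rearrangement breakpoint, from sparse noisy array genotypes, with a
two-state hidden Markov model.

States are H1 (the rearrangement-linked haplotype was transmitted) and H2 (its
homolog). Transitions between adjacent informative SNPs follow the Haldane map,
switch probability 0.5*(1 - exp(-2*r*d)) for genetic distance r*d Morgans.
Emissions model allele drop-out (one allele lost with probability `ado`, the
survivor read as homozygous) followed by independent per-allele genotyping
errors. Forward-backward posteriors and the Viterbi path are computed in log
space. The carrier call is anchored at the SNP nearest the breakpoint, because
linkage to the breakpoint — not the window consensus — is the clinical question.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pysam

NEG_INF = float("-inf")


@dataclass
class HMMParams:
    r_per_mb: float = 0.01  # Morgans per Mb (1 cM/Mb)
    ado: float = 0.1
    error: float = 0.01
    prior_h1: float = 0.5
    threshold: float = 0.95
    min_informative: int = 10
    hemizygous: bool = False

    def __post_init__(self):
        if not (0 <= self.ado < 1 and 0 <= self.error < 1):
            raise ValueError("ado and error must be in [0, 1)")
        if self.r_per_mb < 0:
            raise ValueError("r_per_mb must be >= 0")
        if not 0.5 < self.threshold <= 1:
            raise ValueError("threshold must be in (0.5, 1]")


@dataclass
class ParentalSNP:
    chrom: str
    pos: int
    hap1: str  # rearrangement-linked allele
    hap2: str
    other_parent: tuple[str, str] | None = None
    side_usable: bool = True

    @property
    def alleles(self) -> tuple[str, str]:
        return tuple(sorted({self.hap1, self.hap2}))


@dataclass
class ParentalHaplotypes:
    snps: list[ParentalSNP]
    breakpoint: tuple[str, int]


@dataclass
class EmbryoGenotypes:
    embryo_id: str
    calls: dict[tuple[str, int], tuple[str, str] | None]


@dataclass
class LinkageResult:
    embryo_id: str
    positions: list[int]
    posteriors: np.ndarray  # (n, 2): P(H1), P(H2) per SNP
    viterbi: list[int]  # 0 = H1, 1 = H2
    informative_count: int
    breakpoint_posterior_h1: float | None = None
    decision: str | None = None  # carrier | non-carrier | no-call


# ---------------------------------------------------------------------------
# informative-SNP selection
# ---------------------------------------------------------------------------

def select_informative_snps(
    parental: ParentalHaplotypes, embryo: EmbryoGenotypes
) -> list[tuple[ParentalSNP, tuple[str, str]]]:
    """Sites where the transmitted carrier-parent allele is identifiable:
    carrier parent heterozygous and phased, side usable, other parent homozygous
    and known, embryo genotype present. Sorted by position."""
    chosen = []
    for snp in sorted(parental.snps, key=lambda s: (s.chrom, s.pos)):
        if snp.hap1 == snp.hap2:
            continue
        if not snp.side_usable:
            continue
        if snp.other_parent is None or snp.other_parent[0] != snp.other_parent[1]:
            continue
        obs = embryo.calls.get((snp.chrom, snp.pos))
        if obs is None:
            continue
        chosen.append((snp, obs))
    return chosen


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

def _flip(allele: str, site_alleles: tuple[str, str], e: float, target: str) -> float:
    """P(reported = target | true = allele) under a flip to the site's other allele."""
    if allele == target:
        return 1 - e
    other = site_alleles[1] if allele == site_alleles[0] else site_alleles[0]
    return e if target == other else 0.0


def emission_probability(
    observed: tuple[str, str] | None,
    state: int,
    snp: ParentalSNP,
    params: HMMParams,
) -> float:
    """P(observed genotype | hidden state) by summing over the drop/flip event
    space. `observed` is an unordered allele pair; state 0 = H1, 1 = H2.

    With transmitted allele t and other-parent allele o, the true genotype is
    {t, o}; ADO drops one uniformly chosen allele (prob `ado`), then each
    reported allele independently flips to the site's other allele (prob
    `error`). In hemizygous mode a single allele t is transmitted and reported
    as a homozygous call."""
    if observed is None:
        return 1.0  # missing genotypes carry no emission
    t = snp.hap1 if state == 0 else snp.hap2
    site = (snp.hap1, snp.hap2) if snp.hap1 != snp.hap2 else snp.alleles
    e = params.error

    if params.hemizygous:
        if observed[0] != observed[1]:
            return 0.0
        return _flip(t, site, e, observed[0])

    o = snp.other_parent[0] if snp.other_parent else None
    if o is None:
        raise ValueError("emission needs the other parent's (homozygous) allele")

    def pair_prob(slots: tuple[str, str], prob: float) -> float:
        u, v = slots
        p, q = observed
        if p == q:
            return prob * _flip(u, site, e, p) * _flip(v, site, e, p)
        return prob * (
            _flip(u, site, e, p) * _flip(v, site, e, q)
            + _flip(u, site, e, q) * _flip(v, site, e, p)
        )

    a = params.ado
    total = pair_prob((t, o), 1 - a)  # no drop-out
    total += pair_prob((o, o), a / 2)  # t dropped, o read as hom
    total += pair_prob((t, t), a / 2)  # o dropped, t read as hom
    return total


# ---------------------------------------------------------------------------
# HMM core
# ---------------------------------------------------------------------------

def _switch_probability(d_bp: int, r_per_mb: float) -> float:
    """Haldane map: switch = 0.5*(1 - exp(-2*r*d)), d in Mb, capped at 0.5."""
    d_mb = abs(d_bp) / 1e6
    return min(0.5, 0.5 * (1.0 - math.exp(-2.0 * r_per_mb * d_mb)))


def _log(x: float) -> float:
    return math.log(x) if x > 0 else NEG_INF


def run_linkage_hmm(
    sites: list[tuple[ParentalSNP, tuple[str, str]]],
    params: HMMParams,
    embryo_id: str = "",
) -> LinkageResult:
    """Forward-backward posteriors and Viterbi path over {H1, H2}.

    All arithmetic is in log space, so cohort-scale inputs (>= 1e4 SNPs) cannot
    underflow. Posteriors at each SNP sum to one."""
    n = len(sites)
    if n == 0:
        return LinkageResult(embryo_id, [], np.zeros((0, 2)), [], 0)
    positions = [snp.pos for snp, _obs in sites]
    log_emit = np.empty((n, 2))
    for i, (snp, obs) in enumerate(sites):
        for s in (0, 1):
            log_emit[i, s] = _log(emission_probability(obs, s, snp, params))

    log_trans = np.empty((n - 1, 2, 2))
    for i in range(n - 1):
        sw = _switch_probability(positions[i + 1] - positions[i], params.r_per_mb)
        sw = max(sw, 1e-12)  # keep the chain ergodic at zero distance
        log_trans[i] = [[_log(1 - sw), _log(sw)], [_log(sw), _log(1 - sw)]]

    log_prior = np.array([_log(params.prior_h1), _log(1 - params.prior_h1)])

    # forward
    fwd = np.empty((n, 2))
    fwd[0] = log_prior + log_emit[0]
    for i in range(1, n):
        for s in (0, 1):
            fwd[i, s] = np.logaddexp(
                fwd[i - 1, 0] + log_trans[i - 1, 0, s], fwd[i - 1, 1] + log_trans[i - 1, 1, s]
            ) + log_emit[i, s]
    # backward
    bwd = np.zeros((n, 2))
    for i in range(n - 2, -1, -1):
        for s in (0, 1):
            bwd[i, s] = np.logaddexp(
                log_trans[i, s, 0] + log_emit[i + 1, 0] + bwd[i + 1, 0],
                log_trans[i, s, 1] + log_emit[i + 1, 1] + bwd[i + 1, 1],
            )
    log_post = fwd + bwd
    log_post -= np.logaddexp(log_post[:, 0], log_post[:, 1])[:, None]
    posteriors = np.exp(log_post)

    # Viterbi
    vit = np.empty((n, 2))
    ptr = np.zeros((n, 2), dtype=int)
    vit[0] = log_prior + log_emit[0]
    for i in range(1, n):
        for s in (0, 1):
            scores = [vit[i - 1, 0] + log_trans[i - 1, 0, s], vit[i - 1, 1] + log_trans[i - 1, 1, s]]
            ptr[i, s] = int(np.argmax(scores))
            vit[i, s] = scores[ptr[i, s]] + log_emit[i, s]
    path = [int(np.argmax(vit[-1]))]
    for i in range(n - 1, 0, -1):
        path.append(int(ptr[i, path[-1]]))
    path.reverse()

    return LinkageResult(embryo_id, positions, posteriors, path, n)


def call_carrier_status(
    result: LinkageResult, params: HMMParams, breakpoint_pos: int
) -> LinkageResult:
    """Carrier iff P(H1) at the SNP nearest the breakpoint >= threshold;
    non-carrier iff P(H2) >= threshold; otherwise no-call. Any embryo with
    fewer than min_informative SNPs is a no-call regardless."""
    if result.informative_count < params.min_informative:
        result.decision = "no-call"
        return result
    nearest = int(np.argmin([abs(p - breakpoint_pos) for p in result.positions]))
    p_h1 = float(result.posteriors[nearest, 0])
    result.breakpoint_posterior_h1 = p_h1
    if p_h1 >= params.threshold:
        result.decision = "carrier"
    elif 1 - p_h1 >= params.threshold:
        result.decision = "non-carrier"
    else:
        result.decision = "no-call"
    return result


def analyze_embryo(
    parental: ParentalHaplotypes, embryo: EmbryoGenotypes, params: HMMParams | None = None
) -> LinkageResult:
    params = params or HMMParams()
    sites = select_informative_snps(parental, embryo)
    result = run_linkage_hmm(sites, params, embryo.embryo_id)
    return call_carrier_status(result, params, parental.breakpoint[1])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_parental_vcf(
    path: str,
    breakpoint: tuple[str, int],
    other_parent: dict[tuple[str, int], tuple[str, str]] | str | None = None,
    usable_ranges: list[tuple[str, int, int]] | None = None,
    sample: str | None = None,
) -> ParentalHaplotypes:
    """Carrier-parent haplotypes from a phased VCF (hap1 allele written first).

    `other_parent` maps (chrom, pos) to the other parent's genotype, or names a
    TSV (chrom, pos, allele1, allele2); sites absent from it are treated as
    unknown and excluded by select_informative_snps. Unphased records are kept
    with hap1 == hap2 == '' so they are filtered as uninformative.
    `usable_ranges` restricts side usability to the given (chrom, lo, hi)."""
    if isinstance(other_parent, str):
        other_parent = read_genotype_tsv(other_parent)
    snps = []
    with pysam.VariantFile(path) as vcf:
        name = sample or list(vcf.header.samples)[0]
        for rec in vcf:
            call = rec.samples[name]
            gt = call["GT"]
            if gt is None or None in gt:
                continue
            alleles = rec.alleles
            if not call.phased:
                snps.append(ParentalSNP(rec.chrom, rec.pos, "", "", None, False))
                continue
            hap1, hap2 = alleles[gt[0]], alleles[gt[1]]
            usable = True
            if usable_ranges is not None:
                usable = any(
                    c == rec.chrom and lo <= rec.pos <= hi for c, lo, hi in usable_ranges
                )
            op = other_parent.get((rec.chrom, rec.pos)) if other_parent else None
            snps.append(ParentalSNP(rec.chrom, rec.pos, hap1, hap2, op, usable))
    return ParentalHaplotypes(snps, breakpoint)


def read_genotype_tsv(path: str) -> dict[tuple[str, int], tuple[str, str]]:
    out: dict[tuple[str, int], tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ci = {k: i for i, k in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out[(f[ci["chrom"]], int(f[ci["pos"]]))] = (f[ci["allele1"]], f[ci["allele2"]])
    return out


def read_embryo_tsv(path: str) -> list[EmbryoGenotypes]:
    """Embryo genotype table: embryo, chrom, pos, allele1, allele2 ('.' = no-call)."""
    embryos: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ci = {k: i for i, k in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            eid = f[ci["embryo"]]
            key = (f[ci["chrom"]], int(f[ci["pos"]]))
            a1, a2 = f[ci["allele1"]], f[ci["allele2"]]
            call = None if a1 == "." or a2 == "." else tuple(sorted((a1, a2)))
            embryos.setdefault(eid, {})[key] = call
    return [EmbryoGenotypes(eid, calls) for eid, calls in embryos.items()]


def format_ribbon(
    parental: ParentalHaplotypes,
    results: list[LinkageResult],
    max_rows: int | None = None,
) -> str:
    """Plain-text haplotype ribbon: one row per informative SNP position, one
    column per embryo, cells hap1/hap2 from the Viterbi path ('.' where the
    embryo lacks that SNP)."""
    all_pos = sorted({p for r in results for p in r.positions})
    if max_rows:
        all_pos = all_pos[:max_rows]
    per_embryo = {r.embryo_id: dict(zip(r.positions, r.viterbi)) for r in results}
    ids = [r.embryo_id for r in results]
    width = max([8] + [len(i) for i in ids]) + 1
    bp_chrom, bp_pos = parental.breakpoint
    lines = [f"breakpoint {bp_chrom}:{bp_pos}"]
    lines.append("position".ljust(12) + "".join(i.rjust(width) for i in ids))
    for pos in all_pos:
        cells = []
        for eid in ids:
            s = per_embryo[eid].get(pos)
            cells.append(("." if s is None else f"hap{s + 1}").rjust(width))
        lines.append(f"{pos:<12d}" + "".join(cells))
    return "\n".join(lines)


def write_linkage_report(results: list[LinkageResult], path: str) -> str:
    import json

    payload = [
        {
            "embryo": r.embryo_id,
            "decision": r.decision,
            "informative_snps": r.informative_count,
            "breakpoint_posterior_h1": r.breakpoint_posterior_h1,
            "positions": r.positions,
            "posterior_h1": [float(p) for p in r.posteriors[:, 0]],
            "viterbi": r.viterbi,
        }
        for r in results
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return path
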