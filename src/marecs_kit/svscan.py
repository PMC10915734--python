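"""Structural-variant scanning from split long-read alignments.

Read QC (trim, mean-quality and length cutoffs), breakend signature extraction
from primary + supplementary alignment pairs, clustering into candidates with
DV (variant-supporting) / DR (reference-spanning) read counts, single-base
breakpoint refinement by lower-median, and the three retention filters:
DV > 4, DV/(DV+DR) > 10%, and the >5 Mb karyotype-whitelist gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

from .utils import mean_phred

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# read QC
# ---------------------------------------------------------------------------

@dataclass
class QCConfig:
    min_mean_q: float = 7.0  # exclusive: mean Phred <= 7 removed
    min_length_bp: int = 1000  # exclusive lower bound after trimming
    trim_head_bp: int = 50
    trim_tail_bp: int = 50

    def __post_init__(self):
        for name in ("min_mean_q", "min_length_bp", "trim_head_bp", "trim_tail_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class MalformedRecordError(ValueError):
    pass


def qc_records(records, cfg: QCConfig):
    """Filter an iterable of (name, seq, qual) FASTQ records.

    Each read is first trimmed trim_head + trim_tail bases, then dropped if its
    mean Phred is <= min_mean_q or its trimmed length is < min_length_bp.
    Order is preserved. Yields trimmed records."""
    for name, seq, qual in records:
        if len(seq) != len(qual):
            raise MalformedRecordError(
                f"read {name!r}: sequence length {len(seq)} != quality length {len(qual)}"
            )
        end = len(seq) - cfg.trim_tail_bp
        seq_t = seq[cfg.trim_head_bp : end] if end > cfg.trim_head_bp else ""
        qual_t = qual[cfg.trim_head_bp : end] if end > cfg.trim_head_bp else ""
        if len(seq_t) < cfg.min_length_bp:
            continue
        if mean_phred(qual_t) <= cfg.min_mean_q:
            continue
        yield name, seq_t, qual_t


def iter_fastq(path: str):
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            yield entry.name, entry.sequence, entry.quality or ""


def qc_reads(fastq_in: str, fastq_out: str, cfg: QCConfig | None = None) -> set[str]:
    """File-level QC; writes the surviving trimmed reads and returns their names."""
    cfg = cfg or QCConfig()
    kept: set[str] = set()
    with open(fastq_out, "w") as out:
        for name, seq, qual in qc_records(iter_fastq(fastq_in), cfg):
            out.write(f"@{name}\n{seq}\n+\n{qual}\n")
            kept.add(name)
    return kept


# ---------------------------------------------------------------------------
# alignment digest
# ---------------------------------------------------------------------------

@dataclass
class AlnSeg:
    """One alignment segment of a read, in reference and read coordinates.

    rstart/rend are 1-based inclusive reference coordinates; qstart/qend are
    0-based half-open coordinates in the read's own (sequencing) orientation."""

    chrom: str
    rstart: int
    rend: int
    strand: str
    qstart: int
    qend: int


def digest_alignments(alignments, read_whitelist: set[str] | None = None):
    """Compact per-read alignment segments from pysam records.

    Returns {read_id: [AlnSeg sorted by read position]}. Secondary and unmapped
    records are ignored; supplementaries whose primary never appears are kept as
    single-segment reads (they cannot form a junction and are logged)."""
    reads: dict[str, list[AlnSeg]] = {}
    seen_primary: set[str] = set()
    for rec in alignments:
        if rec.is_unmapped or rec.is_secondary:
            continue
        if read_whitelist is not None and rec.query_name not in read_whitelist:
            continue
        qlen = rec.infer_read_length()
        if qlen is None:
            continue
        qs = rec.query_alignment_start
        qe = rec.query_alignment_end
        if rec.is_reverse:
            qs, qe = qlen - rec.query_alignment_end, qlen - rec.query_alignment_start
        seg = AlnSeg(
            chrom=rec.reference_name,
            rstart=rec.reference_start + 1,
            rend=rec.reference_end,
            strand="-" if rec.is_reverse else "+",
            qstart=qs,
            qend=qe,
        )
        reads.setdefault(rec.query_name, []).append(seg)
        if not rec.is_supplementary:
            seen_primary.add(rec.query_name)
    for rid, segs in reads.items():
        segs.sort(key=lambda s: s.qstart)
        if rid not in seen_primary and len(segs) > 1:
            log.warning("read %s has supplementary alignments but no primary", rid)
    return reads


def read_sam(path: str):
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        yield from fh


# ---------------------------------------------------------------------------
# breakend signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreakendSignature:
    read_id: str
    sv_type: str  # INV | TRA | DEL | DUP
    endA: tuple[str, int, str]  # (chrom, pos, orientation)
    endB: tuple[str, int, str]


def _junction(segA: AlnSeg, segB: AlnSeg) -> BreakendSignature | None:
    """Classify the novel adjacency between two read-consecutive segments.

    Positions are normalized so that, on error-free simulated data, the reported
    pair equals the planted (posA, posB) of the generator's conventions: the
    rearranged interval is [posA, posB) for INV/DEL/DUP, and TRA reports the
    first retained base of each swapped tail."""
    # reference coordinate of the aligned base adjacent to the junction
    pa = segA.rend if segA.strand == "+" else segA.rstart
    pb = segB.rstart if segB.strand == "+" else segB.rend

    if segA.chrom != segB.chrom:
        a = pa + 1 if segA.strand == "+" else pa - 1
        b = pb  # first aligned base of the joined tail
        endA = (segA.chrom, a, segA.strand)
        endB = (segB.chrom, b, segB.strand)
        ends = sorted((endA, endB), key=lambda e: (e[0], e[1]))
        return BreakendSignature("", "TRA", ends[0], ends[1])

    if segA.strand != segB.strand:
        if segA.strand == "+":  # (+,-): head-head junction
            a, b = pa + 1, pb + 1
        else:  # (-,+): tail-tail junction
            a, b = pa, pb
        lo, hi = sorted((a, b))
        return BreakendSignature(
            "", "INV", (segA.chrom, lo, segA.strand), (segA.chrom, hi, segB.strand)
        )

    # same chromosome, same strand: deletion (gap) or tandem duplication (overlap)
    if segA.strand == "+":
        gap_start, gap_end = pa + 1, pb  # first missing .. first aligned of B
    else:
        gap_start, gap_end = pb + 1, pa
    if gap_end > gap_start:
        return BreakendSignature(
            "", "DEL", (segA.chrom, gap_start, "+"), (segA.chrom, gap_end, "+")
        )
    if gap_end < gap_start:
        dup_lo, dup_hi = gap_end, gap_start  # duplicated interval [lo, hi)
        return BreakendSignature(
            "", "DUP", (segA.chrom, dup_lo, "+"), (segA.chrom, dup_hi, "+")
        )
    return None  # contiguous: no rearrangement (insertions are out of scope)


def extract_signatures(alignments) -> list[BreakendSignature]:
    """One breakend signature per primary/supplementary split pair.

    `alignments` may be pysam records or a digest from digest_alignments()."""
    reads = alignments if isinstance(alignments, dict) else digest_alignments(alignments)
    sigs: list[BreakendSignature] = []
    for rid, segs in reads.items():
        for a, b in zip(segs, segs[1:]):
            sig = _junction(a, b)
            if sig is not None:
                sigs.append(
                    BreakendSignature(rid, sig.sv_type, sig.endA, sig.endB)
                )
    return sigs


# ---------------------------------------------------------------------------
# candidates
# ---------------------------------------------------------------------------

@dataclass
class SVCandidate:
    sv_type: str
    breakpointA: tuple[str, int]
    breakpointB: tuple[str, int]
    dv: int
    dr: int = 0
    supporting_reads: set[str] = field(default_factory=set)
    signatures: list[BreakendSignature] = field(default_factory=list)
    heterochromatic: tuple[bool, bool] = (False, False)

    @property
    def length(self) -> int | None:
        """|posB - posA| for intra-chromosomal events; None for breakends."""
        if self.breakpointA[0] != self.breakpointB[0]:
            return None
        return abs(self.breakpointB[1] - self.breakpointA[1])

    @property
    def fraction(self) -> float:
        return self.dv / (self.dv + self.dr) if self.dv + self.dr else 0.0


def _lower_median(values) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def cluster_signatures(
    signatures: list[BreakendSignature], position_tol: int = 50
) -> list[SVCandidate]:
    """Single-linkage merge of same-type signatures whose both ends lie within
    `position_tol`; DV = cluster size; provisional breakpoints = per-end lower
    medians."""
    if position_tol < 0:
        raise ValueError("position_tol must be >= 0")
    by_key: dict[tuple, list[BreakendSignature]] = {}
    for sig in signatures:
        by_key.setdefault((sig.sv_type, sig.endA[0], sig.endB[0]), []).append(sig)

    candidates = []
    for sigs in by_key.values():
        n = len(sigs)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if (
                    abs(sigs[i].endA[1] - sigs[j].endA[1]) <= position_tol
                    and abs(sigs[i].endB[1] - sigs[j].endB[1]) <= position_tol
                ):
                    parent[find(i)] = find(j)
        groups: dict[int, list[BreakendSignature]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(sigs[i])
        for members in groups.values():
            reads = {m.read_id for m in members}
            candidates.append(
                SVCandidate(
                    sv_type=members[0].sv_type,
                    breakpointA=(members[0].endA[0], _lower_median(m.endA[1] for m in members)),
                    breakpointB=(members[0].endB[0], _lower_median(m.endB[1] for m in members)),
                    dv=len(reads),
                    supporting_reads=reads,
                    signatures=members,
                )
            )
    candidates.sort(key=lambda c: (c.breakpointA[0], c.breakpointA[1]))
    return candidates


def compute_reference_support(
    candidate: SVCandidate, alignments, margin: int = 200
) -> SVCandidate:
    """DR = reads (outside the supporting set) with one alignment segment
    contiguously spanning breakpointA +/- margin or breakpointB +/- margin.
    Each read counts once; a read that is both split and spanning stays in DV."""
    reads = alignments if isinstance(alignments, dict) else digest_alignments(alignments)
    dr = 0
    for rid, segs in reads.items():
        if rid in candidate.supporting_reads:
            continue
        spans = False
        for chrom, pos in (candidate.breakpointA, candidate.breakpointB):
            for s in segs:
                if s.chrom == chrom and s.rstart <= pos - margin and s.rend >= pos + margin:
                    spans = True
                    break
            if spans:
                break
        if spans:
            dr += 1
    candidate.dr = dr
    return candidate


def refine_breakpoint(candidate: SVCandidate, signatures=None) -> SVCandidate:
    """Single-base breakpoints as the lower median of member-signature junction
    coordinates; exact on error-free simulated reads."""
    sigs = signatures if signatures is not None else candidate.signatures
    if not sigs:
        raise ValueError("refinement requires at least one supporting signature")
    candidate.breakpointA = (candidate.breakpointA[0], _lower_median(s.endA[1] for s in sigs))
    candidate.breakpointB = (candidate.breakpointB[0], _lower_median(s.endB[1] for s in sigs))
    return candidate


# ---------------------------------------------------------------------------
# retention filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WhitelistEntry:
    """A karyotype-confirmed event: chromosome, approximate region, SV type."""

    chrom: str
    start: int
    end: int
    sv_type: str


@dataclass
class FilterConfig:
    min_dv: int = 4  # exclusive: retain DV > 4
    min_fraction: float = 0.10  # exclusive: retain DV/(DV+DR) > 0.10
    large_sv_mb: float = 5.0
    karyotype_whitelist: list[WhitelistEntry] = field(default_factory=list)
    whitelist_slop: int = 1_000_000  # karyotype-band imprecision

    def __post_init__(self):
        if self.min_dv < 0 or self.large_sv_mb < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 <= self.min_fraction <= 1:
            raise ValueError("min_fraction must be in [0, 1]")


def _matches_whitelist(c: SVCandidate, cfg: FilterConfig) -> bool:
    for w in cfg.karyotype_whitelist:
        if w.sv_type != c.sv_type:
            continue
        lo, hi = w.start - cfg.whitelist_slop, w.end + cfg.whitelist_slop
        for chrom, pos in (c.breakpointA, c.breakpointB):
            if chrom == w.chrom and lo <= pos <= hi:
                return True
    return False


def filter_svs(candidates: list[SVCandidate], cfg: FilterConfig | None = None):
    """Apply the retention rules; returns (retained, {candidate index: reasons}).

    Retain iff DV > min_dv AND DV/(DV+DR) > min_fraction AND (length <=
    large_sv_mb Mb, or the candidate matches a karyotype whitelist entry by
    chromosome, SV type and region overlap). Inter-chromosomal breakends have
    no length, so the size rule does not apply to them."""
    cfg = cfg or FilterConfig()
    retained = []
    reasons: dict[int, list[str]] = {}
    for i, c in enumerate(candidates):
        failed = []
        if not c.dv > cfg.min_dv:
            failed.append(f"DV={c.dv} not > {cfg.min_dv}")
        if not c.fraction > cfg.min_fraction:
            failed.append(f"DV/(DV+DR)={c.fraction:.3f} not > {cfg.min_fraction:.2f}")
        if (
            c.length is not None
            and c.length > cfg.large_sv_mb * 1e6
            and not _matches_whitelist(c, cfg)
        ):
            failed.append(
                f"length {c.length / 1e6:.2f} Mb > {cfg.large_sv_mb} Mb without karyotype support"
            )
        if failed:
            reasons[i] = failed
        else:
            retained.append(c)
    return retained, reasons


# ---------------------------------------------------------------------------
# VCF / report output
# ---------------------------------------------------------------------------

def write_sv_vcf(candidates: list[SVCandidate], contigs: dict[str, int], path: str) -> str:
    """VCF 4.2 with symbolic INV/DEL/DUP records and BND pairs for TRA; INFO
    carries SVTYPE, END, SVLEN, DV, DR."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=DV,Number=1,Type=Integer,Description="Variant-supporting reads">')
    header.add_line('##INFO=<ID=DR,Number=1,Type=Integer,Description="Reference-spanning reads">')
    header.add_line('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">')
    header.add_line('##ALT=<ID=INV,Description="Inversion">')
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    header.add_line('##ALT=<ID=DUP,Description="Tandem duplication">')
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for i, c in enumerate(candidates):
            if c.sv_type == "TRA":
                (ca, pa), (cb, pb) = c.breakpointA, c.breakpointB
                for tag, (ch, po), (mch, mpo) in (
                    ("a", (ca, pa), (cb, pb)),
                    ("b", (cb, pb), (ca, pa)),
                ):
                    rec = vcf.new_record(
                        contig=ch, start=po - 1, stop=po,
                        alleles=("N", f"N[{mch}:{mpo}["), id=f"TRA{i}{tag}",
                    )
                    rec.info["SVTYPE"] = "BND"
                    rec.info["DV"] = c.dv
                    rec.info["DR"] = c.dr
                    rec.info["MATEID"] = f"TRA{i}{'b' if tag == 'a' else 'a'}"
                    vcf.write(rec)
            else:
                svlen = c.breakpointB[1] - c.breakpointA[1]
                rec = vcf.new_record(
                    contig=c.breakpointA[0],
                    start=c.breakpointA[1] - 1,
                    stop=c.breakpointB[1],
                    alleles=("N", f"<{c.sv_type}>"),
                    id=f"{c.sv_type}{i}",
                )
                rec.info["SVTYPE"] = c.sv_type
                rec.info["SVLEN"] = -svlen if c.sv_type == "DEL" else svlen
                rec.info["DV"] = c.dv
                rec.info["DR"] = c.dr
                vcf.write(rec)
    return path


def write_rejection_tsv(candidates, reasons: dict[int, list[str]], path: str) -> str:
    with open(path, "w") as fh:
        fh.write("sv_type\tchromA\tposA\tchromB\tposB\tDV\tDR\treasons\n")
        for i, c in enumerate(candidates):
            if i not in reasons:
                continue
            fh.write(
                f"{c.sv_type}\t{c.breakpointA[0]}\t{c.breakpointA[1]}\t"
                f"{c.breakpointB[0]}\t{c.breakpointB[1]}\t{c.dv}\t{c.dr}\t"
                + "; ".join(reasons[i])
                + "\n"
            )
    return path


def detect(
    sam_path: str,
    cfg: FilterConfig | None = None,
    position_tol: int = 50,
    dr_margin: int = 200,
    read_whitelist: set[str] | None = None,
):
    """SAM -> refined, DR-annotated candidates plus per-candidate rejections."""
    reads = digest_alignments(read_sam(sam_path), read_whitelist)
    sigs = extract_signatures(reads)
    candidates = cluster_signatures(sigs, position_tol)
    for c in candidates:
        compute_reference_support(c, reads, dr_margin)
        refine_breakpoint(c)
    retained, reasons = filter_svs(candidates, cfg)
    return candidates, retained, reasons
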