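"""Synthetic family generator: diploid genome with satellite-like repeat tracts,
planted structural rearrangements, long reads with truth alignments, and embryo
biopsies with array-like noisy genotypes, shallow binned counts and full ground truth.

Everything downstream (SV detection, phasing, liftover, CNV, linkage) is testable
against the truth records emitted here. All coordinates are 1-based inclusive
internally; SAM/VCF/BED conventions are respected at the I/O boundaries.
"""

from __future__ import annotations

import array
import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pysam

from .utils import BASES, child_rng, phred_to_qual_string, revcomp

_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[_b] = _i

# CIGAR op codes as used by pysam (BAM encoding)
_OP_M, _OP_I, _OP_D, _OP_S = 0, 1, 2, 4


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    """Layout of the synthetic diploid genome.

    chromosomes      ordered (name, length) pairs, lengths in bp
    snp_density      heterozygous-site density per bp on unique arms (default
                     one het site per ~3.1 kb, matching the density implied by
                     ~630 phaseable SNPs in a 2 Mbp breakpoint window)
    repeat_het_factor  multiplier for het density inside repeat tracts (<= 0.1
                     per the genome invariant: SNP-poor satellite-like tracts)
    repeat_tracts    chrom -> (start, end) 1-based inclusive; default: middle fifth
    monomer_length   satellite monomer size in bp (alpha-satellite-like 171)
    monomer_divergence  per-copy substitution rate between monomer copies
    """

    chromosomes: list[tuple[str, int]]
    snp_density: float = 3.2e-4
    repeat_het_factor: float = 0.1
    repeat_tracts: dict[str, tuple[int, int]] | None = None
    monomer_length: int = 171
    monomer_divergence: float = 0.02

    def tract_for(self, name: str, length: int) -> tuple[int, int]:
        if self.repeat_tracts and name in self.repeat_tracts:
            return self.repeat_tracts[name]
        return (2 * length // 5 + 1, 3 * length // 5)


@dataclass
class SVSpec:
    """A planted structural rearrangement on one parental haplotype.

    For INV/DEL/DUP the affected reference interval is [posA, posB) (1-based,
    half-open at posB), so the event length is posB - posA. For TRA, the
    derivative chromosomes are chromA[1..posA-1] + chromB[posB..] and
    chromB[1..posB-1] + chromA[posA..].
    """

    sv_type: str  # INV | TRA | DEL | DUP
    chromA: str
    posA: int
    chromB: str
    posB: int
    carrier_haplotype: str = "B"  # A or B

    def __post_init__(self):
        if self.sv_type not in ("INV", "TRA", "DEL", "DUP"):
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.sv_type == "TRA":
            if self.chromA == self.chromB:
                raise ValueError("TRA requires two distinct chromosomes")
        else:
            if self.chromA != self.chromB:
                raise ValueError(f"{self.sv_type} must be intra-chromosomal")
            if not self.posA < self.posB:
                raise ValueError("posA must be < posB")
        if self.carrier_haplotype not in ("A", "B"):
            raise ValueError("carrier_haplotype must be 'A' or 'B'")


@dataclass
class ReadSimConfig:
    """Long-read simulation settings (log-normal lengths, uniform error model)."""

    mean_length: int = 18000
    length_sigma: float = 0.6  # log-normal shape (long nanopore-like tail)
    depth: float = 28.0
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    min_length: int = 300
    min_segment: int = 100  # smallest split-alignment piece emitted
    seed: int = 0

    def validate(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


@dataclass
class EmbryoSimConfig:
    """Embryo cohort settings.

    recombination_rate is in crossovers per Mb per meiosis (1 cM/Mb = 0.01).
    aneuploidy_events are (embryo index, chrom, copy number) whole-chromosome events.
    """

    n_embryos: int = 7
    recombination_rate: float = 0.01
    ado_rate: float = 0.1
    genotype_error: float = 0.01
    nocall_rate: float = 0.05
    aneuploidy_events: list[tuple[int, str, int]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for name in ("ado_rate", "genotype_error", "nocall_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.recombination_rate < 0:
            raise ValueError("recombination_rate must be >= 0")


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """One block of a haplotype arrangement: `length` bases taken from the
    reference `src_chrom` starting at `src_start` (1-based, smallest ref
    coordinate of the block) on `strand` ('-' means reverse complement)."""

    src_chrom: str
    src_start: int
    length: int
    strand: str = "+"


@dataclass
class SVTruth:
    spec: SVSpec
    heterochromatic_A: bool
    heterochromatic_B: bool

    @property
    def junction(self) -> tuple[str, int, str, int]:
        s = self.spec
        return (s.chromA, s.posA, s.chromB, s.posB)


class SyntheticGenome:
    """Diploid genome: two haplotypes differing at het sites and at planted SVs.

    The reference coordinate system is haplotype A's pre-SV sequence; each
    haplotype is a linear arrangement of reference segments plus its own het
    alleles, so truth alignments of any read are exact by construction.
    """

    def __init__(self, ref: dict[str, bytes], het_sites, repeat_tracts, config: GenomeConfig):
        self.ref = ref  # chrom -> reference (hap A source) sequence
        self.het_sites = het_sites  # list of (chrom, pos, alleleA, alleleB)
        self.repeat_tracts = repeat_tracts  # list of (chrom, start, end)
        self.config = config
        self.svs: list[SVTruth] = []
        # per-haplotype SNP-bearing source sequences in reference coordinates
        self.hap_sources: dict[str, dict[str, bytes]] = {"A": dict(ref), "B": {}}
        for chrom, seq in ref.items():
            arr = bytearray(seq)
            for c, pos, _a, b in het_sites:
                if c == chrom:
                    arr[pos - 1] = ord(b)
            self.hap_sources["B"][chrom] = bytes(arr)
        self.arrangements: dict[str, dict[str, list[Segment]]] = {
            hap: {c: [Segment(c, 1, len(s))] for c, s in ref.items()} for hap in "AB"
        }

    # -- views ----------------------------------------------------------------

    @property
    def ref_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.ref.items()}

    def hap_length(self, hap: str, chrom: str) -> int:
        return sum(s.length for s in self.arrangements[hap][chrom])

    def hap_sequence(self, hap: str, chrom: str) -> bytes:
        parts = []
        src = self.hap_sources[hap]
        for seg in self.arrangements[hap][chrom]:
            sl = src[seg.src_chrom][seg.src_start - 1 : seg.src_start - 1 + seg.length]
            parts.append(sl if seg.strand == "+" else revcomp(sl))
        return b"".join(parts)

    @property
    def chromosomes(self) -> dict[str, tuple[bytes, bytes]]:
        return {c: (self.hap_sequence("A", c), self.hap_sequence("B", c)) for c in self.ref}

    def in_repeat(self, chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos <= e for c, s, e in self.repeat_tracts)

    # -- structural edits -------------------------------------------------------

    def _split_at(self, segs: list[Segment], chrom: str, ref_pos: int) -> int:
        """Split the identity-mapped segment list so a boundary falls exactly
        before reference position `ref_pos`; returns the boundary index."""
        off = 0
        for i, seg in enumerate(segs):
            if (
                seg.strand == "+"
                and seg.src_chrom == chrom
                and seg.src_start <= ref_pos <= seg.src_start + seg.length
            ):
                cut = ref_pos - seg.src_start
                if cut == 0:
                    return i
                if cut == seg.length:
                    return i + 1
                left = Segment(chrom, seg.src_start, cut, "+")
                right = Segment(chrom, ref_pos, seg.length - cut, "+")
                segs[i : i + 1] = [left, right]
                return i + 1
            off += seg.length
        raise ValueError(
            f"breakpoint {chrom}:{ref_pos} does not fall in a forward-mapped segment "
            "(overlapping SVs on one haplotype are not supported)"
        )


def build_genome(config: GenomeConfig, seed: int) -> SyntheticGenome:
    """Generate the diploid genome: random unique arms, one tandem-repeat tract
    per chromosome (monomer copies with per-copy divergence), and het sites whose
    density inside the tract is reduced by `repeat_het_factor`."""
    total = sum(length for _n, length in config.chromosomes)
    if total < 1_000_000:
        raise ValueError("total genome size must be >= 1 Mb")
    repeat_density = config.snp_density * config.repeat_het_factor
    if repeat_density > 0.5:
        raise ValueError("SNP density inside repeat tracts would exceed 1 site per 2 bp")

    rng = child_rng(seed, 0)
    ref: dict[str, bytes] = {}
    tracts: list[tuple[str, int, int]] = []
    het_sites: list[tuple[str, int, str, str]] = []
    bases_arr = np.frombuffer(BASES, dtype=np.uint8)

    for name, length in config.chromosomes:
        seq = bases_arr[rng.integers(0, 4, size=length)]
        ts, te = config.tract_for(name, length)
        if not (1 <= ts < te <= length):
            raise ValueError(f"repeat tract out of bounds for {name}")
        # tandem monomer copies with per-copy divergence
        monomer = bases_arr[rng.integers(0, 4, size=config.monomer_length)]
        tract_len = te - ts + 1
        n_copies = math.ceil(tract_len / config.monomer_length)
        tiled = np.tile(monomer, n_copies)[:tract_len].copy()
        div = rng.random(tract_len) < config.monomer_divergence
        idx = np.flatnonzero(div)
        if idx.size:
            tiled[idx] = bases_arr[(_BASE_INDEX[tiled[idx]] + rng.integers(1, 4, idx.size)) % 4]
        seq[ts - 1 : te] = tiled
        tracts.append((name, ts, te))

        # het sites: position-wise Bernoulli with tract-reduced density
        dens = np.full(length, config.snp_density)
        dens[ts - 1 : te] = repeat_density
        hits = np.flatnonzero(rng.random(length) < dens)
        alts = bases_arr[(_BASE_INDEX[seq[hits]] + rng.integers(1, 4, hits.size)) % 4]
        for p, alt in zip(hits, alts):
            het_sites.append((name, int(p) + 1, chr(seq[p]), chr(alt)))
        ref[name] = seq.tobytes()

    return SyntheticGenome(ref, het_sites, tracts, config)


def apply_sv(genome: SyntheticGenome, spec: SVSpec) -> SyntheticGenome:
    """Plant a rearrangement on the carrier haplotype; other haplotype untouched.

    INV reverse-complements [posA, posB); DEL removes it; DUP tandem-duplicates
    it; TRA swaps the chromosome tails at posA/posB. Returns the same genome
    object with the truth record appended."""
    for c, p in ((spec.chromA, spec.posA), (spec.chromB, spec.posB)):
        if c not in genome.ref or not 1 <= p <= len(genome.ref[c]):
            raise ValueError(f"breakpoint {c}:{p} out of bounds")
    arr = genome.arrangements[spec.carrier_haplotype]

    if spec.sv_type == "TRA":
        segs_a, segs_b = arr[spec.chromA], arr[spec.chromB]
        ia = genome._split_at(segs_a, spec.chromA, spec.posA)
        ib = genome._split_at(segs_b, spec.chromB, spec.posB)
        head_a, tail_a = segs_a[:ia], segs_a[ia:]
        head_b, tail_b = segs_b[:ib], segs_b[ib:]
        arr[spec.chromA] = head_a + tail_b
        arr[spec.chromB] = head_b + tail_a
    else:
        segs = arr[spec.chromA]
        i0 = genome._split_at(segs, spec.chromA, spec.posA)
        i1 = genome._split_at(segs, spec.chromA, spec.posB)
        mid = segs[i0:i1]
        if spec.sv_type == "INV":
            flipped = [
                Segment(s.src_chrom, s.src_start, s.length, "-" if s.strand == "+" else "+")
                for s in reversed(mid)
            ]
            segs[i0:i1] = flipped
        elif spec.sv_type == "DEL":
            segs[i0:i1] = []
        elif spec.sv_type == "DUP":
            segs[i0:i1] = mid + [dataclasses.replace(s) for s in mid]

    genome.svs.append(
        SVTruth(
            spec,
            heterochromatic_A=genome.in_repeat(spec.chromA, spec.posA),
            heterochromatic_B=genome.in_repeat(spec.chromB, spec.posB),
        )
    )
    return genome


def write_reference_fasta(genome: SyntheticGenome, path: str) -> str:
    with open(path, "w") as fh:
        for name, seq in genome.ref.items():
            fh.write(f">{name}\n")
            s = seq.decode()
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")
    return path


# ---------------------------------------------------------------------------
# read simulation with truth alignments
# ---------------------------------------------------------------------------

def _mutate(src: np.ndarray, rng: np.random.Generator, cfg: ReadSimConfig):
    """Apply substitution/insertion/deletion errors to an oriented source block.

    Returns (read bytes, cigar ops [(op, len)] in read orientation, NM count).
    The full source block is always consumed, so reference junction coordinates
    of split alignments are never perturbed by errors."""
    n = src.size
    if cfg.sub_rate == 0 and cfg.ins_rate == 0 and cfg.del_rate == 0:
        return src.tobytes(), [(_OP_M, n)], 0
    bases_arr = np.frombuffer(BASES, dtype=np.uint8)
    u = rng.random(n)
    del_mask = u < cfg.del_rate
    sub_mask = (~del_mask) & (u < cfg.del_rate + cfg.sub_rate)
    ins_mask = rng.random(n) < cfg.ins_rate  # insertion before source base i

    out = src.copy()
    sidx = np.flatnonzero(sub_mask)
    if sidx.size:
        out[sidx] = bases_arr[(_BASE_INDEX[out[sidx]] + rng.integers(1, 4, sidx.size)) % 4]

    codes = np.full(2 * n, 255, dtype=np.uint8)
    emit = np.zeros(2 * n, dtype=np.uint8)
    codes[0::2][ins_mask] = _OP_I
    emit[0::2][ins_mask] = bases_arr[rng.integers(0, 4, int(ins_mask.sum()))]
    codes[1::2] = np.where(del_mask, _OP_D, _OP_M)
    emit[1::2] = out
    keep = codes != 255
    codes, emit = codes[keep], emit[keep]
    read = emit[codes != _OP_D].tobytes()

    change = np.flatnonzero(np.diff(codes.astype(np.int16))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [codes.size]))
    cigar = [(int(codes[s]), int(e - s)) for s, e in zip(starts, ends)]
    nm = int(del_mask.sum() + sub_mask.sum() + ins_mask.sum())
    return read, cigar, nm


def _cigar_str(ops) -> str:
    sym = {_OP_M: "M", _OP_I: "I", _OP_D: "D", _OP_S: "S"}
    return "".join(f"{l}{sym[o]}" for o, l in ops)


def _walk_segments(segs: list[Segment], start0: int, length: int):
    """Pieces of haplotype interval [start0, start0+length) (0-based hap coords)
    as (src_chrom, src_start0, piece_len, strand) in haplotype order."""
    pieces = []
    off = 0
    for seg in segs:
        if off >= start0 + length:
            break
        seg_end = off + seg.length
        lo = max(start0, off)
        hi = min(start0 + length, seg_end)
        if lo < hi:
            if seg.strand == "+":
                s0 = seg.src_start - 1 + (lo - off)
            else:
                s0 = seg.src_start - 1 + (seg_end - hi)
            pieces.append((seg.src_chrom, s0, hi - lo, seg.strand))
        off = seg_end
    return pieces


def simulate_reads(
    genome: SyntheticGenome,
    cfg: ReadSimConfig,
    fastq_path: str,
    sam_path: str,
) -> tuple[str, str]:
    """Draw long reads from both haplotypes and emit FASTQ plus truth SAM.

    Reads crossing an SV junction on the carrier haplotype are written as a
    primary alignment plus SA-tagged supplementaries whose reference junction
    equals the planted breakpoint exactly. Deterministic per cfg.seed."""
    cfg.validate()
    rng = child_rng(cfg.seed, 1)
    total_err = cfg.sub_rate + cfg.ins_rate + cfg.del_rate
    qual_q = 60 if total_err == 0 else max(2, round(-10 * math.log10(total_err)))

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": l} for c, l in genome.ref_lengths.items()],
        }
    )
    target_bases = cfg.depth * sum(genome.ref_lengths.values())
    mu = math.log(cfg.mean_length) - cfg.length_sigma**2 / 2

    hap_chrom: list[tuple[str, str, int]] = []
    for hap in "AB":
        for chrom in genome.ref:
            hap_chrom.append((hap, chrom, genome.hap_length(hap, chrom)))
    weights = np.array([l for _h, _c, l in hap_chrom], dtype=float)
    weights /= weights.sum()
    hap_seqs = {(h, c): genome.hap_sequence(h, c) for h, c, _l in hap_chrom}

    emitted = 0.0
    ridx = 0
    cum_weights = np.cumsum(weights)
    batch: list[tuple[int, float, float]] = []
    qual_template = array.array("B", bytes([qual_q]) * (4 * cfg.mean_length + 10_000))
    qual_cache: dict[int, str] = {}
    with open(fastq_path, "w") as fq, pysam.AlignmentFile(sam_path, "w", header=header) as sam:
        while emitted < target_bases:
            if not batch:  # draw randomness in blocks; stopping mid-block is fine
                picks = np.searchsorted(cum_weights, rng.random(2048))
                lens = rng.lognormal(mu, cfg.length_sigma, 2048)
                fracs = rng.random(2048)
                batch = list(zip(picks.tolist(), lens.tolist(), fracs.tolist()))[::-1]
            pick, raw_len, frac = batch.pop()
            hap, chrom, hap_len = hap_chrom[pick]
            length = max(cfg.min_length, int(raw_len))
            start0 = int(frac * max(1, hap_len - cfg.min_length))
            length = min(length, hap_len - start0)
            name = f"r{ridx:06d}_{hap}"
            ridx += 1
            emitted += length

            pieces = _walk_segments(genome.arrangements[hap][chrom], start0, length)
            hseq = np.frombuffer(hap_seqs[(hap, chrom)], dtype=np.uint8)
            read_parts: list[bytes] = []
            aln_pieces = []  # (qs, qe, src_chrom, ref_start0, ref_len, strand, cigar, nm)
            qpos = 0
            hoff = start0
            for src_chrom, s0, plen, strand in pieces:
                block = hseq[hoff : hoff + plen]  # oriented source, errors applied in read frame
                read_piece, ops, nm = _mutate(block, rng, cfg)
                if plen >= cfg.min_segment:
                    aln_pieces.append(
                        (qpos, qpos + len(read_piece), src_chrom, s0, plen, strand, ops, nm)
                    )
                read_parts.append(read_piece)
                qpos += len(read_piece)
                hoff += plen
            read = b"".join(read_parts)
            qual = qual_cache.get(len(read))
            if qual is None:
                qual = phred_to_qual_string(qual_q, len(read))
                if len(qual_cache) < 4096:
                    qual_cache[len(read)] = qual
            fq.write(f"@{name}\n{read.decode()}\n+\n{qual}\n")

            if not aln_pieces:
                continue
            primary = max(range(len(aln_pieces)), key=lambda i: aln_pieces[i][4])
            sa_strings = []
            records = []
            for i, (qs, qe, src_chrom, s0, _rl, strand, ops, nm) in enumerate(aln_pieces):
                rlen = len(read)
                if strand == "+":
                    cig = ([(_OP_S, qs)] if qs else []) + ops + ([(_OP_S, rlen - qe)] if rlen - qe else [])
                    seq_out = read
                else:
                    cig = (
                        ([(_OP_S, rlen - qe)] if rlen - qe else [])
                        + ops[::-1]
                        + ([(_OP_S, qs)] if qs else [])
                    )
                    seq_out = revcomp(read)
                a = pysam.AlignedSegment(header)
                a.query_name = name
                a.flag = (16 if strand == "-" else 0) | (0 if i == primary else 2048)
                a.reference_name = src_chrom
                a.reference_start = s0
                a.mapping_quality = 60
                a.cigartuples = cig
                a.query_sequence = seq_out.decode()
                if len(seq_out) <= len(qual_template):
                    a.query_qualities = qual_template[: len(seq_out)]
                else:
                    a.query_qualities = array.array("B", bytes([qual_q]) * len(seq_out))
                a.set_tag("NM", nm)
                records.append(a)
                sa_strings.append(f"{src_chrom},{s0 + 1},{strand},{_cigar_str(cig)},60,{nm};")
            if len(records) > 1:
                for i, a in enumerate(records):
                    a.set_tag("SA", "".join(s for j, s in enumerate(sa_strings) if j != i))
            for a in records:
                sam.write(a)
    return fastq_path, sam_path


# ---------------------------------------------------------------------------
# embryos
# ---------------------------------------------------------------------------

@dataclass
class EmbryoTruth:
    """Ground truth for one embryo: transmitted carrier-parent haplotype as
    (start, end, hap) segments per chromosome, carrier status at the anchor
    breakpoint, true genotypes per het site, and per-chromosome copy number."""

    embryo_id: str
    segments: dict[str, list[tuple[int, int, str]]]
    carrier: bool
    genotypes: dict[tuple[str, int], tuple[str, str]]
    copy_number: dict[str, int]

    def transmitted_hap(self, chrom: str, pos: int) -> str:
        for s, e, h in self.segments[chrom]:
            if s <= pos <= e:
                return h
        raise KeyError(f"{chrom}:{pos} outside segments")


def simulate_embryos(
    genome: SyntheticGenome, spec: SVSpec, cfg: EmbryoSimConfig
) -> list[EmbryoTruth]:
    """Carrier-parent meioses with Poisson(r * L_Mb) crossovers at uniform
    positions; the other parent contributes a homozygous reference background.

    Carrier status is evaluated at the arm-side breakpoint (chromB:posB), the
    breakpoint used for linkage."""
    cfg.validate()
    rng = child_rng(cfg.seed, 2)
    lengths = genome.ref_lengths
    for _i, chrom, _cn in cfg.aneuploidy_events:
        if chrom not in lengths:
            raise ValueError(f"aneuploidy event names unknown chromosome {chrom!r}")
    het_by_chrom: dict[str, list[tuple[int, str, str]]] = {c: [] for c in lengths}
    for c, pos, a, b in genome.het_sites:
        het_by_chrom[c].append((pos, a, b))

    embryos = []
    for k in range(cfg.n_embryos):
        segments: dict[str, list[tuple[int, int, str]]] = {}
        genotypes: dict[tuple[str, int], tuple[str, str]] = {}
        for chrom, length in lengths.items():
            n_xo = rng.poisson(cfg.recombination_rate * length / 1e6)
            cuts = sorted(int(p) for p in rng.integers(1, length, size=n_xo))
            hap = "A" if rng.random() < 0.5 else "B"
            segs = []
            prev = 1
            for cut in cuts:
                if cut > prev:
                    segs.append((prev, cut - 1, hap))
                    prev = cut
                hap = "B" if hap == "A" else "A"
            segs.append((prev, length, hap))
            segments[chrom] = segs
            for pos, a, b in het_by_chrom[chrom]:
                th = next(h for s, e, h in segs if s <= pos <= e)
                transmitted = a if th == "A" else b
                genotypes[(chrom, pos)] = (transmitted, a)  # other parent: hom-ref (allele A)
        cn = {c: 2 for c in lengths}
        for i, chrom, copies in cfg.aneuploidy_events:
            if i == k:
                cn[chrom] = copies
        carrier = (
            segments[spec.chromB]
            and next(h for s, e, h in segments[spec.chromB] if s <= spec.posB <= e)
            == spec.carrier_haplotype
        )
        embryos.append(EmbryoTruth(f"E{k + 1}", segments, bool(carrier), genotypes, cn))
    return embryos


@dataclass
class EmbryoGenotypes:
    """Observed (array-like) SNP calls for one biopsy; None means no-call."""

    embryo_id: str
    calls: dict[tuple[str, int], tuple[str, str] | None]


def genotype_embryos(
    truths: list[EmbryoTruth],
    cfg: EmbryoSimConfig,
    site_alleles: dict[tuple[str, int], tuple[str, str]] | None = None,
) -> list[EmbryoGenotypes]:
    """Array genotyping noise: per site, no-call with prob nocall_rate; else one
    allele drops with prob ado_rate (het read as hom); then each reported allele
    flips to the site's other allele with prob genotype_error, independently.

    `site_alleles` (chrom, pos) -> the site's two known alleles lets flips land
    on the site's other allele even when the true genotype is homozygous; pass
    a map built from SyntheticGenome.het_sites."""
    cfg.validate()
    rng = child_rng(cfg.seed, 3)
    out = []
    for truth in truths:
        calls: dict[tuple[str, int], tuple[str, str] | None] = {}
        for key, (g1, g2) in truth.genotypes.items():
            if rng.random() < cfg.nocall_rate:
                calls[key] = None
                continue
            alleles = [g1, g2]
            if rng.random() < cfg.ado_rate:
                keep = alleles[int(rng.integers(0, 2))]
                alleles = [keep, keep]
            known = set(site_alleles[key]) if site_alleles else {g1, g2}
            reported = []
            for a in alleles:
                if rng.random() < cfg.genotype_error:
                    alt = next((x for x in sorted(known) if x != a), None)
                    if alt is None:  # hom site with no recorded alt: random flip
                        others = [x for x in "ACGT" if x != a]
                        alt = others[int(rng.integers(0, 3))]
                    reported.append(alt)
                else:
                    reported.append(a)
            calls[key] = tuple(sorted(reported))
        out.append(EmbryoGenotypes(truth.embryo_id, calls))
    return out


def het_site_alleles(genome: SyntheticGenome) -> dict[tuple[str, int], tuple[str, str]]:
    return {(c, p): (a, b) for c, p, a, b in genome.het_sites}


def counts_for_cnv(
    truths: list[EmbryoTruth],
    genome: SyntheticGenome,
    bin_size: int,
    mean_count: float,
    seed: int,
):
    """Shallow-coverage binned read counts: per bin ~ Poisson(mean_count * copy/2).

    Returns {embryo_id: list of (chrom, start, end, count)} with 1-based
    inclusive bin bounds tiling each chromosome."""
    lengths = genome.ref_lengths
    for chrom, length in lengths.items():
        if length // bin_size < 20:
            raise ValueError(f"bin_size leaves fewer than 20 bins on {chrom}")
    rng = child_rng(seed, 4)
    out = {}
    for truth in truths:
        rows = []
        for chrom, length in lengths.items():
            n_bins = length // bin_size
            lam = mean_count * truth.copy_number[chrom] / 2.0
            counts = rng.poisson(lam, size=n_bins) if lam > 0 else np.zeros(n_bins, dtype=int)
            for j in range(n_bins):
                rows.append((chrom, j * bin_size + 1, (j + 1) * bin_size, int(counts[j])))
        out[truth.embryo_id] = rows
    return out


# ---------------------------------------------------------------------------
# truth writers (plain-text formats only)
# ---------------------------------------------------------------------------

def write_parental_vcf(genome: SyntheticGenome, path: str, sample: str = "carrier") -> str:
    """Truth parental het sites as a phased VCF; the GT is alleleA|alleleB so
    haplotype of origin is recoverable (0|1 when alt is on haplotype B)."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom, length in genome.ref_lengths.items():
        header.contigs.add(chrom, length=length)
    header.add_sample(sample)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for chrom, pos, a, b in sorted(genome.het_sites):
            rec = vcf.new_record(contig=chrom, start=pos - 1, stop=pos, alleles=(a, b))
            rec.samples[sample]["GT"] = (0, 1)
            rec.samples[sample].phased = True
            vcf.write(rec)
    return path


def write_embryo_tsv(genos: list[EmbryoGenotypes], path: str, shift: dict[str, int] | None = None) -> str:
    """Embryo genotype table (embryo, chrom, pos, allele1, allele2; '.' = no-call).

    `shift` optionally re-expresses positions in a shifted (array reference)
    coordinate system, mirroring genotypes delivered on a different assembly."""
    with open(path, "w") as fh:
        fh.write("embryo\tchrom\tpos\tallele1\tallele2\n")
        for g in genos:
            for (chrom, pos), call in sorted(g.calls.items()):
                p = pos + (shift or {}).get(chrom, 0)
                if call is None:
                    fh.write(f"{g.embryo_id}\t{chrom}\t{p}\t.\t.\n")
                else:
                    fh.write(f"{g.embryo_id}\t{chrom}\t{p}\t{call[0]}\t{call[1]}\n")
    return path


def write_bincounts_tsv(counts: dict[str, list], path: str) -> str:
    with open(path, "w") as fh:
        fh.write("embryo\tchrom\tstart\tend\tcount\n")
        for embryo_id, rows in counts.items():
            for chrom, s, e, c in rows:
                fh.write(f"{embryo_id}\t{chrom}\t{s}\t{e}\t{c}\n")
    return path


def write_embryo_truth_tsv(truths: list[EmbryoTruth], path: str) -> str:
    with open(path, "w") as fh:
        fh.write("embryo\tcarrier\tcopy_number\tsegments\n")
        for t in truths:
            cn = ";".join(f"{c}:{n}" for c, n in t.copy_number.items())
            segs = ";".join(
                f"{c}:{s}-{e}:{h}" for c, lst in t.segments.items() for s, e, h in lst
            )
            fh.write(f"{t.embryo_id}\t{int(t.carrier)}\t{cn}\t{segs}\n")
    return path


def write_shift_chain(
    genome: SyntheticGenome, shifts: dict[str, int], path: str, inverse_path: str | None = None
) -> str:
    """Synthetic UCSC chain pair mapping the simulation reference onto a shifted
    'array' coordinate system (one chain per chromosome, constant offset)."""
    with open(path, "w") as fh:
        for i, (chrom, length) in enumerate(genome.ref_lengths.items()):
            off = shifts.get(chrom, 0)
            q_size = length + off + 10_000
            fh.write(
                f"chain 1000 {chrom} {length} + 0 {length} "
                f"{chrom} {q_size} + {off} {off + length} {i + 1}\n{length}\n\n"
            )
    if inverse_path:
        with open(inverse_path, "w") as fh:
            for i, (chrom, length) in enumerate(genome.ref_lengths.items()):
                off = shifts.get(chrom, 0)
                q_size = length + off + 10_000
                fh.write(
                    f"chain 1000 {chrom} {q_size} + {off} {off + length} "
                    f"{chrom} {length} + 0 {length} {i + 1}\n{length}\n\n"
                )
    return path


def write_truth_json(genome: SyntheticGenome, truths: list[EmbryoTruth], path: str) -> str:
    payload = {
        "chromosomes": genome.ref_lengths,
        "repeat_tracts": genome.repeat_tracts,
        "n_het_sites": len(genome.het_sites),
        "svs": [
            {
                "sv_type": t.spec.sv_type,
                "chromA": t.spec.chromA,
                "posA": t.spec.posA,
                "chromB": t.spec.chromB,
                "posB": t.spec.posB,
                "carrier_haplotype": t.spec.carrier_haplotype,
                "heterochromatic_A": t.heterochromatic_A,
                "heterochromatic_B": t.heterochromatic_B,
            }
            for t in genome.svs
        ],
        "embryos": [
            {"id": t.embryo_id, "carrier": t.carrier, "copy_number": t.copy_number}
            for t in truths
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return path
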