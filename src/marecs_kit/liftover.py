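"""UCSC chain-file coordinate liftover.

Parses chain files into ordered aligned blocks, lifts single positions
(strand-aware, highest-scoring chain wins where chains overlap) and transforms
phased VCFs between coordinate systems while preserving hap1/hap2 assignments.
Chain coordinates are 0-based half-open at the parser boundary and converted to
this package's 1-based convention at the API surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam


class ChainParseError(ValueError):
    pass


@dataclass
class ChainBlock:
    """One gapless aligned block. Source ('t' side of the chain, the assembly
    being lifted from) and destination intervals are 0-based half-open;
    destination coordinates are stored on the plus strand of the destination
    sequence regardless of chain strand."""

    src_chrom: str
    src_start: int
    src_end: int
    dst_chrom: str
    dst_start: int
    dst_end: int
    strand: str
    score: float


@dataclass
class ChainMap:
    blocks: list[ChainBlock] = field(default_factory=list)
    dst_sizes: dict[str, int] = field(default_factory=dict)
    src_sizes: dict[str, int] = field(default_factory=dict)

    def _by_chrom(self) -> dict[str, list[ChainBlock]]:
        out: dict[str, list[ChainBlock]] = {}
        for b in self.blocks:
            out.setdefault(b.src_chrom, []).append(b)
        for lst in out.values():
            lst.sort(key=lambda b: (b.src_start, -b.score))
        return out

    def inverted(self) -> "ChainMap":
        """Swap source and destination roles; valid for any strand because the
        within-block mapping of a minus-strand block is an involution."""
        inv = [
            ChainBlock(
                b.dst_chrom, b.dst_start, b.dst_end, b.src_chrom, b.src_start, b.src_end,
                b.strand, b.score,
            )
            for b in self.blocks
        ]
        return ChainMap(inv, dst_sizes=dict(self.src_sizes), src_sizes=dict(self.dst_sizes))


def read_chain(path: str) -> ChainMap:
    """Parse a UCSC chain file; validates that the size/dt/dq triples sum to the
    header's source and destination extents and that paired blocks have equal
    length (the format guarantees this by construction)."""
    cmap = ChainMap()
    with open(path) as fh:
        header = None
        t_pos = q_pos = 0
        lineno_hdr = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                if header is not None:
                    raise ChainParseError(
                        f"line {lineno}: new chain before previous one ended (line {lineno_hdr})"
                    )
                f = line.split()
                if len(f) < 12:
                    raise ChainParseError(f"line {lineno}: malformed chain header")
                try:
                    header = {
                        "score": float(f[1]),
                        "t_name": f[2], "t_size": int(f[3]), "t_strand": f[4],
                        "t_start": int(f[5]), "t_end": int(f[6]),
                        "q_name": f[7], "q_size": int(f[8]), "q_strand": f[9],
                        "q_start": int(f[10]), "q_end": int(f[11]),
                    }
                except ValueError as exc:
                    raise ChainParseError(f"line {lineno}: {exc}") from exc
                if header["t_strand"] != "+":
                    raise ChainParseError(f"line {lineno}: source strand must be '+'")
                t_pos, q_pos = header["t_start"], header["q_start"]
                lineno_hdr = lineno
                cmap.src_sizes[header["t_name"]] = header["t_size"]
                cmap.dst_sizes[header["q_name"]] = header["q_size"]
                continue
            if header is None:
                raise ChainParseError(f"line {lineno}: alignment data outside a chain")
            parts = line.split()
            if len(parts) not in (1, 3):
                raise ChainParseError(f"line {lineno}: expected 'size [dt dq]'")
            try:
                size = int(parts[0])
                dt = int(parts[1]) if len(parts) == 3 else 0
                dq = int(parts[2]) if len(parts) == 3 else 0
            except ValueError as exc:
                raise ChainParseError(f"line {lineno}: {exc}") from exc
            if header["q_strand"] == "+":
                dst_start, dst_end = q_pos, q_pos + size
            else:
                # q coords count along the minus strand; store plus-strand interval
                dst_start = header["q_size"] - (q_pos + size)
                dst_end = header["q_size"] - q_pos
            cmap.blocks.append(
                ChainBlock(
                    header["t_name"], t_pos, t_pos + size,
                    header["q_name"], dst_start, dst_end,
                    header["q_strand"], header["score"],
                )
            )
            t_pos += size + dt
            q_pos += size + dq
            if len(parts) == 1:
                if t_pos != header["t_end"] or q_pos != header["q_end"]:
                    raise ChainParseError(
                        f"line {lineno}: block sums do not match chain header at line "
                        f"{lineno_hdr} (source {t_pos} vs {header['t_end']}, "
                        f"dest {q_pos} vs {header['q_end']})"
                    )
                header = None
        if header is not None:
            raise ChainParseError(f"truncated chain file: chain at line {lineno_hdr} never ended")
    if not cmap.blocks:
        raise ChainParseError("chain file contains no alignment blocks")
    return cmap


@dataclass
class LiftResult:
    mapped: bool
    chrom: str | None = None
    pos: int | None = None
    strand: str | None = None
    reason: str | None = None


def lift_position(cmap: ChainMap, chrom: str, pos: int) -> LiftResult:
    """Lift a 1-based position. Positions in inter-block gaps are unmapped with
    reason 'gap'; unknown chromosomes are unmapped with reason 'unknown
    chromosome'. Overlapping chains resolve to the highest score."""
    by_chrom = cmap._by_chrom()
    if chrom not in by_chrom:
        return LiftResult(False, reason="unknown chromosome")
    p0 = pos - 1
    best: ChainBlock | None = None
    for b in by_chrom[chrom]:
        if b.src_start <= p0 < b.src_end and (best is None or b.score > best.score):
            best = b
    if best is None:
        return LiftResult(False, reason="gap")
    off = p0 - best.src_start
    if best.strand == "+":
        q0 = best.dst_start + off
    else:
        q0 = best.dst_end - 1 - off
    return LiftResult(True, best.dst_chrom, q0 + 1, best.strand)


def lift_haplotype(
    cmap: ChainMap, in_vcf: str, out_vcf: str, drop_report: str | None = None
) -> tuple[int, int]:
    """Lift every record of a (phased) VCF to the destination coordinates.

    Phase assignments (GT order, PS, INFO) are carried through unchanged;
    unmappable SNPs go to the drop report with their reason. Output records are
    sorted by destination coordinate. Returns (n_lifted, n_dropped)."""
    dropped: list[tuple[str, int, str]] = []
    with pysam.VariantFile(in_vcf) as vin:
        header = pysam.VariantHeader()
        for line in str(vin.header).splitlines():
            if line.startswith("##") and not line.startswith("##contig"):
                header.add_line(line[:])
        for chrom, size in cmap.dst_sizes.items():
            header.contigs.add(chrom, length=size)
        for s in vin.header.samples:
            header.add_sample(s)
        lifted = []
        for rec in vin:
            res = lift_position(cmap, rec.chrom, rec.pos)
            if not res.mapped:
                dropped.append((rec.chrom, rec.pos, res.reason))
                continue
            lifted.append((res.chrom, res.pos, rec))
        lifted.sort(key=lambda t: (t[0], t[1]))
        with pysam.VariantFile(out_vcf, "w", header=header) as vout:
            for chrom, pos, rec in lifted:
                new = vout.new_record(
                    contig=chrom, start=pos - 1, stop=pos, alleles=rec.alleles, id=rec.id
                )
                for k, v in rec.info.items():
                    new.info[k] = v
                for s in rec.samples:
                    for k, v in rec.samples[s].items():
                        if v is not None:
                            new.samples[s][k] = v
                    new.samples[s].phased = rec.samples[s].phased
                vout.write(new)
    if drop_report is not None:
        with open(drop_report, "w") as fh:
            fh.write("chrom\tpos\treason\n")
            for chrom, pos, reason in dropped:
                fh.write(f"{chrom}\t{pos}\t{reason}\n")
    return len(lifted), len(dropped)
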