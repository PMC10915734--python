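"""Lift the index case's long-arm inversion breakpoint between assemblies using
the published T2T-CHM13 -> GRCh37 chain file.

The chain is a ~10 MB external download and is NOT bundled:

    https://hgdownload.soe.ucsc.edu/goldenPath/hs1/liftOver/  (or the
    t2t-chm13-v2.0 'chm13v2-hg19' chain from the T2T globus mirror)

Usage: python examples/liftover_published_chain.py /path/to/chm13v2ToHg19.over.chain
"""

import sys

from marecs_kit.liftover import lift_position, read_chain

ARM_BREAKPOINT = ("chrX", 99_918_578)  # T2T-CHM13 coordinate of the Xq22.1 breakpoint

if len(sys.argv) != 2:
    sys.exit(__doc__)

cmap = read_chain(sys.argv[1])
res = lift_position(cmap, *ARM_BREAKPOINT)
if res.mapped:
    print(f"{ARM_BREAKPOINT[0]}:{ARM_BREAKPOINT[1]:,} (T2T) -> {res.chrom}:{res.pos:,} (GRCh37)")
    print("# the GRCh37 position of this breakpoint is reported as 100,729,404")
else:
    print(f"unmapped: {res.reason}")
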