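"""Stage-one screening: karyotype strings from shallow binned read counts.

Simulates five biopsies over four chromosome analogues, planting one trisomy 22
and one monosomy 18, and prints the ISCN-like strings the screen reports.
"""

import pandas as pd

from marecs_kit import cnvcall, simgen

genome = simgen.build_genome(
    simgen.GenomeConfig(
        chromosomes=[(c, 1_000_000) for c in ("chr17", "chr18", "chr21", "chr22")],
        snp_density=0.0,
    ),
    seed=2,
)
sv = simgen.SVSpec("INV", "chr17", 400_000, "chr17", 600_000)
cfg = simgen.EmbryoSimConfig(
    n_embryos=5, aneuploidy_events=[(1, "chr22", 3), (3, "chr18", 1)], seed=2
)
truths = simgen.simulate_embryos(genome, sv, cfg)
counts = simgen.counts_for_cnv(truths, genome, bin_size=20_000, mean_count=100.0, seed=2)

frames = {
    e: pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
    for e, rows in counts.items()
}
screen = cnvcall.screen_embryos(frames)
for embryo in sorted(screen):
    karyotype, states, _ratios = screen[embryo]
    print(f"{embryo}: {karyotype}   (copy states: {states})")
print(
    "# 46,XN is euploid; +22(×3)/-18(×1) mark whole-chromosome gains/losses.\n"
    "# Aneuploid embryos are excluded before haplotype linkage in the pipeline."
)
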