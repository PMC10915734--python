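"""Built-in demonstration scenarios with full ground truth.

`pedigree1` mirrors the topology of an X-linked pericentric inversion family:
two 5 Mb chromosomes, a heterozygous inversion on the carrier parent with one
breakpoint inside a satellite-like repeat tract (centromere analogue) and the
other in the unique arm, ~28x long reads, and a cohort of biopsied embryos with
array-like genotypes, shallow bin counts, and a synthetic chain to an 'array'
coordinate system standing in for the assembly switch before linkage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from . import simgen
from .simgen import (
    EmbryoSimConfig,
    GenomeConfig,
    ReadSimConfig,
    SVSpec,
    SyntheticGenome,
)

PEDIGREE1_GENOME = GenomeConfig(
    chromosomes=[("chrX", 5_000_000), ("chr22", 5_000_000)],
    snp_density=3.2e-4,
    repeat_het_factor=0.1,
    repeat_tracts={"chrX": (200_000, 2_300_000), "chr22": (2_400_000, 2_600_000)},
)

# one breakpoint mid-repeat-tract (centromere-like), one in the unique arm;
# 1.8 Mb inversion, comfortably under the 5 Mb karyotype gate
PEDIGREE1_SV = SVSpec("INV", "chrX", 2_250_000, "chrX", 4_050_000, carrier_haplotype="B")

# shift to the 'array' coordinate system (echoes a reference-assembly offset)
PEDIGREE1_SHIFTS = {"chrX": 810_826, "chr22": 120_000}


@dataclass
class ScenarioRun:
    """Everything a pipeline stage needs, plus the truth to grade it against."""

    genome: SyntheticGenome
    sv: SVSpec
    embryo_truths: list
    embryo_genotypes: list
    bin_counts: dict
    paths: dict[str, str] = field(default_factory=dict)


def pedigree1(
    seed: int,
    out_dir: str,
    error_rate: float = 0.0,
    depth: float = 28.0,
    mean_read_length: int = 18_000,
    n_embryos: int = 7,
    write_reads: bool = True,
) -> ScenarioRun:
    """Build the pedigree1 scenario deterministically from `seed` and write all
    stage inputs under `out_dir`. `error_rate` is the total per-base error,
    split 3:1:1 over substitutions, insertions and deletions (nanopore-like)."""
    os.makedirs(out_dir, exist_ok=True)
    genome = simgen.build_genome(PEDIGREE1_GENOME, seed)
    simgen.apply_sv(genome, PEDIGREE1_SV)

    read_cfg = ReadSimConfig(
        mean_length=mean_read_length,
        depth=depth,
        sub_rate=error_rate * 0.6,
        ins_rate=error_rate * 0.2,
        del_rate=error_rate * 0.2,
        seed=seed,
    )
    embryo_cfg = EmbryoSimConfig(
        n_embryos=n_embryos,
        aneuploidy_events=[(2, "chr22", 3), (3, "chr22", 1)] if n_embryos >= 4 else [],
        seed=seed,
    )

    paths = {k: os.path.join(out_dir, v) for k, v in {
        "reference": "reference.fa",
        "fastq": "reads.fastq",
        "sam": "truth_alignments.sam",
        "parental_vcf": "parental_het_truth.vcf",
        "other_parent": "other_parent.tsv",
        "embryos": "embryo_genotypes.tsv",
        "embryo_truth": "embryo_truth.tsv",
        "bins": "bin_counts.tsv",
        "chain": "source_to_array.chain",
        "chain_inverse": "array_to_source.chain",
        "truth_json": "truth.json",
    }.items()}

    simgen.write_reference_fasta(genome, paths["reference"])
    if write_reads:
        simgen.simulate_reads(genome, read_cfg, paths["fastq"], paths["sam"])

    truths = simgen.simulate_embryos(genome, PEDIGREE1_SV, embryo_cfg)
    genos = simgen.genotype_embryos(truths, embryo_cfg, simgen.het_site_alleles(genome))
    bins = simgen.counts_for_cnv(truths, genome, bin_size=100_000, mean_count=100.0, seed=seed)

    simgen.write_parental_vcf(genome, paths["parental_vcf"])
    with open(paths["other_parent"], "w") as fh:
        fh.write("chrom\tpos\tallele1\tallele2\n")
        for chrom, pos, a, _b in sorted(genome.het_sites):
            fh.write(f"{chrom}\t{pos}\t{a}\t{a}\n")  # hom reference background
    simgen.write_embryo_tsv(genos, paths["embryos"], shift=PEDIGREE1_SHIFTS)
    simgen.write_embryo_truth_tsv(truths, paths["embryo_truth"])
    simgen.write_bincounts_tsv(bins, paths["bins"])
    simgen.write_shift_chain(genome, PEDIGREE1_SHIFTS, paths["chain"], paths["chain_inverse"])
    simgen.write_truth_json(genome, truths, paths["truth_json"])

    return ScenarioRun(genome, PEDIGREE1_SV, truths, genos, bins, paths)
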