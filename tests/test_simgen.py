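"""Synthetic-family generator: genome construction, SV planting, read simulation
with truth alignments, embryo meioses and genotyping noise."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from marecs_kit import simgen, svscan
from marecs_kit.simgen import (
    EmbryoSimConfig,
    GenomeConfig,
    ReadSimConfig,
    SVSpec,
)
from marecs_kit.utils import revcomp

SMALL = GenomeConfig(
    chromosomes=[("chr1", 1_200_000)],
    snp_density=1e-3,
    repeat_tracts={"chr1": (500_001, 700_000)},
)


def test_zero_snp_density_yields_no_het_sites():
    cfg = GenomeConfig(chromosomes=[("chr1", 1_200_000)], snp_density=0.0)
    genome = simgen.build_genome(cfg, seed=3)
    assert genome.het_sites == []
    a, b = genome.chromosomes["chr1"]
    assert a == b


def test_same_seed_gives_byte_identical_genomes_and_reads(tmp_path):
    outputs = []
    for trial in ("x", "y"):
        genome = simgen.build_genome(SMALL, seed=11)
        simgen.apply_sv(genome, SVSpec("INV", "chr1", 600_000, "chr1", 900_000))
        fq = tmp_path / f"{trial}.fastq"
        sam = tmp_path / f"{trial}.sam"
        simgen.simulate_reads(
            genome, ReadSimConfig(mean_length=9_000, depth=4.0, seed=7), str(fq), str(sam)
        )
        outputs.append((genome.hap_sequence("B", "chr1"), fq.read_bytes(), sam.read_bytes()))
    assert outputs[0] == outputs[1]


def test_het_count_matches_binomial_expectation():
    # 2 Mb arm at density 1/1000: direct count of planted sites within 3 SDs
    cfg = GenomeConfig(
        chromosomes=[("chr1", 2_200_000)],
        snp_density=1e-3,
        repeat_tracts={"chr1": (2_000_001, 2_200_000)},
    )
    genome = simgen.build_genome(cfg, seed=5)
    arm = [s for s in genome.het_sites if s[1] <= 2_000_000]
    n, p = 2_000_000, 1e-3
    sd = math.sqrt(n * p * (1 - p))
    assert abs(len(arm) - n * p) <= 3 * sd


def test_rejects_het_density_above_repeat_packing_limit():
    cfg = GenomeConfig(
        chromosomes=[("chr1", 1_200_000)], snp_density=0.9, repeat_het_factor=0.9
    )
    with pytest.raises(ValueError, match="2 bp"):
        simgen.build_genome(cfg, seed=0)


class TestApplySV:
    def test_inversion_is_involution(self):
        genome = simgen.build_genome(SMALL, seed=2)
        original = genome.hap_sequence("B", "chr1")
        spec = SVSpec("INV", "chr1", 100_000, "chr1", 300_000)
        simgen.apply_sv(genome, spec)
        simgen.apply_sv(genome, spec)
        assert genome.hap_sequence("B", "chr1") == original

    def test_inversion_matches_reverse_complement_oracle(self):
        genome = simgen.build_genome(SMALL, seed=2)
        a, b = 100_000, 300_000
        before = genome.hap_sequence("B", "chr1")
        simgen.apply_sv(genome, SVSpec("INV", "chr1", a, "chr1", b))
        after = genome.hap_sequence("B", "chr1")
        assert after[a - 1 : b - 1] == revcomp(before[a - 1 : b - 1])
        assert after[: a - 1] == before[: a - 1]
        assert after[b - 1 :] == before[b - 1 :]
        # non-carrier haplotype untouched
        assert genome.hap_sequence("A", "chr1") == genome.hap_sources["A"]["chr1"]

    def test_translocation_flags_repeat_tract_breakpoint(self):
        cfg = GenomeConfig(
            chromosomes=[("chr1", 800_000), ("chr2", 800_000)],
            repeat_tracts={"chr1": (300_001, 500_000), "chr2": (600_001, 700_000)},
        )
        genome = simgen.build_genome(cfg, seed=4)
        simgen.apply_sv(genome, SVSpec("TRA", "chr1", 400_000, "chr2", 100_000))
        truth = genome.svs[0]
        assert truth.heterochromatic_A is True
        assert truth.heterochromatic_B is False
        # tails swapped: derivative chr1 length = posA-1 + (len(chr2) - posB + 1)
        assert genome.hap_length("B", "chr1") == 399_999 + 700_001
        assert genome.hap_length("A", "chr1") == 800_000

    def test_overlapping_svs_rejected(self):
        genome = simgen.build_genome(SMALL, seed=2)
        simgen.apply_sv(genome, SVSpec("DEL", "chr1", 100_000, "chr1", 200_000))
        with pytest.raises(ValueError, match="overlapping"):
            simgen.apply_sv(genome, SVSpec("INV", "chr1", 150_000, "chr1", 400_000))

    @pytest.mark.parametrize(
        "bad",
        [
            dict(sv_type="INV", chromA="chr1", posA=5, chromB="chr1", posB=2),
            dict(sv_type="TRA", chromA="chr1", posA=5, chromB="chr1", posB=9),
            dict(sv_type="DEL", chromA="chr1", posA=5, chromB="chr2", posB=9),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            SVSpec(**bad)


@pytest.fixture(scope="module")
def sim(tmp_path_factory):
    genome = simgen.build_genome(SMALL, seed=8)
    simgen.apply_sv(genome, SVSpec("INV", "chr1", 600_000, "chr1", 900_000))
    d = tmp_path_factory.mktemp("reads")
    cfg = ReadSimConfig(mean_length=9_000, depth=6.0, seed=9)
    fq, sam = simgen.simulate_reads(genome, cfg, str(d / "r.fastq"), str(d / "r.sam"))
    return genome, cfg, fq, sam


class TestSimulateReads:
    def test_error_free_unique_arm_read_equals_reference(self, sim):
        genome, _cfg, _fq, sam = sim
        for rec in svscan.read_sam(sam):
            if rec.is_supplementary or rec.has_tag("SA") or "_A" not in rec.query_name:
                continue
            ref = genome.ref["chr1"][rec.reference_start : rec.reference_end]
            assert rec.query_sequence.encode() == ref
            break
        else:
            pytest.fail("no unique-arm haplotype-A read found")

    def test_total_bases_match_requested_depth(self, sim):
        genome, cfg, fq, _sam = sim
        total = sum(len(seq) for _n, seq, _q in svscan.iter_fastq(fq))
        genome_len = sum(genome.ref_lengths.values())
        assert abs(total / genome_len - cfg.depth) / cfg.depth < 0.05

    def test_truth_split_pairs_reconstruct_planted_junction_exactly(self, sim):
        _genome, _cfg, _fq, sam = sim
        sigs = svscan.extract_signatures(svscan.read_sam(sam))
        assert sigs, "expected split-read signatures across the inversion"
        for sig in sigs:
            assert sig.sv_type == "INV"
            assert (sig.endA[1], sig.endB[1]) == (600_000, 900_000)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ReadSimConfig(sub_rate=1.2).validate()
        with pytest.raises(ValueError):
            ReadSimConfig(depth=0).validate()


NOSNP = GenomeConfig(chromosomes=[("chr1", 1_200_000)], snp_density=0.0)
SV1 = SVSpec("INV", "chr1", 600_000, "chr1", 900_000)


class TestSimulateEmbryos:
    def test_no_recombination_gametes_copy_one_haplotype(self):
        genome = simgen.build_genome(NOSNP, seed=1)
        simgen.apply_sv(genome, SV1)
        cfg = EmbryoSimConfig(n_embryos=10_000, recombination_rate=0.0, seed=3)
        truths = simgen.simulate_embryos(genome, SV1, cfg)
        haps = set()
        for t in truths:
            segs = t.segments["chr1"]
            assert len(segs) == 1 and segs[0][:2] == (1, 1_200_000)
            haps.add(segs[0][2])
        carriers = sum(t.carrier for t in truths)
        sd = math.sqrt(10_000 * 0.25)
        assert abs(carriers - 5_000) <= 3 * sd
        assert haps == {"A", "B"}

    def test_crossover_counts_follow_poisson(self):
        genome = simgen.build_genome(NOSNP, seed=1)
        cfg = EmbryoSimConfig(n_embryos=10_000, recombination_rate=2.0, seed=5)
        truths = simgen.simulate_embryos(genome, SV1, cfg)
        counts = np.array([len(t.segments["chr1"]) - 1 for t in truths])
        lam = 2.0 * 1.2
        kmax = 8
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        expected = np.array(
            [stats.poisson.pmf(k, lam) for k in range(kmax)] + [stats.poisson.sf(kmax - 1, lam)]
        ) * len(counts)
        p = stats.chisquare(observed, expected).pvalue
        assert p > 0.01

    def test_aneuploidy_event_recorded(self):
        cfg = GenomeConfig(chromosomes=[("chr1", 600_000), ("chr22", 600_000)], snp_density=0.0)
        genome = simgen.build_genome(cfg, seed=1)
        sv = SVSpec("INV", "chr1", 200_000, "chr1", 400_000)
        ecfg = EmbryoSimConfig(n_embryos=5, aneuploidy_events=[(3, "chr22", 3)], seed=2)
        truths = simgen.simulate_embryos(genome, sv, ecfg)
        assert truths[3].copy_number["chr22"] == 3
        assert all(t.copy_number["chr22"] == 2 for i, t in enumerate(truths) if i != 3)

    def test_unknown_chromosome_in_event_rejected(self):
        genome = simgen.build_genome(NOSNP, seed=1)
        cfg = EmbryoSimConfig(aneuploidy_events=[(0, "chrZ", 3)], seed=0)
        with pytest.raises(ValueError, match="chrZ"):
            simgen.simulate_embryos(genome, SV1, cfg)

    def test_carrier_status_consistent_with_transmitted_haplotype(self):
        genome = simgen.build_genome(SMALL, seed=6)
        simgen.apply_sv(genome, SV1)
        cfg = EmbryoSimConfig(n_embryos=50, recombination_rate=2.0, seed=7)
        for t in simgen.simulate_embryos(genome, SV1, cfg):
            assert t.carrier == (t.transmitted_hap("chr1", SV1.posB) == "B")


@pytest.fixture(scope="module")
def dense_truths():
    cfg = GenomeConfig(
        chromosomes=[("chr1", 1_200_000)],
        snp_density=0.01,
        repeat_tracts={"chr1": (500_001, 700_000)},
    )
    genome = simgen.build_genome(cfg, seed=4)
    truths = simgen.simulate_embryos(
        genome, SV1, EmbryoSimConfig(n_embryos=1, recombination_rate=1.0, seed=6)
    )
    return genome, truths


class TestGenotypeEmbryos:
    def test_noiseless_genotypes_equal_truth(self, dense_truths):
        genome, truths = dense_truths
        cfg = EmbryoSimConfig(n_embryos=1, ado_rate=0, genotype_error=0, nocall_rate=0, seed=1)
        geno = simgen.genotype_embryos(truths, cfg, simgen.het_site_alleles(genome))[0]
        for key, truth_gt in truths[0].genotypes.items():
            assert geno.calls[key] == tuple(sorted(truth_gt))

    def test_ado_rate_recovered_at_het_sites(self, dense_truths):
        genome, truths = dense_truths
        cfg = EmbryoSimConfig(n_embryos=1, ado_rate=0.1, genotype_error=0, nocall_rate=0, seed=2)
        geno = simgen.genotype_embryos(truths, cfg, simgen.het_site_alleles(genome))[0]
        het_keys = [k for k, g in truths[0].genotypes.items() if g[0] != g[1]]
        assert len(het_keys) >= 2_000
        hom_observed = sum(
            1 for k in het_keys if geno.calls[k][0] == geno.calls[k][1]
        )
        n, p = len(het_keys), 0.1
        sd = math.sqrt(n * p * (1 - p))
        assert abs(hom_observed - n * p) <= 3 * sd

    def test_full_nocall_rate_blanks_everything(self, dense_truths):
        genome, truths = dense_truths
        cfg = EmbryoSimConfig(n_embryos=1, nocall_rate=1.0, seed=3)
        geno = simgen.genotype_embryos(truths, cfg)[0]
        assert all(v is None for v in geno.calls.values())


class TestCountsForCNV:
    def _genome(self):
        cfg = GenomeConfig(
            chromosomes=[("chr1", 1_000_000), ("chr2", 1_000_000)], snp_density=0.0
        )
        return simgen.build_genome(cfg, seed=1)

    def test_disomic_mean_matches_poisson_expectation(self):
        genome = self._genome()
        truths = simgen.simulate_embryos(
            genome, SVSpec("INV", "chr1", 400_000, "chr1", 600_000), EmbryoSimConfig(n_embryos=1, seed=1)
        )
        counts = simgen.counts_for_cnv(truths, genome, 20_000, 100.0, seed=2)["E1"]
        vals = [c for _c, _s, _e, c in counts]
        sd = math.sqrt(100.0 / len(vals))
        assert abs(np.mean(vals) - 100.0) <= 3 * sd

    def test_trisomic_to_disomic_ratio(self):
        genome = self._genome()
        sv = SVSpec("INV", "chr1", 400_000, "chr1", 600_000)
        cfg = EmbryoSimConfig(n_embryos=1, aneuploidy_events=[(0, "chr2", 3)], seed=4)
        truths = simgen.simulate_embryos(genome, sv, cfg)
        counts = simgen.counts_for_cnv(truths, genome, 20_000, 100.0, seed=5)["E1"]
        tri = np.mean([c for ch, _s, _e, c in counts if ch == "chr2"])
        dis = np.mean([c for ch, _s, _e, c in counts if ch == "chr1"])
        assert 1.4 <= tri / dis <= 1.6

    def test_zero_mean_count_gives_all_zeros(self):
        genome = self._genome()
        truths = simgen.simulate_embryos(
            genome, SVSpec("INV", "chr1", 400_000, "chr1", 600_000), EmbryoSimConfig(n_embryos=1, seed=1)
        )
        counts = simgen.counts_for_cnv(truths, genome, 20_000, 0.0, seed=6)["E1"]
        assert all(c == 0 for _c, _s, _e, c in counts)

    def test_too_coarse_bins_rejected(self):
        genome = self._genome()
        truths = simgen.simulate_embryos(
            genome, SVSpec("INV", "chr1", 400_000, "chr1", 600_000), EmbryoSimConfig(n_embryos=1, seed=1)
        )
        with pytest.raises(ValueError, match="20 bins"):
            simgen.counts_for_cnv(truths, genome, 100_000, 50.0, seed=0)
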