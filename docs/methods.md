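# Methods

marecs-kit is a desk-scale implementation of the two-stage MaReCs workflow
("Mapping Allele with Resolved Carrier Status") for preimplantation genetic
testing of structural rearrangements (PGT-SR), built around the case where one
breakpoint of an inversion or reciprocal translocation falls in satellite-like
heterochromatin that only a gapless (T2T-class) reference resolves. This note
records the models, the parameters that matter, the numerical choices, and what
the synthetic data does and does not show.

## The workflow

1. **Read QC** (`svscan.qc_reads`). Each long read is trimmed 50 bp at head and
   tail, then removed if its mean Phred score is ≤ 7 or its trimmed length is
   < 1000 bp. The quality rule is applied to the *mean* Phred; the upstream
   long-read filters this mirrors do not state mean vs per-base, and mean is the
   common long-read convention.
2. **SV detection** (`svscan`). Each primary + supplementary split-alignment
   pair yields one breakend signature. Orientation decides the type: same
   chromosome + opposite strands → INV; different chromosomes → TRA (breakend);
   same strand with a reference gap → DEL, with an overlap → DUP. Junction
   coordinates are normalized so that the rearranged interval is [posA, posB)
   — for an inversion the two junction families ("head-head" and "tail-tail")
   then vote for the same (posA, posB) pair and merge into one candidate.
   Signatures of one type with both ends within 50 bp (single linkage) form a
   candidate; DV is the number of distinct supporting reads, DR the number of
   other reads whose single alignment block contiguously spans a breakpoint
   ± 200 bp (a read that is both split and spanning counts only in DV).
   Breakpoints are refined to the lower median of the member junctions, which
   is exact on error-free truth alignments. Retention requires **DV > 4**,
   **DV/(DV+DR) > 10%**, and for events longer than **5 Mb** a karyotype
   whitelist match (chromosome + SV type + region overlap with ± 1 Mb slop,
   reflecting karyotype-band imprecision). The 50 bp tolerance, 200 bp span
   margin and lower-median tie-break are declared conventions; the published
   pipeline inherits equivalents silently from its SV caller.
3. **Breakpoint-anchored phasing** (`phaser`). Heterozygous SNPs are called
   from pileups in a ± 2 Mbp window per breakpoint: a site needs depth ≥ 10 and
   both top alleles at fraction ≥ 0.25 (thresholds declared; they replace a
   neural variant caller at desk scale; indels are ignored). hap1 — by
   convention the rearrangement-linked haplotype — is seeded by majority vote
   of the alleles observed on the SV-supporting reads themselves; ties stay
   unassigned. Assignments then propagate along a maximum-weight spanning
   forest of the SNP co-occurrence graph (edge weight |cis − trans| read
   support, edge sign = flip). "Same read or contig" is realized as this
   transitive read-graph phasing without assembly: the window (2 Mb) is two
   orders of magnitude longer than a read, so single molecules cannot span it.
   The per-SNP **margin** is the bottleneck (minimum) of the seed margin and
   the edge margins along the tree path: the weakest link bounds confidence.
   (A path *sum* was considered and rejected — it inflates confidence with
   distance and defeats margin-based filtering under noise.) Each breakpoint
   side (upstream/downstream) is usable iff ≥ 20 SNPs are assigned with
   positive margin; downstream stages ignore unusable sides.
4. **Liftover** (`liftover`). A UCSC chain-file parser (0-based half-open at
   the parser boundary, 1-based at the API), affine strand-aware position
   mapping, highest-scoring chain on overlap (UCSC semantics), and VCF
   transformation that carries hap1/hap2 labels through unchanged and reports
   every dropped site with a reason. Positions in inter-block gaps are lost —
   the same silent loss real assembly transitions show. Alleles are not
   complemented on minus-strand blocks; the bundled synthetic chains are all
   plus-strand, and a user lifting real minus-strand chains must handle allele
   orientation as with the standard UCSC tool.
5. **CNV screening** (`cnvcall`). Whole-chromosome calls only (the events this
   workflow gates on are whole-chromosome): per-bin ratios against a disomic
   baseline, then a chromosome is a gain at mean ratio ≥ 1.35, a loss at
   ≤ 0.65, no-call under 20 bins. Thresholds are declared conventions — the
   reference pipeline is a commercial black box. Single samples use an
   iteratively trimmed median baseline; cohorts (≥ 3 embryos) use the per-bin
   median across embryos, which stays correct even when a large fraction of
   one genome is aneuploid, followed by a per-sample rescale chosen to
   maximize the number of disomic chromosomes (ties to the gentlest rescale).
   With a 2-chromosome demo genome the single-sample baseline is genuinely
   ambiguous (a trisomy of one chromosome and a monosomy of the other explain
   the same counts); the cohort baseline resolves it. No GC correction —
   synthetic counts are GC-free; the interface leaves the hook. Karyotypes are
   ISCN-like with sex masked: `46,XN`, `47,XN,+22(×3)`, `45,XN,-18(×1)`
   (ASCII hyphen; the multiplication glyph is configurable).
6. **Linkage HMM** (`linkhmm`). Two hidden states: H1 (the embryo received the
   rearrangement-linked haplotype) and H2. Informative sites are those where
   the transmitted carrier-parent allele is identifiable: carrier parent
   heterozygous and phased, side usable, other parent homozygous, embryo
   genotype present. Transitions follow the Haldane map, switch probability
   0.5·(1 − e^(−2rd)) with r in Morgans/Mb (default 0.01 = 1 cM/Mb) and d the
   inter-SNP distance in Mb, floored at 1e−12 to keep the chain ergodic.
   Emissions sum over the drop/flip event space: with transmitted allele t and
   other-parent allele o the true genotype is {t, o}; with probability `ado`
   (default 0.1) one uniformly chosen allele drops and the survivor is read as
   homozygous; each reported allele then flips to the site's other allele with
   probability `error` (default 0.01). Missing genotypes are skipped, not
   imputed. A hemizygous mode (single transmitted allele; flip-only emission)
   covers X-linked cases in male embryos — the clinical handling of embryo sex
   is not specified by the source workflow, so the mode is a flag, not a
   default. Forward–backward and Viterbi run in log space (no underflow at
   ≥ 10⁴ sites, verified). The decision anchors on the SNP nearest the
   breakpoint — linkage to the breakpoint is the clinical question — with
   carrier iff P(H1) ≥ 0.95 there, non-carrier iff P(H2) ≥ 0.95, otherwise
   no-call; fewer than 10 informative SNPs is a no-call regardless. The HMM is
   this package's concretization: the source workflow states only that a
   likelihood-based HMM was used, so this is the minimal model consistent with
   that description, checked against exhaustive path enumeration in tests.

## The synthetic-data generator

`simgen` builds the study conditions; it is not tuned per test.

- **Genome.** Chromosomes are random sequence with one tandem-repeat tract
  each: 171 bp monomer copies (alpha-satellite-like) with 2% per-copy
  divergence. Het sites are planted at density 3.2e−4/bp on unique arms — the
  density implied by ~630 phaseable SNPs in a 2 Mbp breakpoint window on real
  data — and at 10% of that inside the tract. Coordinates are 1-based
  inclusive internally; SAM/VCF/BED conventions hold at I/O boundaries.
- **Rearrangements.** One haplotype (the carrier's) receives the SV; INV
  reverse-complements [posA, posB), DEL/DUP remove/duplicate it, TRA swaps
  chromosome tails. Each haplotype is represented as a segment map over
  reference coordinates, so truth alignments are exact by construction.
- **Reads.** Log-normal lengths (default mean 18 kb, shape 0.6 — a nanopore-
  like tail), default 28× depth, uniform substitution/insertion/deletion
  errors. Reads crossing a junction are emitted as primary + SA-tagged
  supplementary SAM records whose junction reference coordinates equal the
  planted breakpoint exactly; errors perturb bases and CIGARs within a
  segment, never the segment boundaries. The simulator replaces basecalling
  and alignment entirely; an external aligner can be swapped in on the SAM
  interface, but nothing depends on it.
- **Embryos.** Carrier-parent meioses with Poisson(r·L) crossovers at uniform
  positions (r = 0.01/Mb default), the other parent contributing a homozygous
  reference background; whole-chromosome aneuploidies as copy-number events;
  array genotyping noise exactly matching the HMM's emission model (no-call
  5%, ADO 10%, allele flip 1% by default). Aneuploidy affects bin counts only,
  not SNP genotypes — aneuploid embryos are excluded before linkage anyway,
  as in the clinical workflow. Carrier truth is evaluated at the arm-side
  breakpoint, the one linkage anchors on.
- **Scenario `pedigree1`** (the default demo and test condition): two 5 Mb
  chromosomes at 28×; a 1.8 Mb inversion on chrX with posA = 2,250,000 inside
  a 2.1 Mb repeat tract and posB = 4,050,000 in the unique arm — the topology
  of a pericentric X inversion scaled to desk size; 7 embryos including one
  trisomy-22-analogue and one monosomy-22-analogue; a constant-shift chain
  pair to an "array" coordinate system standing in for the assembly switch
  before linkage. On this geometry the 2 Mb window upstream of posA lies
  entirely in the repeat tract, where SNPs are ~31 kb apart — beyond what
  18 kb reads can bridge — so that side fails side assessment for the same
  mechanistic reason centromeric flanks fail on real data, while both arm-side
  windows phase completely.

**What passing does not show.** The generator has uniform base composition, no
GC or mappability structure, no real alpha-satellite homology (a truth-aligned
simulator cannot probe mapping ambiguity in satellite arrays — that burden sits
with the aligner and reference, not this pipeline), no segmental aneuploidy or
mosaicism, no WGA amplification bias beyond i.i.d. ADO/error, and exact
junction coordinates in the truth alignments (±10 bp recovery under 10% read
error demonstrates robustness of clustering and medians, not of an aligner).
Results on real nanopore data depend on the upstream aligner and variant
quality in ways these tests cannot certify.

## Problem sizes and determinism

The shipped tests run the full pedigree1 scenario twice (error 0 and 10%;
about 10 Mb of genome at 28×, ~16k reads), a 200-embryo linkage cohort on a
32-SNP panel, 10,000-meiosis distributional checks, and exhaustive-enumeration
oracles up to 12 sites — sizes chosen so the whole suite completes in a few
minutes on one CPU while every stage is still exercised end to end. All
randomness flows from explicit integer seeds through `numpy` SeedSequence
spawning, so identical seeds give byte-identical FASTQ/SAM/VCF/TSV outputs;
rerunning the pipeline with the same config reproduces every decision in the
report.

## Known limitations

- Insertions are not detected (no soft-clip signature extraction), and
  sub-chromosomal CNV is out of scope by design.
- The het-SNP caller is a threshold pileup caller; it will call occasional
  spurious sites at 10% read error (they carry low margins and are filtered by
  margin-based consumers).
- `normalize_counts` on a single sample cannot disambiguate reciprocal
  baseline explanations when most of a small genome is aneuploid; use the
  cohort path for screening.
- Chain liftover does not complement alleles across minus-strand blocks and
  does not compose multi-step lifts.
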