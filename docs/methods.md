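# Methods

`minicircler` reconstructs highly fragmented ("minicircle") mitochondrial
genomes from whole-genome shotgun reads. A minicircle genome consists of
K small circular chromosomes (here ~1.1–3.1 kb), each carrying one to a
few of the 37 canonical mitochondrial genes plus a non-coding control
region (CR) whose sequence motifs are largely shared across all circles of
one individual. That shared CR is both the central obstacle (short-read
assemblers collapse or chimerize it) and the central opportunity: reads
from every circle pile onto any one circle's CR, so coverage itself
becomes a signal for fragmentation, and the CR/coding junction acts as an
in-silico anchor that captures one junction-crossing read set per circle.

## Pipeline model and assumptions

The workflow assumes paired-end Illumina-style reads (150 bp, ~400 bp
inserts) from total DNA, a set of protein bait sequences for the 13
mitochondrial protein-coding genes (PCGs), and nucleotide references for
rRNA/tRNA genes. Stages:

1. **Read preparation.** Exact duplicate pairs are removed; each mate
   loses its first 5 nt; 3'-terminal bases with phred < 28 are trimmed
   with a 1 nt window; a pair is discarded whole if either mate falls
   below 75 nt. A seeded per-pair Bernoulli subsample (default 10%)
   guards production-size libraries against numts and index-swapping
   contaminants. Orphan mates are never retained: the extension stage
   leans on intact pair information, so dropping the pair is both simpler
   and safer than keeping half of it.
2. **Baited seed assembly.** A mate joins a bait's pool when a 5-aa exact
   seed plus local Smith–Waterman (BLOSUM62, −11/−1) reaches 40 bits
   (Karlin–Altschul conversion with gapped-BLOSUM62 λ=0.267, K=0.041).
   Recruitment is pair-level and pools are assembled with a greedy exact
   suffix–prefix overlap assembler (k=31) with column-majority consensus.
   A raw-score threshold of 40 would admit hundreds of random control-region
   reads per run (expect ≈ K·m·n·e^(−λS) hits); in bits the same number is
   astronomically small, which is why the threshold is interpreted on the
   bit scale.
3. **Iterative mapping extension.** Reads are mapped each round by k-mer
   (21) diagonal seeding plus a maximal-subarray match scan (+1/−3) that
   clips mismatching tails; a placement needs ≥40 nt at ≥90% identity.
   Each contig end grows by a consensus over overhanging reads: ≥3 reads
   per column and a ≥70% majority, with reads dropped from later columns
   once they disagree. When the raw pile-up is contested — which happens
   systematically where the conserved CR core ends and circle-specific
   sequence begins — the call is restricted to *pair-confirmed* reads,
   i.e. mates whose partner placed on the contig in proper orientation at
   an insert distance within 4 sd. Only the contig's own circle has
   partners anchored in nearby unique sequence, so pair confirmation is
   what carries extension across the shared core without chimerism. If
   neither vote is decisive the end stalls; the opposite end closes the
   circle instead.
4. **Circularity.** A contig whose two ends have wrapped carries an exact
   duplicated stretch; the longest prefix==suffix border is found by a
   KMP failure function and must exceed 50 bp (i.e. ≥51). Because a
   contested consensus can leave one or two junk bases at a tip and an
   exact border check is all-or-nothing, the in-loop detector first
   tolerates trimming up to 5 bases from either tip before the exact
   test. Collapsed circles receive one column-majority polishing pass
   over all mapped reads, which removes seed-inherited consensus errors
   so that independently seeded assemblies of the same chromosome
   converge byte-identically.
5. **Coverage boundary.** The per-base depth profile of an extended
   contig is smoothed (101 nt moving mean), split at the geometric mean
   of the two depth modes (1-D 2-means; the high mode is seeded at the
   profile maximum because the conserved core can occupy well under 10%
   of the circle), segments shorter than 150 nt are absorbed, and each
   boundary is sharpened against the unsmoothed profile. The high/low
   ratio estimates the number of circles sharing the core; the high→low
   transition nearest upstream of a coding start is the CR/coding
   boundary.
6. **Boundary priming ("bioinformatic PCR").** A 250 bp window ending at
   that boundary is cut from the anchor contig; the full pool is scanned
   for mates whose alignment reaches (within 8 nt of) the window's 3'
   terminus and continues ≥15 nt beyond it. The tolerance matters: the
   detected boundary can sit a base or two outside the conserved core,
   and foreign-circle reads can only align up to the core's edge. The
   harvested reads are assembled; contigs are kept when the mean
   coverage of their junction-supported core (columns ≥ max(3, 25% of
   peak)) reaches 20×; the 5' prefix shared at ≥90% column identity is
   trimmed off; the remaining circle-specific tails are extension seeds.
   At 50× simulated depth this ≥20× floor is deliberately harsh: a
   junction-anchored contig's coverage is roughly 0.5–0.7 of the circle's
   genomic coverage, so circles at the low end of the copy-number range
   fail it. That is why the pipeline does not rely on this stage alone.
7. **Reference rescue.** rRNA and tRNA circles have no protein bait, so
   the pipeline also seeds extension from nucleotide recruitment against
   the supplied rRNA/tRNA reference set. Redundant seeds (already
   contained in a finished circular chromosome at ≥95% identity) are
   skipped; redundancy is never judged against linear fragments, which
   would otherwise block the proper seed.
8. **Annotation and typing.** PCGs are called by six-frame translated
   local alignment (≥50% aa identity over ≥70% of the reference),
   rRNA/tRNA by nucleotide alignment (≥80% identity over the reference),
   on the doubled sequence so calls may wrap the origin; PCG calls are
   nudged onto in-frame start/stop codons of the invertebrate
   mitochondrial code (NCBI table 5). Circles are rotated and
   strand-flipped into a canonical form anchored at the longest gene.
   Conserved CR blocks are found by cross-mapping all circles against a
   reference circle (≥50 nt, ≥80% identity, e-value proxy ≤1e−20 from an
   ungapped +1/−2 Karlin–Altschul parameterization). CR columns where a
   minor allele exceeds 20% of mapped reads become IUPAC ambiguity
   codes; coding columns are never masked. Circles with byte-identical
   coding regions are collapsed to the best-covered representative.
9. **Comparison.** A circle's arrangement is its circular word of
   (gene, strand) symbols; the canonical key is the lexicographically
   minimal rotation (Booth's algorithm) of the word or its reflected
   (order-reversed, strand-flipped) reading. Sharing between species is
   the multiset intersection of keys — identical content *and* circular
   order *and* relative strands. Shared-circle counts are sensitive to
   this definition (looser readings that ignore strand or tRNA placement
   give larger counts), so a content-only mode exists behind a flag for
   sensitivity analysis.

## Synthetic data generator

`simulate_genome` emulates the architecture the pipeline targets: K
circles (default 17), each PCG/rRNA on its own circle, two tRNA-only
circles, 1–4 genes per circle, lengths confined to 1,100–3,100 bp, coding
~65% AT. The CR is a conserved core — two motif blocks (120 + 80 nt)
shared *verbatim* across circles and placed adjacent — flanked by
circle-specific spacers (upstream 40–460 nt, downstream 60–140 nt, total
100–600 nt). Identical-not-similar blocks make the coverage-multiplication
law exact and testable; adjacency matters because read anchoring (40 nt
minimum) ramps coverage at every conserved/unique edge, and splitting the
core would depress the CR/coding ratio well below the circle count.
The downstream spacer range reproduces the ~31–139 nt circle-specific
tails the junction harvest is expected to recover. Per-circle copy number
is log-uniform on 0.5–2.0×. `simulate_reads` draws pairs per circle at
depth × copy-number coverage (Poisson count), fragment length N(400, 40),
uniform start with wrap across the origin, 0.2% substitution error, and
occasional low-quality 3' tails to exercise trimming. PCG sequences are
stop-free random ORFs under table 5 whose translations are emitted as the
bait set; tRNA/rRNA genes come from a bundled *synthetic* placeholder set
(random AT-biased sequences of realistic lengths, not real genes —
structural tRNA identification is out of scope).

What the generator does **not** emulate: indel sequencing errors, PCR
duplicates beyond exact copies, numts, heteroplasmy, inter-circle CR
divergence outside the conserved blocks (spacers are fully random), or
real tRNA/rRNA sequence structure. Passing tests therefore demonstrate
the pipeline's logic — recruitment, extension across a shared core,
circularization, canonicalization, comparison — not its robustness to
numt contamination or to CRs whose "conserved" motifs have drifted apart.

## Test and verification conditions

Desk-scale checks simulate at depth 50× with the defaults above and run
the pipeline with subsampling disabled: the simulated library *is* the
working fraction (the 10% rule exists to tame ~10⁷-read production
libraries, and 10% of a 50× library would leave 5×, below the extension
consensus minimum). End-to-end recovery is asserted for K ∈ {5, 10, 17}:
exactly K circular chromosomes, each rotation/strand-equivalent to its
simulated counterpart at ≥99.5% identity (IUPAC-aware) with the correct
gene content and order. The coverage-multiplication law (ratio ≈ K ±25%)
is asserted under equal per-circle copy numbers, which is the law's own
premise: with copy-number variation the ratio estimates
K · (mean copy)/(anchor's copy), which is why real libraries with uneven
circle stoichiometry show ratios well below K. These problem sizes complete in
roughly one to three minutes per K on a single core.

## Numerical and design choices

- Mapping is substitution-oriented (diagonal seeding, no gapped
  extension); gapped identity checks elsewhere use edlib. Adequate for
  Illumina-style error profiles; not for long-read data.
- Consensus ties truncate extension rather than guess; a 3-vote column
  must be unanimous (ceil(0.7·3) = 3).
- Extension is capped at read_len − anchor (110 nt) per end per
  iteration, at 100 iterations, and at a 10 kb runaway guard.
- The terminal-repeat test is exact; ambiguity codes compare as
  mismatches there.
- Canonical rotation tie-breaks: longest gene, then label, then
  position; unannotated circles fall back to the lexicographically
  minimal rotation of the lexicographically smaller strand.
- Duplicate collapsing demands *exact* coding equality after
  canonicalization (near-identical coding regions stay distinct); the
  polishing pass is what makes this exactness attainable.
- AT% counts ambiguity codes in the denominator only.
- All randomness flows through explicitly seeded NumPy generators; equal
  inputs and seeds give byte-identical outputs, including FASTA/GFF3.

## Known limitations

- Circles whose entire coding complement is missing from the bait and
  reference sets are only reachable through the junction-harvest stage,
  and there only when their junction coverage clears the 20× floor.
- Short, fast-evolving genes (the real atp8/nad6 problem) will drop below
  the translated-search thresholds for sufficiently diverged baits; this
  is expected behavior, not a defect, and mirrors what homology-based
  annotation can deliver.
- The conserved-prefix trimmer assumes junction contigs share a common
  5' anchor region; CRs with little cross-circle conservation would
  defeat the whole boundary-priming strategy.
- Linear (non-circularizable) contigs are emitted flagged rather than
  force-circularized; chromosomes whose control region cannot be
  assembled through stay linear, as they should.
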