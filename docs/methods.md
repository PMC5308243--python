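# Methods

## Gene model and coordinates

All genomic coordinates are 0-based half-open; GFF3 (1-based inclusive) and
GenBank locations are converted once, at the I/O boundary. Exon and CDS
lists are stored in transcript (5′→3′) orientation, so minus-strand genes
list the acceptor-proximal exon first; every downstream computation is
strand-agnostic as a consequence, and a strand-symmetry invariant
(reverse-complementing a locus and flipping all annotations changes no
intron classification) is enforced by the test suite. When a gene has
several transcripts, the longest-CDS transcript is analyzed by default —
the analysis operates on one structure per gene — with an option to keep
all. Models whose CDS length is not a positive multiple of 3 are flagged
incomplete but not dropped. Non-canonical splice dinucleotides (anything
other than GT..AG) warn rather than error, so imperfect annotations remain
loadable. Translation uses the standard genetic code only (nuclear
arthropod genes).

## Intron phases and the boundary signature

With `L` the number of coding nucleotides strictly 5′ of an intron, phase
is `L mod 3` and the interrupted codon index is `⌊L/3⌋`. For phase-0
introns this index names the codon immediately 3′ of the intron, which
keeps residue offsets comparable across phases. Introns entirely 5′ of the
first coding nucleotide are UTR5, entirely 3′ of the last are UTR3; both
carry phase `NA` and are excluded from phase statistics but retained in
records and diagrams.

"Near the cleavage site" is operationalized as
`|⌊L/3⌋ − signal_len| ≤ w` with default `w = 3` residues. The known gene
families motivate this default: signal-terminal introns sit at offset 0,
and the ICK families' propeptide-internal intron sits 1–3 residues past the
cleavage site. No authoritative numeric window exists for "near", so `w` is
configurable, the per-intron offset is always reported (any other window
can be applied post hoc), and the precursor-region label distinguishes
signal-terminal from propeptide-internal cases. When several phase-1
introns fall in-window the smallest `|offset|` wins, ties breaking to the
smaller ordinal. Widening `w` can only add signatures (monotonicity,
tested).

## Phase-frequency test

Observed phase counts are compared to reference proportions by a two-sided
exact multinomial test for totals ≤ 30 and a χ² goodness-of-fit (df = 2)
above. The exact p-value sums the probability of every outcome triple whose
probability does not exceed the observed outcome's; a relative tolerance of
1e−9 on that comparison absorbs floating-point jitter on exact ties (e.g.
under the uniform reference). The switch point of 30 keeps full enumeration
cheap where it matters — cohorts in this field are tens of genes. At the
switch point the two paths agree to within about 0.08 absolute in p; this
residual reflects the different outcome orderings (probability-mass versus
Pearson statistic), not an implementation defect, and shrinks with n.

Reference sets: `nonsecretory_human` (0.50, 0.30, 0.20) and
`secretory_human` (0.3136, 0.499, 0.188; phase-1 excess), both renormalized
to sum exactly to 1, plus `uniform` and user-supplied `custom:p0,p1,p2`.
These are literature summaries over external proteome surveys, used only as
null proportions — the package never recomputes them from proteome data.

## Boundary permutation test

The statistic is the number of genes whose boundary-signature call is true.
Under the null each gene keeps its coding-intron count, but every intron's
insertion junction is redrawn uniformly over the `3·precursor_len − 1`
intra-CDS nucleotide junctions; the junction determines position and phase
jointly, so both are randomized — the hypothesis under test is the joint
positional-and-phase enrichment. The p-value uses the add-one estimator
`(1 + #{null ≥ observed}) / (1 + n_perm)`, which never returns 0 and is
valid for discrete statistics. The seed is a required, logged input. Each
gene draws from its own RNG stream keyed by (seed, crc32(gene_id)), making
the result exactly invariant to input ordering while staying reproducible.

The test's size is verified by simulation: 500 junction-uniform null
cohorts of 40 genes (1–3 coding introns each, signal peptides 18–25
residues, precursors 60–120 residues) at `n_perm = 199`, asserting the
rejection rate at α = 0.05 inside the 99 % binomial band. The cohort size
was chosen by a Poisson-binomial calculation so that the discrete null
distribution is spread enough for the nominal level to be approachable;
very small cohorts make any count statistic conservative.

## ICK and CSαβ motifs

The scorpion-venom ICK consensus is matched strictly:
`C X{6} C X{4} D C C X{2,4} [KR] C X{3} G X{4,6} C [KR]`, leftmost,
non-overlapping by default (these peptides are single-domain); the
conserved D, G and K/R positions accept exactly those residues — the
consensus is a consensus, not a profile. Ring membership is read as the two
backbone segments C1..C2 and C4..C5 (cysteines included) closed by the
C1–C4 and C2–C5 bridges; this is the unique reading under which the
admissible spacers give ring sizes exactly 13–15, and the derivation is
re-checked by enumeration in the tests rather than assumed. Since the
C1..C2 segment is fixed (8 residues) the ring size is `11 + s` where `s`
is the C4-side spacer (2–4); the pre-C6 spacer does not enter the ring.
CSαβ reporting is positional only: all overlapping `CX₃C` and `CXC`
windows, plus a flag for the helix-before-strand arrangement (some `CX₃C`
preceding some `CXC`).

## Promoter modules

Motifs are IUPAC consensus strings scanned on both strands at every
position; an `N` in the promoter (masked base) matches only an `N` in the
motif. Sharing between promoters is the Jaccard index over binary motif
presence — the biological argument is about which key sites a promoter has,
not how many copies — with 0 defined for two motif-free promoters. The
shipped `data/example_motifs.tsv` is explicitly illustrative (textbook
C/EBP-family, TATA and CAAT consensi), not a curated venom-gland module.

## Synthetic data

The generator builds genes from the inside out: a uniform random
sense-codon CDS (stop appended), UTRs and flanks, then introns inserted at
exactly the junction `3·codon + phase`, each with GT..AG termini on the
coding strand; minus-strand genes are emitted as the reverse-complemented
locus with flipped coordinates. Ground truth (phases, interrupted codons,
precursor regions, offsets, signature flags) is computed from the spec at
generation time, never by running the analysis code, so round-trip tests
are genuine two-route checks. Everything is deterministic under the spec
seed.

What the generator emulates: exon–intron topologies, reading-frame
placement, UTR introns, strand, canonical splice sites, SP/PP/MP
partitions. What it does not: codon bias, hydrophobic signal-peptide
composition, splice-site context beyond the GT..AG dinucleotides, intron
length distributions of any particular genome (lengths default to
60–2000 nt uniform), or evolutionary history. Passing tests therefore
demonstrate correctness of the structural analysis, not performance on
noisy real annotations — with real data the annotations themselves are the
accuracy bottleneck, and they enter this package as trusted inputs.

The curated 12-gene cohort (`paper_style_cohort`) fixes the family mix to
five CSαβ genes (two with a 5′-UTR intron, one long-chain KTx with a second
phase-1 intron in the mature region), three ICK genes (propeptide phase-1
at offsets +2, plus a long phase-2 intron at the mature N-terminus), one
SP–MP–PP antimicrobial peptide gene, two multi-intron protease genes (all
three phases in the mature region) and one Kunitz-type inhibitor gene with
an extra mature-region phase-1 intron — every gene carrying the boundary
signature, as in the secreted venom families this mirrors.

Test problem sizes: the oracle-equivalence suite runs 1000 random genes
(both strands, 1–6 introns, optional UTR introns) with intron lengths
drawn from 60–300 nt, and round-trip suites use cohorts of 60–120 genes;
these sizes give full coverage of the branch structure (every
phase × region × strand combination many times over) while keeping the
suite fast.

## Known limitations

- Signal peptides, propeptides and mature spans are inputs; no sequence-
  based prediction is attempted.
- The exact multinomial test enumerates outcome triples; it is not meant
  for totals far beyond the n ≤ 30 switch (the χ² path covers those).
- The ICK matcher is strict; natural sequences deviating from the printed
  consensus (e.g. E for D) will not match — by design, with overlapped
  scanning and user-supplied relaxed patterns as the escape hatch.
- Diagrams are schematics: box widths are proportional to residue counts
  but intron connectors are fixed-width and UTR introns are drawn at the
  UTR/feature junction rather than to base-pair scale.
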