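# intronsig

Exon–intron architecture analysis of secretory peptide genes: intron-phase
classification, mapping of introns onto precursor-protein regions, and
detection of the **phase-1 intron at the signal-peptide cleavage boundary**
— the gene-structure signature of exon shuffling between signal-donating
and mature-peptide-donating genes.

The package is aimed at molecular-evolution work on secreted peptide gene
families (the motivating system is scorpion venom: CSαβ and ICK neurotoxins,
α-helical antimicrobial peptides, proteases and Kunitz-type protease
inhibitors), where structurally unrelated families share a common phase-1
intron near the end of the signal peptide.

## The analysis in brief

For an intron with `L` coding nucleotides 5′ of it, the **phase** is
`L mod 3` (phase 0 between codons, phase 1 after the first nucleotide of a
codon, phase 2 after the second), and the **interrupted codon** has residue
index `⌊L/3⌋`. Given a precursor annotation (signal peptide of `s` residues,
propeptide/mature spans), each coding intron gets an offset
`⌊L/3⌋ − s` from the cleavage site; a gene carries the **boundary
signature** when some phase-1 intron has `|offset| ≤ w` (default window
`w = 3` residues).

The statistical layer provides an exact multinomial / χ² goodness-of-fit
test of observed phase counts against literature reference proportions
(human non-secretory ≈ 50/30/20 for phases 0/1/2; human secretory
≈ 31.4/49.9/18.8, i.e. a phase-1 excess), and a permutation test of
boundary clustering whose null redraws each intron's insertion junction
uniformly over the `3·precursor_len − 1` intra-CDS junctions.

Also included: a strict matcher for the scorpion-venom ICK consensus
`C-X₆-C-X₄-D-C-C-X₂₋₄-K/R-C-X₃-G-X₄₋₆-C-K/R` (reporting cysteine positions,
C1–C4/C2–C5/C3–C6 connectivity and macrocycle ring size, which the
consensus constrains to 13–15 residues), the CSαβ `CX₃C`/`CXC` motif pair,
an IUPAC promoter-motif scanner with Jaccard module-sharing scores, a
ground-truth synthetic gene generator, and gene-structure diagrams
(text/SVG).

## Worked example

Generate the packaged 12-gene cohort that reproduces the classic secretory
venom-gene topologies, then annotate it:

```bash
intronsig simulate --paper-style --seed 11 --out cohort
intronsig annotate --gff cohort/genes.gff3 --fasta cohort/loci.fasta \
    --annotations cohort/precursors.tsv --out results
# 12/12 genes with the boundary phase-1 signature (fraction 1.000)
```

`results/introns.tsv` holds one intron per row:

```
gene_id         ordinal donor acceptor length region phase L  interrupted_codon_index precursor_region offset_from_cleavage
csab_kctx_a     1       177   249      72     CODING 1     67 22                      MATURE           0
csab_kctx_utr5  1       80    290      210    UTR5   NA    NA NA                      UTR5             NA
csab_kctx_utr5  2       404   499      95     CODING 1     64 21                      MATURE           0
```

The first gene's single intron is phase 1 and interrupts codon 22 — exactly
the signal-peptide cleavage site (offset 0). Structure schematics make the
shared architecture obvious:

```
intronsig diagram --gff cohort/genes.gff3 --fasta cohort/loci.fasta \
    --annotations cohort/precursors.tsv
# csab_kctx_a       [5'UTR][SP]--i(1)--[MP][3'UTR]
# csab_kctx_utr5    [5'UTR]--i(NA)--[SP]--i(1)--[MP][3'UTR]
```

Is the clustering at the boundary more than chance? On this cohort the
permutation test (`intronsig permtest ... --nperm 9999 --seed 1`) reports
`observed: 12` signature genes against a null mean of `0.60`, with
`p_value: 0.0001` — the add-one floor at 9999 permutations. The
phase-frequency test (`intronsig enrich`) counts 2/15/5 coding introns by
phase and rejects the non-secretory 50/30/20 reference with an exact
multinomial `p ≈ 4.6e-05`: the phase-1 excess expected of secretory genes.

All subcommands: `annotate`, `enrich`, `permtest`, `motif`, `promoter`,
`simulate`, `diagram`, `report` (the last writes a single JSON document
combining all sections). The same functionality is available as a library
(`import intronsig`).

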