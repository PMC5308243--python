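"""Synthetic secretory-peptide gene models with fully known ground truth.

Every generated gene is built outward from its precursor protein: a random
sense-codon CDS (no internal stops), flanked by untranslated regions, with
introns inserted at exactly the nucleotide junctions implied by a requested
(codon index, phase) pair. Each intron gets canonical GT..AG termini on the
coding strand; minus-strand specs emit the reverse-complemented locus with
coordinates flipped accordingly. Because intron placement is specified in
reading-frame terms, the generator knows every downstream answer — phases,
interrupted codons, precursor regions, boundary-signature flags — before any
analysis code runs, which is what makes it a usable oracle.

Signal peptides are sampled like any other codons (no hydrophobicity
modelling): no pipeline stage reads residue chemistry, so structural realism
stops at the exon-intron architecture. Intron lengths default to the
60-2000 nt range typical of compact arthropod venom peptide genes.

:func:`paper_style_cohort` returns a curated 12-gene set reproducing the
classic topologies of secreted venom peptide families: five CSalpha/beta
toxin genes (two with an extra 5'-UTR intron, one long-chain KTx with a
second phase-1 intron in the mature region), three ICK genes (short phase-1
intron inside the propeptide adjacent to the signal, long phase-2 intron at
the mature N-terminus), one SP-MP-PP antimicrobial peptide gene, two
multi-intron protease genes and one Kunitz-type inhibitor gene — all
carrying the boundary phase-1 signature.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .models import GeneModel, GenomicInterval, PrecursorAnnotation
from .io import translate_cds, write_gff3, write_precursor_annotations
from .promoter import IUPAC, IupacMotif, scan_promoter

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(BASES, repeat=3)
    if "".join(c) not in STOP_CODONS
)
MIN_INTRON_LEN = 10
DEFAULT_INTRON_LEN_RANGE = (60, 2000)


@dataclass
class SyntheticGeneSpec:
    """Blueprint for one synthetic gene; all randomness flows from ``seed``."""

    gene_id: str
    signal_len: int = 22
    precursor_len: int = 80
    propeptide_spans: list[tuple[int, int]] = field(default_factory=list)
    mature_spans: list[tuple[int, int]] = field(default_factory=list)
    #: (target codon index, phase, intron length nt), transcript order.
    intron_specs: list[tuple[int, int, int]] = field(default_factory=list)
    #: optional (offset nt into the 5'UTR, intron length nt).
    utr5_intron: tuple[int, int] | None = None
    strand: str = "+"
    utr5_len: int = 60
    utr3_len: int = 60
    flank_len: int = 50
    seed: int = 0

    def junctions(self) -> list[int]:
        """Coding-nucleotide junctions (L values) implied by the intron specs."""
        return [3 * codon + phase for codon, phase, _ in self.intron_specs]

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.signal_len < 1 or self.precursor_len <= self.signal_len:
            raise ValidationError(f"{self.gene_id}: bad signal/precursor lengths")
        js = self.junctions()
        for j, (codon, phase, ilen) in zip(js, self.intron_specs):
            if phase not in (0, 1, 2):
                raise ValidationError(f"{self.gene_id}: bad phase {phase}")
            if not (1 <= j <= 3 * self.precursor_len - 1):
                raise ValidationError(
                    f"{self.gene_id}: intron at codon {codon} phase {phase} "
                    "falls outside the CDS"
                )
            if ilen < MIN_INTRON_LEN:
                raise ValidationError(f"{self.gene_id}: intron length {ilen} too short")
        if any(b <= a for a, b in zip(js, js[1:])):
            raise ValidationError(f"{self.gene_id}: intron junctions must strictly increase")
        if self.utr5_intron is not None:
            off, ilen = self.utr5_intron
            if not (0 < off < self.utr5_len):
                raise ValidationError(f"{self.gene_id}: UTR5 intron offset outside the UTR")
            if ilen < MIN_INTRON_LEN:
                raise ValidationError(f"{self.gene_id}: UTR5 intron too short")


@dataclass
class GroundTruth:
    """Per-gene answers the pipeline must reproduce exactly."""

    gene_id: str
    protein: str
    #: per intron: ordinal, region, phase (None for UTR), interrupted_codon_index,
    #: precursor_region, offset_from_cleavage.
    introns: list[dict]
    has_boundary_signature: bool
    window: int


@dataclass
class SyntheticGene:
    spec: SyntheticGeneSpec
    model: GeneModel           # sequence attached
    annotation: PrecursorAnnotation
    truth: GroundTruth

    @property
    def locus_id(self) -> str:
        return self.model.seq_id


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def _intron_seq(rng: np.random.Generator, length: int) -> str:
    return "GT" + _random_seq(rng, length - 4) + "AG"


def generate_gene(spec: SyntheticGeneSpec, window: int = 3) -> SyntheticGene:
    """Materialize a spec into a locus, gene model, annotation and truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    codon_idx = rng.integers(0, len(SENSE_CODONS), spec.precursor_len)
    cds = "".join(SENSE_CODONS[i] for i in codon_idx)
    cds += STOP_CODONS[rng.integers(0, 3)]
    protein = translate_cds(cds)

    utr5 = _random_seq(rng, spec.utr5_len)
    utr3 = _random_seq(rng, spec.utr3_len)
    transcript = utr5 + cds + utr3

    # (transcript position, intron sequence), transcript order.
    inserts: list[tuple[int, str]] = []
    if spec.utr5_intron is not None:
        off, ilen = spec.utr5_intron
        inserts.append((off, _intron_seq(rng, ilen)))
    for j, (_, _, ilen) in zip(spec.junctions(), spec.intron_specs):
        inserts.append((spec.utr5_len + j, _intron_seq(rng, ilen)))

    flank5 = _random_seq(rng, spec.flank_len)
    flank3 = _random_seq(rng, spec.flank_len)

    # Assemble the plus-sense locus and record exon coordinates.
    parts = [flank5]
    exon_coords: list[tuple[int, int]] = []   # genomic, plus-sense
    exon_tpos: list[tuple[int, int]] = []     # transcript coordinates per exon
    g = len(flank5)
    prev_t = 0
    for tpos, iseq in inserts + [(len(transcript), "")]:
        seg = transcript[prev_t:tpos]
        parts.append(seg)
        exon_coords.append((g, g + len(seg)))
        exon_tpos.append((prev_t, tpos))
        g += len(seg)
        if iseq:
            parts.append(iseq)
            g += len(iseq)
        prev_t = tpos
    parts.append(flank3)
    locus = "".join(parts)

    # CDS genomic segments: transcript CDS range intersected with each exon.
    cds_t0, cds_t1 = spec.utr5_len, spec.utr5_len + len(cds)
    cds_coords = []
    for (gs, ge), (ts, te) in zip(exon_coords, exon_tpos):
        lo, hi = max(ts, cds_t0), min(te, cds_t1)
        if lo < hi:
            cds_coords.append((gs + (lo - ts), gs + (hi - ts)))

    seq_id = f"{spec.gene_id}_locus"
    if spec.strand == "-":
        from Bio.Seq import Seq
        L = len(locus)
        locus = str(Seq(locus).reverse_complement())
        flip = lambda se: (L - se[1], L - se[0])
        exon_coords = [flip(se) for se in exon_coords]
        cds_coords = [flip(se) for se in cds_coords]
    exons = [GenomicInterval(seq_id, s, e, spec.strand) for s, e in exon_coords]
    cds_segments = [GenomicInterval(seq_id, s, e, spec.strand) for s, e in cds_coords]

    model = GeneModel(
        gene_id=spec.gene_id, seq_id=seq_id, strand=spec.strand,
        exons=exons, cds_segments=cds_segments, sequence=locus,
    )
    annot = PrecursorAnnotation(
        gene_id=spec.gene_id, signal_len=spec.signal_len,
        precursor_len=spec.precursor_len,
        propeptide_spans=list(spec.propeptide_spans),
        mature_spans=list(spec.mature_spans),
    )
    truth = _ground_truth(spec, annot, protein, window)
    return SyntheticGene(spec=spec, model=model, annotation=annot, truth=truth)


def _ground_truth(
    spec: SyntheticGeneSpec, annot: PrecursorAnnotation, protein: str, window: int
) -> GroundTruth:
    introns = []
    ordinal = 0
    if spec.utr5_intron is not None:
        ordinal += 1
        introns.append({
            "ordinal": ordinal, "region": "UTR5", "phase": None,
            "interrupted_codon_index": None, "precursor_region": "UTR5",
            "offset_from_cleavage": None,
        })
    signature = False
    for codon, phase, _ in spec.intron_specs:
        ordinal += 1
        offset = codon - spec.signal_len
        if phase == 1 and abs(offset) <= window:
            signature = True
        introns.append({
            "ordinal": ordinal, "region": "CODING", "phase": phase,
            "interrupted_codon_index": codon,
            "precursor_region": annot.region_of(codon),
            "offset_from_cleavage": offset,
        })
    return GroundTruth(
        gene_id=spec.gene_id, protein=protein, introns=introns,
        has_boundary_signature=signature, window=window,
    )


# ---------------------------------------------------------------------------
# Cohorts


def paper_style_cohort(seed: int = 0, strand_mix: bool = False) -> list[SyntheticGene]:
    """The curated 12-gene set of classic secretory venom gene topologies."""
    rng = np.random.default_rng(seed)

    def s(**kw) -> SyntheticGeneSpec:
        kw.setdefault("seed", int(rng.integers(2**31)))
        if strand_mix:
            kw.setdefault("strand", "+-"[int(rng.integers(0, 2))])
        return SyntheticGeneSpec(**kw)

    specs = [
        # CSalpha/beta toxins: boundary phase-1 intron at the signal end.
        s(gene_id="csab_kctx_a", signal_len=22, precursor_len=59,
          intron_specs=[(22, 1, 72)]),
        s(gene_id="csab_sctx_b", signal_len=19, precursor_len=85,
          intron_specs=[(19, 1, 650)]),
        # Short-chain KTx with an extra 5'-UTR intron.
        s(gene_id="csab_kctx_utr5", signal_len=21, precursor_len=49,
          intron_specs=[(21, 1, 95)], utr5_intron=(30, 210), utr5_len=80),
        # Defensin with a 5'-UTR intron.
        s(gene_id="csab_dfn_utr5", signal_len=23, precursor_len=80,
          intron_specs=[(23, 1, 120)], utr5_intron=(40, 400), utr5_len=80),
        # Long-chain KTx with a second phase-1 intron in the mature region.
        s(gene_id="csab_kctx_two_p1", signal_len=20, precursor_len=87,
          intron_specs=[(20, 1, 110), (55, 1, 380)]),
        # ICK toxins: short phase-1 intron inside the propeptide adjacent to
        # the signal, long phase-2 intron at the mature N-terminus.
        s(gene_id="ick_ktx_a", signal_len=24, precursor_len=63,
          propeptide_spans=[(24, 30)], mature_spans=[(30, 63)],
          intron_specs=[(26, 1, 65), (33, 2, 900)]),
        s(gene_id="ick_cal_b", signal_len=25, precursor_len=64,
          propeptide_spans=[(25, 31)], mature_spans=[(31, 64)],
          intron_specs=[(27, 1, 70), (34, 2, 1200)]),
        s(gene_id="ick_cal_c", signal_len=22, precursor_len=60,
          propeptide_spans=[(22, 27)], mature_spans=[(27, 60)],
          intron_specs=[(24, 1, 62), (29, 2, 800)]),
        # alpha-helical AMP: SP-MP-PP precursor, single boundary intron.
        s(gene_id="amp_a", signal_len=23, precursor_len=48,
          mature_spans=[(23, 36)], propeptide_spans=[(36, 48)],
          intron_specs=[(23, 1, 85)]),
        # Chymotrypsin-like proteases: multi-intron mature region, all phases.
        s(gene_id="prot_a", signal_len=18, precursor_len=240,
          intron_specs=[(18, 1, 140), (60, 0, 300), (120, 2, 210), (180, 1, 95)]),
        s(gene_id="prot_b", signal_len=17, precursor_len=235,
          intron_specs=[(17, 1, 180), (80, 2, 250), (150, 0, 130)]),
        # Kunitz-type protease inhibitor.
        s(gene_id="pi_kunitz_a", signal_len=21, precursor_len=80,
          intron_specs=[(21, 1, 90), (50, 1, 160)]),
    ]
    return [generate_gene(sp) for sp in specs]


def generate_cohort(
    n: int,
    signature_prob: float = 1.0,
    phase_props: tuple[float, float, float] = (0.5, 0.3, 0.2),
    seed: int = 0,
    window: int = 3,
    strand_mix: bool = True,
    utr5_intron_prob: float = 0.2,
    max_extra_introns: int = 3,
    intron_len_range: tuple[int, int] = DEFAULT_INTRON_LEN_RANGE,
) -> list[SyntheticGene]:
    """Random cohort: boundary signatures planted with probability
    ``signature_prob``; other introns uniform in position with phases drawn
    from ``phase_props``."""
    if n < 1:
        raise ValidationError("generate_cohort: n must be >= 1")
    rng = np.random.default_rng(seed)
    genes = []
    props = np.asarray(phase_props, dtype=float)
    props = props / props.sum()
    for i in range(n):
        signal_len = int(rng.integers(18, 26))
        precursor_len = int(rng.integers(60, 121))
        junctions: dict[int, tuple[int, int]] = {}  # j -> (codon, phase)
        if rng.random() < signature_prob:
            codon = signal_len + int(rng.integers(-2, 3))
            junctions[3 * codon + 1] = (codon, 1)
        planted = len(junctions)
        target = planted + int(rng.integers(0 if planted else 1, max_extra_introns + 1))
        while len(junctions) < target:
            phase = int(rng.choice(3, p=props))
            codon = int(rng.integers(1, precursor_len))
            j = 3 * codon + phase
            if 1 <= j <= 3 * precursor_len - 1 and j not in junctions:
                junctions[j] = (codon, phase)
        intron_specs = [
            (codon, phase, int(rng.integers(*intron_len_range)))
            for _, (codon, phase) in sorted(junctions.items())
        ]
        utr5_intron = None
        utr5_len = int(rng.integers(40, 120))
        if rng.random() < utr5_intron_prob:
            utr5_intron = (int(rng.integers(1, utr5_len)),
                           int(rng.integers(*intron_len_range)))
        spec = SyntheticGeneSpec(
            gene_id=f"synth{i + 1:04d}",
            signal_len=signal_len, precursor_len=precursor_len,
            intron_specs=intron_specs, utr5_intron=utr5_intron,
            strand="+-"[int(rng.integers(0, 2))] if strand_mix else "+",
            utr5_len=utr5_len, utr3_len=int(rng.integers(30, 100)),
            seed=int(rng.integers(2**31)),
        )
        genes.append(generate_gene(spec, window=window))
    return genes


# ---------------------------------------------------------------------------
# Promoters


def _instantiate_iupac(rng: np.random.Generator, pattern: str) -> str:
    return "".join(IUPAC[c][rng.integers(0, len(IUPAC[c]))] for c in pattern)


def generate_promoters(
    n: int,
    planted_module: list[IupacMotif],
    outlier_count: int = 1,
    seed: int = 0,
    length: int = 600,
    omit_per_outlier: int = 1,
) -> tuple[dict[str, str], dict[str, dict[str, int]]]:
    """Promoter set sharing a planted regulatory module, plus outliers.

    Returns ``(sequences, truth)`` where ``truth[promoter_id]`` maps each
    planted motif_id to its start position. The first ``outlier_count``
    promoter ids (``outlier1`` ...) lack the first ``omit_per_outlier``
    module motifs — their backgrounds are rejection-sampled until genuinely
    free of the omitted sites, emulating a housekeeping promoter missing key
    tissue-specific binding sites.
    """
    if n < 2:
        raise ValidationError("generate_promoters: n must be >= 2")
    if outlier_count >= n:
        raise ValidationError("outlier_count must be < n")
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    truth: dict[str, dict[str, int]] = {}
    for i in range(n):
        is_outlier = i < outlier_count
        pid = f"outlier{i + 1}" if is_outlier else f"venom_prom{i - outlier_count + 1}"
        motifs = planted_module[omit_per_outlier:] if is_outlier else planted_module
        omitted = planted_module[:omit_per_outlier] if is_outlier else []
        for _ in range(200):
            seq = list(_random_seq(rng, length))
            planted: dict[str, int] = {}
            taken: list[tuple[int, int]] = []
            ok = True
            for motif in motifs:
                site = _instantiate_iupac(rng, motif.pattern)
                for _ in range(100):
                    pos = int(rng.integers(0, length - len(site) + 1))
                    if all(pos + len(site) <= s or pos >= e for s, e in taken):
                        break
                else:
                    ok = False
                    break
                seq[pos:pos + len(site)] = site
                taken.append((pos, pos + len(site)))
                planted[motif.motif_id] = pos
            if not ok:
                continue
            seq_str = "".join(seq)
            if omitted and any(scan_promoter(seq_str, omitted, pid)):
                continue  # background accidentally contains an omitted site
            sequences[pid] = seq_str
            truth[pid] = planted
            break
        else:
            raise ValidationError(f"could not place module in promoter {pid}")
    return sequences, truth


# ---------------------------------------------------------------------------
# File emission


def write_cohort(genes: list[SyntheticGene], outdir: str | Path) -> dict[str, Path]:
    """Emit loci FASTA + GFF3 + precursor TSV + ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "loci.fasta",
        "gff3": outdir / "genes.gff3",
        "annotations": outdir / "precursors.tsv",
        "truth": outdir / "truth.json",
    }
    with open(paths["fasta"], "w") as fh:
        for g in genes:
            fh.write(f">{g.locus_id}\n")
            seq = g.model.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    write_gff3([g.model for g in genes], paths["gff3"])
    write_precursor_annotations([g.annotation for g in genes], paths["annotations"])
    with open(paths["truth"], "w") as fh:
        json.dump([asdict(g.truth) for g in genes], fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
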