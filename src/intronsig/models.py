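"""Core data model for exon-intron architecture analysis.

All coordinates are 0-based half-open on the genomic (plus) strand; GFF3 and
GenBank positions are converted at the I/O boundary. Exon and CDS segment
lists are kept in *transcript* (5'->3') orientation, so a minus-strand gene
lists its promoter-proximal exon first even though that exon has the largest
genomic coordinates.

Residue ("precursor") coordinates are 0-based indices into the translated
precursor protein, excluding the stop codon. The precursor of a secretory
peptide is partitioned into a signal peptide (SP, residues ``[0, signal_len)``),
zero or more propeptide (PP) spans and one or more mature peptide (MP) spans;
the order of PP and MP along the precursor is unconstrained (some antimicrobial
peptide precursors are SP-MP-PP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

STRANDS = ("+", "-")

#: Precursor region labels.
SIGNAL = "SIGNAL"
PROPEPTIDE = "PROPEPTIDE"
MATURE = "MATURE"
UTR5 = "UTR5"
UTR3 = "UTR3"
CODING = "CODING"


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded 0-based half-open interval ``[start, end)`` on a sequence."""

    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(
                f"unknown strand {self.strand!r} for {self.seq_id}:{self.start}-{self.end}"
            )
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class GeneModel:
    """One transcript's exon/CDS structure on a locus.

    ``exons`` and ``cds_segments`` are in transcript orientation: ascending
    genomic start for ``+`` genes, descending for ``-`` genes. ``complete``
    marks models whose concatenated CDS is a positive multiple of 3; models
    failing that are loaded anyway but flagged, so a caller can decide.
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: list[GenomicInterval]
    cds_segments: list[GenomicInterval] = field(default_factory=list)
    sequence: str | None = None
    complete: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"unknown strand {self.strand!r} for gene {self.gene_id}")
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id} has no exons")
        self._check_ordering(self.exons, "exon")
        self._check_ordering(self.cds_segments, "CDS segment")
        for seg in self.cds_segments:
            if not any(ex.contains(seg) for ex in self.exons):
                raise ValidationError(
                    f"gene {self.gene_id}: CDS segment [{seg.start},{seg.end}) "
                    "is not contained in any exon"
                )
        if self.sequence is not None:
            seq_len = len(self.sequence)
            for ex in self.exons:
                if ex.end > seq_len:
                    raise ValidationError(
                        f"gene {self.gene_id}: exon end {ex.end} exceeds sequence "
                        f"length {seq_len}"
                    )
        n = self.cds_len
        self.complete = n > 0 and n % 3 == 0

    def _check_ordering(self, ivs: list[GenomicInterval], what: str) -> None:
        for a, b in zip(ivs, ivs[1:]):
            ok = a.end <= b.start if self.strand == "+" else b.end <= a.start
            if not ok:
                raise ValidationError(
                    f"gene {self.gene_id}: {what}s overlap or are out of transcript "
                    f"order: [{a.start},{a.end}) then [{b.start},{b.end})"
                )

    @property
    def cds_len(self) -> int:
        return sum(len(s) for s in self.cds_segments)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


@dataclass
class PrecursorAnnotation:
    """SP / PP / MP partition of a precursor protein, in residue coordinates."""

    gene_id: str
    signal_len: int
    precursor_len: int
    propeptide_spans: list[tuple[int, int]] = field(default_factory=list)
    mature_spans: list[tuple[int, int]] = field(default_factory=list)
    complete: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if self.signal_len < 1:
            raise ValidationError(f"gene {self.gene_id}: signal_len must be >= 1")
        if self.precursor_len <= self.signal_len:
            raise ValidationError(
                f"gene {self.gene_id}: precursor_len {self.precursor_len} does not "
                f"exceed signal_len {self.signal_len}"
            )
        # Missing spans: everything downstream of the signal is mature by default.
        if not self.propeptide_spans and not self.mature_spans:
            self.mature_spans = [(self.signal_len, self.precursor_len)]
        spans = [(0, self.signal_len)] + list(self.propeptide_spans) + list(self.mature_spans)
        for s, e in spans:
            if not (0 <= s < e <= self.precursor_len):
                raise ValidationError(
                    f"gene {self.gene_id}: span [{s},{e}) outside precursor "
                    f"[0,{self.precursor_len})"
                )
        for (s1, e1), (s2, e2) in zip(sorted(spans), sorted(spans)[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"gene {self.gene_id}: overlapping precursor spans "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        covered = sum(e - s for s, e in spans)
        self.complete = covered == self.precursor_len

    def region_of(self, residue: int) -> str | None:
        """Label (SIGNAL/PROPEPTIDE/MATURE) of a residue index, or None if unannotated."""
        if residue < 0 or residue >= self.precursor_len:
            return None
        if residue < self.signal_len:
            return SIGNAL
        for s, e in self.propeptide_spans:
            if s <= residue < e:
                return PROPEPTIDE
        for s, e in self.mature_spans:
            if s <= residue < e:
                return MATURE
        return None
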