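"""Intron phase classification and the signal-boundary phase-1 signature.

An intron's *phase* is its position relative to the reading frame: phase 0
falls between codons, phase 1 between the first and second nucleotides of a
codon, phase 2 between the second and third. Writing ``L`` for the number of
coding nucleotides 5' of the intron, the phase is simply ``L mod 3`` and the
interrupted codon has index ``floor(L / 3)`` (for a phase-0 intron that is
the codon immediately 3' of the intron, which keeps residue offsets
comparable across phases).

Secretory precursors begin with a signal peptide of ``signal_len`` residues;
the *boundary signature* is a phase-1 intron whose interrupted codon lies
within a small residue window of the signal-peptide cleavage site. Such
introns recur across structurally unrelated secreted peptide families and
are the hallmark of exon shuffling between signal-donating and
mature-peptide-donating genes that this package is built to detect.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InconsistencyError, ValidationError
from .models import CODING, UTR3, UTR5, GeneModel, PrecursorAnnotation


@dataclass(frozen=True)
class IntronRecord:
    """One intron: genomic placement plus reading-frame classification."""

    gene_id: str
    ordinal: int                      # 1-based, transcript orientation
    donor_pos: int                    # genomic coord of the transcript-5' intron boundary
    acceptor_pos: int                 # genomic coord of the transcript-3' boundary
    length: int
    region: str                       # UTR5 | CODING | UTR3
    upstream_coding_nt: int | None    # L; None for UTR5 introns
    phase: int | None                 # 0/1/2, None for UTR introns
    interrupted_codon_index: int | None


@dataclass(frozen=True)
class RegionCall:
    """Which precursor region an intron interrupts, and how far from cleavage."""

    gene_id: str
    ordinal: int
    precursor_region: str             # SIGNAL | PROPEPTIDE | MATURE | UTR5 | UTR3
    offset_from_cleavage: int | None  # residues; negative = inside signal peptide


@dataclass(frozen=True)
class BoundaryCall:
    """Per-gene verdict on the phase-1 signal-boundary signature."""

    gene_id: str
    has_boundary_phase1: bool
    signature_intron_ordinal: int | None
    offset_from_cleavage: int | None
    window: int


@dataclass(frozen=True)
class GeneSetSummary:
    n_genes: int
    n_with_signature: int
    fraction: float
    exceptions: tuple[str, ...]       # gene_ids lacking the signature


def compute_intron_phases(model: GeneModel) -> list[IntronRecord]:
    """Classify every intron of a gene model by region and phase.

    There is one record per inter-exon gap, ordered and numbered in
    transcript orientation. ``L`` accumulates coding nucleotides strictly 5'
    of the intron; introns entirely 5' of the first coding nucleotide are
    UTR5, entirely 3' of the last are UTR3, both with phase ``None``.
    """
    total_cds = model.cds_len
    # Coding nt per exon, in transcript order (each CDS segment sits in one exon).
    coding_per_exon = [0] * len(model.exons)
    for seg in model.cds_segments:
        for i, ex in enumerate(model.exons):
            if ex.contains(seg):
                coding_per_exon[i] += len(seg)
                break

    records = []
    upstream = 0
    for i, (a, b) in enumerate(zip(model.exons, model.exons[1:])):
        upstream += coding_per_exon[i]
        if model.strand == "+":
            donor, acceptor = a.end, b.start
            length = b.start - a.end
        else:
            donor, acceptor = a.start, b.end
            length = a.start - b.end
        if length < 0:
            raise ValidationError(f"gene {model.gene_id}: overlapping exons")
        if length == 0:
            raise ValidationError(
                f"gene {model.gene_id}: zero-length intron between exons {i + 1} and {i + 2}"
            )
        if total_cds == 0 or upstream == 0:
            region, phase, codon, L = UTR5, None, None, None
        elif upstream >= total_cds:
            region, phase, codon, L = UTR3, None, None, None
        else:
            region = CODING
            L = upstream
            phase = L % 3
            codon = L // 3
        records.append(IntronRecord(
            gene_id=model.gene_id, ordinal=i + 1,
            donor_pos=donor, acceptor_pos=acceptor, length=length,
            region=region, upstream_coding_nt=L, phase=phase,
            interrupted_codon_index=codon,
        ))
    return records


def map_to_precursor(
    introns: list[IntronRecord], annot: PrecursorAnnotation
) -> list[RegionCall]:
    """Place each coding intron into the SP/PP/MP partition of the precursor.

    The offset from cleavage is ``interrupted_codon_index - signal_len``
    (negative = inside the signal peptide). UTR introns pass through with
    their UTR label and no offset.
    """
    calls = []
    for rec in introns:
        if rec.gene_id != annot.gene_id:
            raise InconsistencyError(
                f"intron gene_id {rec.gene_id!r} != annotation gene_id {annot.gene_id!r}"
            )
        if rec.region != CODING:
            calls.append(RegionCall(rec.gene_id, rec.ordinal, rec.region, None))
            continue
        idx = rec.interrupted_codon_index
        if idx >= annot.precursor_len:
            raise InconsistencyError(
                f"gene {rec.gene_id}: intron {rec.ordinal} interrupts codon {idx} "
                f"but the annotated precursor has only {annot.precursor_len} residues"
            )
        region = annot.region_of(idx)
        if region is None:
            raise InconsistencyError(
                f"gene {rec.gene_id}: codon {idx} is not covered by any annotated span"
            )
        calls.append(RegionCall(
            rec.gene_id, rec.ordinal, region, idx - annot.signal_len
        ))
    return calls


def call_boundary_signature(
    introns: list[IntronRecord],
    regions: list[RegionCall],
    annot: PrecursorAnnotation,
    window: int = 3,
) -> BoundaryCall:
    """Decide whether a gene carries the phase-1 signal-boundary signature.

    True iff some phase-1 intron sits within ``window`` residues of the
    cleavage site. Among several qualifying introns the one with the
    smallest absolute offset is named (ties break to the smaller ordinal).
    """
    if window < 0:
        raise ValidationError(f"window must be >= 0, got {window}")
    offsets = {rc.ordinal: rc.offset_from_cleavage for rc in regions}
    best = None
    for rec in introns:
        if rec.phase != 1:
            continue
        off = offsets.get(rec.ordinal)
        if off is None or abs(off) > window:
            continue
        if best is None or abs(off) < abs(best[1]):
            best = (rec.ordinal, off)
    if best is None:
        return BoundaryCall(annot.gene_id, False, None, None, window)
    return BoundaryCall(annot.gene_id, True, best[0], best[1], window)


def summarize_gene_set(calls: list[BoundaryCall]) -> GeneSetSummary:
    """Count boundary signatures across a gene set and list the exceptions."""
    if not calls:
        raise ValidationError("summarize_gene_set: empty call list")
    n_true = sum(c.has_boundary_phase1 for c in calls)
    exceptions = tuple(c.gene_id for c in calls if not c.has_boundary_phase1)
    return GeneSetSummary(len(calls), n_true, n_true / len(calls), exceptions)


def intron_table_rows(
    introns: list[IntronRecord], regions: list[RegionCall] | None = None
) -> list[dict]:
    """Flatten records (and optional region calls) into TSV-ready rows."""
    by_ordinal = {rc.ordinal: rc for rc in regions} if regions else {}
    rows = []
    for rec in introns:
        rc = by_ordinal.get(rec.ordinal)
        rows.append({
            "gene_id": rec.gene_id,
            "ordinal": rec.ordinal,
            "donor": rec.donor_pos,
            "acceptor": rec.acceptor_pos,
            "length": rec.length,
            "region": rec.region,
            "phase": "NA" if rec.phase is None else rec.phase,
            "L": "NA" if rec.upstream_coding_nt is None else rec.upstream_coding_nt,
            "interrupted_codon_index": (
                "NA" if rec.interrupted_codon_index is None
                else rec.interrupted_codon_index
            ),
            "precursor_region": rc.precursor_region if rc else "NA",
            "offset_from_cleavage": (
                rc.offset_from_cleavage
                if rc and rc.offset_from_cleavage is not None else "NA"
            ),
        })
    return rows


def boundary_table_rows(calls: list[BoundaryCall]) -> list[dict]:
    return [
        {
            "gene_id": c.gene_id,
            "has_boundary_phase1": c.has_boundary_phase1,
            "signature_intron_ordinal": (
                "NA" if c.signature_intron_ordinal is None else c.signature_intron_ordinal
            ),
            "offset_from_cleavage": (
                "NA" if c.offset_from_cleavage is None else c.offset_from_cleavage
            ),
            "window": c.window,
        }
        for c in calls
    ]
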