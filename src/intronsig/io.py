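"""Reading and writing gene annotations, sequences and tabular outputs.

GFF3 (1-based inclusive) and GenBank locations are converted to the internal
0-based half-open convention here and nowhere else. When a gene carries
several transcripts the one with the longest CDS is kept by default, because
downstream analyses operate on one structure per gene; ``all_transcripts=True``
keeps every one.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError, ValidationError
from .models import GeneModel, GenomicInterval, PrecursorAnnotation

log = logging.getLogger(__name__)

GFF_SUFFIXES = {".gff", ".gff3"}
GENBANK_SUFFIXES = {".gb", ".gbk", ".gbff", ".genbank"}

INTRON_TABLE_COLUMNS = [
    "gene_id", "ordinal", "donor", "acceptor", "length", "region", "phase",
    "L", "interrupted_codon_index", "precursor_region", "offset_from_cleavage",
]
BOUNDARY_TABLE_COLUMNS = [
    "gene_id", "has_boundary_phase1", "signature_intron_ordinal",
    "offset_from_cleavage", "window",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ``{id: sequence}`` dict (uppercased)."""
    records = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records[rec.id] = str(rec.seq).upper()
    except ValueError as exc:
        raise FormatError(f"{path}: not parseable as FASTA ({exc})") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records parsed")
    return records


def _sniff_format(path: Path) -> str:
    if path.suffix.lower() in GFF_SUFFIXES:
        return "gff3"
    if path.suffix.lower() in GENBANK_SUFFIXES:
        return "genbank"
    with open(path) as fh:
        head = fh.read(256)
    if head.startswith("LOCUS"):
        return "genbank"
    return "gff3"


def load_gene_models(
    annotation_path: str | Path,
    fasta_path: str | Path | None = None,
    all_transcripts: bool = False,
) -> list[GeneModel]:
    """Load gene models from a GFF3 or GenBank file.

    Minus-strand exon lists come back reversed into transcript orientation.
    Models whose CDS length is not a positive multiple of 3 are flagged
    ``complete=False`` but kept. Non-canonical splice dinucleotides only
    warn (annotations must remain loadable); use :func:`splice_dinucleotides`
    to inspect them.
    """
    annotation_path = Path(annotation_path)
    sequences = read_fasta(fasta_path) if fasta_path else {}
    fmt = _sniff_format(annotation_path)
    if fmt == "genbank":
        models = _load_genbank(annotation_path)
    else:
        models = _load_gff3(annotation_path, all_transcripts)
    for m in models:
        if m.sequence is None and m.seq_id in sequences:
            m.sequence = sequences[m.seq_id]
            m.__post_init__()  # re-validate bounds against the sequence
    for m in models:
        if m.sequence is not None:
            for donor, acceptor in splice_dinucleotides(m):
                if (donor, acceptor) != ("GT", "AG"):
                    warnings.warn(
                        f"gene {m.gene_id}: non-canonical splice site "
                        f"{donor}..{acceptor}",
                        stacklevel=2,
                    )
        if not m.complete:
            log.warning("gene %s: CDS length %d not a multiple of 3; flagged incomplete",
                        m.gene_id, m.cds_len)
    return models


def _load_gff3(path: Path, all_transcripts: bool) -> list[GeneModel]:
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc

    for cds in db.features_of_type("CDS"):
        if not cds.attributes.get("Parent"):
            raise ValidationError(
                f"{path}: CDS feature at {cds.seqid}:{cds.start}-{cds.end} has no Parent"
            )

    transcripts: list[gffutils.Feature] = []
    for ftype in ("mRNA", "transcript"):
        transcripts.extend(db.features_of_type(ftype))
    models = []
    by_gene: dict[str, list[GeneModel]] = {}
    for t in transcripts:
        model = _model_from_transcript(db, t, path)
        if model is None:
            continue
        parents = t.attributes.get("Parent", [model.gene_id])
        by_gene.setdefault(parents[0], []).append(model)
    for gene_id, group in by_gene.items():
        if all_transcripts:
            models.extend(group)
        else:
            models.append(max(group, key=lambda m: m.cds_len))
    return models


def _model_from_transcript(db, t, path: Path) -> GeneModel | None:
    if t.strand not in ("+", "-"):
        raise ValidationError(
            f"{path}: unknown strand {t.strand!r} on transcript {t.id}"
        )
    exons = list(db.children(t, featuretype="exon"))
    cds = list(db.children(t, featuretype="CDS"))
    if not exons and not cds:
        return None
    if not exons:
        exons = cds
    reverse = t.strand == "-"

    def convert(feats):
        ivs = [
            GenomicInterval(f.seqid, f.start - 1, f.end, t.strand) for f in feats
        ]
        return sorted(ivs, key=lambda iv: iv.start, reverse=reverse)

    return GeneModel(
        gene_id=t.id,
        seq_id=t.seqid,
        strand=t.strand,
        exons=convert(exons),
        cds_segments=convert(cds),
    )


def _load_genbank(path: Path) -> list[GeneModel]:
    models = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise FormatError(f"{path}: not parseable as GenBank ({exc})") from exc
    if not records:
        raise FormatError(f"{path}: no GenBank records parsed")
    for rec in records:
        mrna_by_gene = {}
        for feat in rec.features:
            if feat.type == "mRNA":
                mrna_by_gene[_feature_name(feat, rec)] = feat
        for i, feat in enumerate(f for f in rec.features if f.type == "CDS"):
            name = _feature_name(feat, rec, fallback=f"{rec.id}_cds{i + 1}")
            strand_num = feat.location.strand
            if strand_num not in (1, -1):
                raise ValidationError(f"{path}: CDS {name} has unknown strand")
            strand = "+" if strand_num == 1 else "-"
            reverse = strand == "-"

            def convert(location):
                ivs = [
                    GenomicInterval(rec.id, int(part.start), int(part.end), strand)
                    for part in location.parts
                ]
                return sorted(ivs, key=lambda iv: iv.start, reverse=reverse)

            cds_ivs = convert(feat.location)
            mrna = mrna_by_gene.get(name)
            exon_ivs = convert(mrna.location) if mrna is not None else list(cds_ivs)
            model = GeneModel(
                gene_id=name, seq_id=rec.id, strand=strand,
                exons=exon_ivs, cds_segments=cds_ivs,
                sequence=str(rec.seq).upper() or None,
            )
            models.append(model)
    return models


def _feature_name(feat, rec, fallback: str | None = None) -> str:
    for key in ("gene", "locus_tag", "protein_id"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return fallback or rec.id


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS features; inverse of the GFF3 loader."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = _genomic_span(m)
            base = f"{m.seq_id}\tintronsig\t"
            tail = f"\t.\t{m.strand}\t"
            fh.write(f"{base}gene\t{span[0] + 1}\t{span[1]}{tail}.\t"
                     f"ID=gene:{m.gene_id}\n")
            fh.write(f"{base}mRNA\t{span[0] + 1}\t{span[1]}{tail}.\t"
                     f"ID={m.gene_id};Parent=gene:{m.gene_id}\n")
            for iv in sorted(m.exons, key=lambda iv: iv.start):
                fh.write(f"{base}exon\t{iv.start + 1}\t{iv.end}{tail}.\t"
                         f"Parent={m.gene_id}\n")
            for iv in sorted(m.cds_segments, key=lambda iv: iv.start):
                fh.write(f"{base}CDS\t{iv.start + 1}\t{iv.end}{tail}.\t"
                         f"ID=cds:{m.gene_id};Parent={m.gene_id}\n")


def _genomic_span(m: GeneModel) -> tuple[int, int]:
    return min(iv.start for iv in m.exons), max(iv.end for iv in m.exons)


def spliced_cds(model: GeneModel) -> str:
    """Concatenated coding sequence in transcript orientation.

    Minus-strand segments are reverse-complemented; the result always reads
    5'->3' on the mRNA.
    """
    if model.sequence is None:
        raise ValidationError(f"gene {model.gene_id}: no sequence attached")
    parts = []
    for seg in model.cds_segments:
        if seg.end > len(model.sequence):
            raise ValidationError(
                f"gene {model.gene_id}: CDS segment end {seg.end} outside sequence"
            )
        piece = model.sequence[seg.start:seg.end]
        if model.strand == "-":
            piece = str(Seq(piece).reverse_complement())
        parts.append(piece)
    return "".join(parts)


def translate_cds(cds: str) -> str:
    """Translate a coding sequence under the standard genetic code.

    A single trailing stop is stripped; an internal stop raises, naming the
    offending codon index.
    """
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} is not a multiple of 3")
    protein = str(Seq(cds).translate(table=1))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValidationError(f"internal stop codon at codon index {protein.index('*')}")
    return protein


def splice_dinucleotides(model: GeneModel) -> list[tuple[str, str]]:
    """(donor, acceptor) dinucleotides of each intron, on the coding strand."""
    if model.sequence is None:
        return []
    out = []
    for a, b in zip(model.exons, model.exons[1:]):
        if model.strand == "+":
            intron = model.sequence[a.end:b.start]
        else:
            intron = str(Seq(model.sequence[b.end:a.start]).reverse_complement())
        if len(intron) >= 4:
            out.append((intron[:2], intron[-2:]))
    return out


# ---------------------------------------------------------------------------
# Precursor annotations


def _parse_spans(cell) -> list[tuple[int, int]]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    spans = []
    for token in str(cell).split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            s, e = token.split("-")
            spans.append((int(s), int(e)))
        except ValueError as exc:
            raise FormatError(f"bad span token {token!r} (expected 'start-end')") from exc
    return spans


def load_precursor_annotations(path: str | Path) -> list[PrecursorAnnotation]:
    """Load SP/PP/MP annotations from a TSV or JSON sidecar.

    TSV columns: gene_id, signal_len, precursor_len, propeptide_spans,
    mature_spans; spans are semicolon-separated ``start-end`` tokens in
    0-based half-open residue coordinates. JSON: a list of objects with the
    same keys (spans as ``[start, end]`` pairs).
    """
    path = Path(path)
    rows: list[dict]
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            rows = json.load(fh)
        for row in rows:
            row["propeptide_spans"] = [tuple(s) for s in row.get("propeptide_spans", [])]
            row["mature_spans"] = [tuple(s) for s in row.get("mature_spans", [])]
    else:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        if "gene_id" not in df.columns or "signal_len" not in df.columns:
            raise FormatError(f"{path}: needs gene_id and signal_len columns")
        rows = []
        for _, r in df.iterrows():
            rows.append({
                "gene_id": r["gene_id"],
                "signal_len": int(r["signal_len"]),
                "precursor_len": int(r["precursor_len"]),
                "propeptide_spans": _parse_spans(r.get("propeptide_spans")),
                "mature_spans": _parse_spans(r.get("mature_spans")),
            })
    return [PrecursorAnnotation(**row) for row in rows]


def write_precursor_annotations(annots: list[PrecursorAnnotation], path: str | Path) -> None:
    def fmt(spans):
        return ";".join(f"{s}-{e}" for s, e in spans)

    df = pd.DataFrame([
        {
            "gene_id": a.gene_id,
            "signal_len": a.signal_len,
            "precursor_len": a.precursor_len,
            "propeptide_spans": fmt(a.propeptide_spans),
            "mature_spans": fmt(a.mature_spans),
        }
        for a in annots
    ])
    df.to_csv(path, sep="\t", index=False)


def write_table(rows: list[dict], columns: list[str], path: str | Path) -> None:
    """Write a TSV with a fixed column order (missing keys become NA)."""
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
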