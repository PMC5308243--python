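"""Gene-structure schematics: precursor-region boxes with intron connectors.

Text mode emits a one-line schematic such as::

    [5'UTR]--i(NA)--[SP]--i(1)--[MP][PP]

with one box per annotated precursor region (SP/PP/MP) plus UTR boxes, and
one ``i(phase)`` connector per intron at the residue position it interrupts
(introns inside a region split its box). SVG mode draws the same layout
deterministically — same inputs, byte-identical document.
"""

from __future__ import annotations

from .models import CODING, UTR5, UTR3, GeneModel, PrecursorAnnotation
from .phase import IntronRecord

REGION_SHORT = {"SIGNAL": "SP", "PROPEPTIDE": "PP", "MATURE": "MP"}
SVG_COLORS = {
    "SP": "#d95f02", "PP": "#7570b3", "MP": "#1b9e77",
    "5'UTR": "#cccccc", "3'UTR": "#cccccc",
}


def _utr_lengths(model: GeneModel) -> tuple[int, int]:
    """(5'UTR nt, 3'UTR nt) from exon vs CDS extents in transcript order."""
    utr5 = 0
    seen_cds = False
    for ex in model.exons:
        coding = [s for s in model.cds_segments if ex.contains(s)]
        if not coding:
            if not seen_cds:
                utr5 += len(ex)
            continue
        seen_cds = True
        if model.strand == "+":
            utr5 += min(s.start for s in coding) - ex.start
        else:
            utr5 += ex.end - max(s.end for s in coding)
        break
    total_exonic = sum(len(e) for e in model.exons)
    return utr5, total_exonic - utr5 - model.cds_len


def _layout(
    model: GeneModel, introns: list[IntronRecord], annot: PrecursorAnnotation
) -> list[tuple[str, object]]:
    """Ordered ('box', label, n_residues) / ('intron', record) tokens."""
    utr5_nt, utr3_nt = _utr_lengths(model)
    boxes = [(0, annot.signal_len, "SP")]
    boxes += [(s, e, "PP") for s, e in annot.propeptide_spans]
    boxes += [(s, e, "MP") for s, e in annot.mature_spans]
    boxes.sort()
    coding = sorted(
        (r for r in introns if r.region == CODING),
        key=lambda r: r.interrupted_codon_index,
    )
    tokens: list[tuple[str, object]] = []
    if utr5_nt > 0:
        tokens.append(("box", ("5'UTR", max(1, utr5_nt // 3))))
    for r in introns:
        if r.region == UTR5:
            tokens.append(("intron", r))
    used = set()
    for a, b, label in boxes:
        inner = [r for r in coding if a < r.interrupted_codon_index < b]
        at_start = [r for r in coding
                    if r.interrupted_codon_index == a and r.ordinal not in used]
        for r in at_start:
            tokens.append(("intron", r))
            used.add(r.ordinal)
        prev = a
        for r in inner:
            tokens.append(("box", (label, r.interrupted_codon_index - prev)))
            tokens.append(("intron", r))
            used.add(r.ordinal)
            prev = r.interrupted_codon_index
        tokens.append(("box", (label, b - prev)))
    for r in introns:
        if r.region == UTR3:
            tokens.append(("intron", r))
    if utr3_nt > 0:
        tokens.append(("box", ("3'UTR", max(1, utr3_nt // 3))))
    return tokens


def render_structure(
    model: GeneModel,
    introns: list[IntronRecord],
    annot: PrecursorAnnotation,
    fmt: str = "text",
) -> str:
    """One gene's structure as a text schematic or an SVG document."""
    tokens = _layout(model, introns, annot)
    if fmt == "text":
        out = []
        for kind, payload in tokens:
            if kind == "box":
                out.append(f"[{payload[0]}]")
            else:
                phase = "NA" if payload.phase is None else payload.phase
                out.append(f"--i({phase})--")
        return "".join(out)
    if fmt == "svg":
        return _render_svg(model.gene_id, tokens)
    raise ValueError(f"unknown diagram format {fmt!r}")


def _render_svg(gene_id: str, tokens) -> str:
    px_per_res = 4.0
    x, y, h = 10.0, 40.0, 22.0
    parts = []
    for kind, payload in tokens:
        if kind == "box":
            label, n_res = payload
            w = max(18.0, n_res * px_per_res)
            color = SVG_COLORS.get(label, "#999999")
            parts.append(
                f'<rect x="{x:.1f}" y="{y:.1f}" width="{w:.1f}" height="{h:.1f}" '
                f'fill="{color}" stroke="black" stroke-width="0.8"/>'
            )
            parts.append(
                f'<text x="{x + w / 2:.1f}" y="{y + h / 2 + 4:.1f}" font-size="10" '
                f'text-anchor="middle" font-family="sans-serif">{label}</text>'
            )
            x += w
        else:
            rec = payload
            phase = "NA" if rec.phase is None else str(rec.phase)
            w = 26.0
            apex_x = x + w / 2
            parts.append(
                f'<polyline points="{x:.1f},{y:.1f} {apex_x:.1f},{y - 18:.1f} '
                f'{x + w:.1f},{y:.1f}" fill="none" stroke="black" stroke-width="0.8"/>'
            )
            parts.append(
                f'<text x="{apex_x:.1f}" y="{y - 21:.1f}" font-size="9" '
                f'text-anchor="middle" font-family="sans-serif">'
                f"{phase}/{rec.length}nt</text>"
            )
            x += w
    width = x + 10.0
    body = "\n  ".join(parts)
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width:.1f}" height="80">\n'
        f'  <text x="10" y="16" font-size="11" font-family="sans-serif" '
        f'font-weight="bold">{gene_id}</text>\n'
        f"  {body}\n</svg>\n"
    )
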