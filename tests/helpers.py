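"""Independent oracles and transforms used by the test suite.

Everything here deliberately takes a different computational route from the
package code it checks: set-based position counting instead of exon walks,
reverse-complement-then-slice splicing, 3^n sequence enumeration instead of
outcome-triple enumeration, and a per-position IUPAC window scan.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from intronsig.models import GeneModel, GenomicInterval

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def oracle_intron_classes(model: GeneModel) -> list[tuple[str, int | None, int | None]]:
    """(region, phase, interrupted_codon_index) per intron, by counting the
    set of coding genomic positions 5' (in transcript sense) of each gap."""
    coding = set()
    for seg in model.cds_segments:
        coding.update(range(seg.start, seg.end))
    total = len(coding)
    out = []
    for a, b in zip(model.exons, model.exons[1:]):
        if model.strand == "+":
            gap_start = a.end
            upstream = sum(1 for p in coding if p < gap_start)
        else:
            gap_end = a.start  # intron interval is [b.end, a.start)
            upstream = sum(1 for p in coding if p >= gap_end)
        if total == 0 or upstream == 0:
            out.append(("UTR5", None, None))
        elif upstream >= total:
            out.append(("UTR3", None, None))
        else:
            out.append(("CODING", upstream % 3, upstream // 3))
    return out


def oracle_spliced_cds(model: GeneModel) -> str:
    """Reverse-complement the whole locus first, then splice by transformed
    coordinates (the brute-force route for minus-strand genes)."""
    seq = model.sequence
    if model.strand == "+":
        parts = sorted((s.start, s.end) for s in model.cds_segments)
        return "".join(seq[a:b] for a, b in parts)
    rc = revcomp(seq)
    L = len(seq)
    parts = sorted((L - s.end, L - s.start) for s in model.cds_segments)
    return "".join(rc[a:b] for a, b in parts)


def flip_model(model: GeneModel) -> GeneModel:
    """The same gene described on the reverse-complemented locus."""
    L = len(model.sequence)
    new_strand = "-" if model.strand == "+" else "+"

    def flip(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(iv.seq_id, L - iv.end, L - iv.start, new_strand)

    return GeneModel(
        gene_id=model.gene_id,
        seq_id=model.seq_id,
        strand=new_strand,
        exons=[flip(iv) for iv in model.exons],
        cds_segments=[flip(iv) for iv in model.cds_segments],
        sequence=revcomp(model.sequence),
    )


@lru_cache(maxsize=None)
def _outcome_pmf_table(n: int, probs: tuple[float, float, float]) -> dict:
    table: dict[tuple[int, int, int], float] = {}
    for seq in itertools.product(range(3), repeat=n):
        pr = 1.0
        for k in seq:
            pr *= probs[k]
        key = (seq.count(0), seq.count(1), seq.count(2))
        table[key] = table.get(key, 0.0) + pr
    return table


def oracle_exact_multinomial_p(
    obs: tuple[int, int, int], probs: tuple[float, float, float]
) -> float:
    """Two-sided exact multinomial p by enumerating all 3^n phase sequences."""
    n = sum(obs)
    table = _outcome_pmf_table(n, probs)
    p_obs = table[obs]
    return min(1.0, sum(v for v in table.values() if v <= p_obs * (1 + 1e-9)))


IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}


def oracle_iupac_scan(seq: str, pattern: str) -> list[int]:
    """Forward-strand start positions by an explicit per-window check."""
    hits = []
    w = len(pattern)
    for i in range(len(seq) - w + 1):
        ok = True
        for base, m in zip(seq[i:i + w], pattern):
            if base == "N":
                if m != "N":
                    ok = False
                    break
            elif base not in IUPAC_SETS[m]:
                ok = False
                break
        if ok:
            hits.append(i)
    return hits
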