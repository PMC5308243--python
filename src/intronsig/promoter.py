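"""IUPAC consensus scanning of promoter regions and module-sharing scores.

Venom-gland-expressed genes can share promoter "modules" — co-occurring
transcription-factor binding sites (e.g. C/EBPalpha sites) absent from
housekeeping promoters. This module scans user-supplied IUPAC consensus
motifs on both strands and summarizes sharing as pairwise Jaccard indices
over each promoter's set of present motifs. Presence is binary: the
comparison is about which sites a promoter has, not how many copies.

An ``N`` in the *promoter* sequence (masked base) matches nothing unless the
motif position itself is ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .errors import FormatError, ValidationError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


@dataclass(frozen=True)
class IupacMotif:
    motif_id: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValidationError(f"motif {self.motif_id!r}: empty pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValidationError(
                f"motif {self.motif_id!r}: invalid IUPAC letters {sorted(bad)}"
            )
        object.__setattr__(self, "pattern", self.pattern.upper())

    def reverse_complement(self) -> str:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(self.pattern))


@dataclass(frozen=True)
class MotifHit:
    promoter_id: str
    motif_id: str
    start: int        # 0-based on the forward strand
    strand: str
    site: str         # forward-strand letters of the matched window


@dataclass
class ModuleMatrix:
    presence: pd.DataFrame   # promoters x motifs, bool
    jaccard: pd.DataFrame    # promoters x promoters, float

    @property
    def promoter_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def motif_ids(self) -> list[str]:
        return list(self.presence.columns)


def _matches_at(seq: str, pattern: str, pos: int) -> bool:
    for offset, m in enumerate(pattern):
        base = seq[pos + offset]
        if base == "N":
            if m != "N":
                return False
        elif base not in IUPAC[m]:
            return False
    return True


def scan_promoter(
    promoter: str, motifs: list[IupacMotif], promoter_id: str = "promoter"
) -> list[MotifHit]:
    """All matches of each motif on both strands; overlaps are reported.

    Minus-strand matches are found by scanning the reverse-complemented
    pattern on the forward strand, so ``start`` and ``site`` are always in
    forward-strand coordinates and letters.
    """
    promoter = promoter.upper()
    bad = set(promoter) - set("ACGTN")
    if bad:
        raise ValidationError(f"promoter {promoter_id!r}: invalid letters {sorted(bad)}")
    hits = []
    for motif in motifs:
        for strand, pattern in (("+", motif.pattern), ("-", motif.reverse_complement())):
            w = len(pattern)
            for pos in range(len(promoter) - w + 1):
                if _matches_at(promoter, pattern, pos):
                    hits.append(MotifHit(
                        promoter_id, motif.motif_id, pos, strand,
                        promoter[pos:pos + w],
                    ))
    hits.sort(key=lambda h: (h.motif_id, h.start, h.strand))
    return hits


def module_matrix(
    hits_by_promoter: dict[str, list[MotifHit]], motif_ids: list[str]
) -> ModuleMatrix:
    """Binary presence matrix and pairwise Jaccard sharing scores.

    ``jaccard(i, j) = |motifs(i) & motifs(j)| / |motifs(i) | motifs(j)|``;
    a pair of promoters with no motifs at all scores 0.
    """
    promoter_ids = list(hits_by_promoter)
    presence = pd.DataFrame(False, index=promoter_ids, columns=motif_ids)
    for pid, hits in hits_by_promoter.items():
        for h in hits:
            presence.loc[pid, h.motif_id] = True
    jac = pd.DataFrame(0.0, index=promoter_ids, columns=promoter_ids)
    sets = {pid: set(presence.columns[presence.loc[pid]]) for pid in promoter_ids}
    for i in promoter_ids:
        for j in promoter_ids:
            union = sets[i] | sets[j]
            jac.loc[i, j] = len(sets[i] & sets[j]) / len(union) if union else 0.0
    return ModuleMatrix(presence=presence, jaccard=jac)


def load_motifs(path: str | Path) -> list[IupacMotif]:
    """Read a two-column TSV (motif_id, IUPAC pattern); '#' lines are comments."""
    motifs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected motif_id<TAB>pattern")
            motifs.append(IupacMotif(parts[0], parts[1]))
    if not motifs:
        raise FormatError(f"{path}: no motifs parsed")
    return motifs


def hit_table_rows(hits: list[MotifHit]) -> list[dict]:
    return [
        {
            "promoter_id": h.promoter_id, "motif_id": h.motif_id,
            "start": h.start, "strand": h.strand, "site": h.site,
        }
        for h in hits
    ]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
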