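"""Scaffold motif annotation for venom peptide families.

Two disulfide-rich scaffolds dominate short venom peptides:

* the inhibitor cystine knot (ICK): three disulfides C1-C4, C2-C5, C3-C6, in
  which the C3-C6 bridge threads the macrocycle ("ring") formed by the other
  two bridges plus the backbone segments C1..C2 and C4..C5. The scorpion ICK
  consensus is ``C X{6} C X{4} D C C X{2,4} [KR] C X{3} G X{4,6} C [KR]``;
  under the segment reading of the ring, its admissible spacer lengths give
  ring sizes of exactly 13-15 residues.
* the CSalpha/beta fold: an alpha-helix carrying the invariant ``C-X3-C``
  motif tethered to the second beta-strand's ``C-X-C`` motif by two
  disulfides.

Matching is strict consensus matching over {A..Y}: the conserved D, G and
K/R positions accept exactly those residues. No similarity scoring is done.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ValidationError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Strict scorpion-venom ICK consensus with the six cysteines captured.
ICK_PATTERN = re.compile(
    r"(C).{6}(C).{4}D(C)(C).{2,4}[KR](C).{3}G.{4,6}(C)[KR]"
)

CONNECTIVITY = ((1, 4), (2, 5), (3, 6))
CONNECTIVITY_STRING = "1-4,2-5,3-6"


@dataclass(frozen=True)
class IckMatch:
    protein_id: str
    cys_positions: tuple[int, int, int, int, int, int]  # C1..C6, 0-based
    spacer_lengths: tuple[int, int, int, int, int]      # residues between Ci and Ci+1
    ring_size: int
    connectivity: tuple[tuple[int, int], ...]
    start: int
    end: int


@dataclass(frozen=True)
class CsabMotifReport:
    protein_id: str
    cx3c_positions: tuple[int, ...]
    cxc_positions: tuple[int, ...]
    has_pair: bool


def _check_protein(protein: str) -> None:
    bad = set(protein) - AMINO_ACIDS
    if bad:
        raise ValidationError(f"non-residue characters in protein: {sorted(bad)}")


def ring_size_from_positions(cys_positions: tuple[int, ...]) -> int:
    """Ring size of an ICK match: residues of the C1..C2 and C4..C5 backbone
    segments (cysteines included) closed by the C1-C4 and C2-C5 bridges."""
    c1, c2, _, c4, c5, _ = cys_positions
    return (c2 - c1 + 1) + (c5 - c4 + 1)


def match_ick_consensus(
    protein: str, protein_id: str = "protein", overlapping: bool = False
) -> list[IckMatch]:
    """All matches of the scorpion ICK consensus, leftmost-first.

    Non-overlapping by default (venom ICK peptides are single-domain);
    ``overlapping=True`` scans every start position.
    """
    _check_protein(protein)
    if overlapping:
        matches = []
        for i in range(len(protein)):
            m = ICK_PATTERN.match(protein, i)
            if m:
                matches.append(m)
    else:
        matches = list(ICK_PATTERN.finditer(protein))
    out = []
    for m in matches:
        cys = tuple(m.start(g) for g in range(1, 7))
        spacers = tuple(b - a - 1 for a, b in zip(cys, cys[1:]))
        out.append(IckMatch(
            protein_id=protein_id,
            cys_positions=cys,
            spacer_lengths=spacers,
            ring_size=ring_size_from_positions(cys),
            connectivity=CONNECTIVITY,
            start=m.start(),
            end=m.end(),
        ))
    return out


def enumerate_consensus_ring_sizes(rng=None) -> dict[tuple[int, int], int]:
    """Ring size for every spacer combination the consensus admits.

    Instantiates the consensus for each (C4-side spacer, pre-C6 spacer)
    pair and runs the matcher on it, so the returned sizes are measured, not
    assumed. ``rng`` (a numpy Generator) randomizes the X residues;
    the default uses alanine.
    """
    sizes = {}
    for s1 in (2, 3, 4):        # X{2,4} between C4 and K/R
        for s2 in (4, 5, 6):    # X{4,6} between G and C6
            seq = _instantiate_consensus(s1, s2, rng)
            hits = match_ick_consensus(seq)
            if len(hits) != 1:
                raise AssertionError(
                    f"consensus instance for spacers ({s1},{s2}) gave {len(hits)} matches"
                )
            sizes[(s1, s2)] = hits[0].ring_size
    return sizes


def _instantiate_consensus(s1: int, s2: int, rng=None) -> str:
    def x(n: int) -> str:
        if rng is None:
            return "A" * n
        # X excludes nothing, but avoid C/D/G/K/R so the strict pattern
        # cannot accidentally anchor on a spacer residue.
        alphabet = sorted(AMINO_ACIDS - set("CDGKR"))
        return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))

    return "C" + x(6) + "C" + x(4) + "DCC" + x(s1) + "K" + "C" + x(3) + "G" + x(s2) + "C" + "R"


def match_csab_motifs(protein: str, protein_id: str = "protein") -> CsabMotifReport:
    """Positions of the CSalpha/beta C-X3-C and C-X-C motifs (overlapping scan).

    ``has_pair`` is true when at least one C-X3-C precedes at least one
    C-X-C, the arrangement that pins the helix to the second beta-strand.
    """
    _check_protein(protein)
    cx3c = tuple(m.start(1) for m in re.finditer(r"(?=(C.{3}C))", protein))
    cxc = tuple(m.start(1) for m in re.finditer(r"(?=(C.C))", protein))
    has_pair = any(p < q for p in cx3c for q in cxc)
    return CsabMotifReport(protein_id, cx3c, cxc, has_pair)


def count_cysteines(protein: str) -> tuple[int, int]:
    """(cysteine count, maximum pairable disulfide bridges = count // 2)."""
    _check_protein(protein)
    n = protein.count("C")
    return n, n // 2


def ick_table_rows(matches: list[IckMatch]) -> list[dict]:
    return [
        {
            "protein_id": m.protein_id,
            "start": m.start,
            "end": m.end,
            "cys_positions": ",".join(map(str, m.cys_positions)),
            "spacer_lengths": ",".join(map(str, m.spacer_lengths)),
            "ring_size": m.ring_size,
            "connectivity": CONNECTIVITY_STRING,
        }
        for m in matches
    ]
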