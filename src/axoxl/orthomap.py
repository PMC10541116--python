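"""Orthogroup collapsing and alignment-based residue transfer.

Cross-links are identified on *Tetrahymena* proteins but often mapped onto
structures of homologs from other species (or onto human gene names).  Two
operations make that possible: relabelling records by eukaryotic orthogroup,
and transferring residue positions across species through a global
(Needleman-Wunsch, affine-gap) pairwise alignment.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import Chain, CrossLinkRecord, OrthoMap

UNALIGNED = "unaligned"
MISSING = "missing_in_structure"

NEG_INF = float("-inf")


@functools.lru_cache(maxsize=1)
def _blosum62() -> dict[tuple[str, str], float]:
    mat = substitution_matrices.load("BLOSUM62")
    table: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = float(mat[a, b])
    return table


def _score(a: str, b: str, table) -> float:
    # unknown residue X is neutral
    if a == "X" or b == "X":
        return 0.0
    try:
        return table[(a, b)]
    except KeyError:
        raise ValueError(f"residue outside the amino-acid alphabet: {a!r}/{b!r}")


@dataclass
class Alignment:
    """A global pairwise alignment as a list of aligned columns.

    Each column is ``(pos_a | None, pos_b | None)`` with 1-based sequence
    positions; None marks a gap.  ``score`` is in substitution-matrix units.
    """

    accession_a: str
    accession_b: str
    columns: list[tuple[int | None, int | None]]
    score: float

    @property
    def identity(self) -> float:
        """Identical aligned pairs over total alignment columns."""
        if not self.columns:
            return 0.0
        n_id = sum(
            1 for pa, pb in self.columns
            if pa is not None and pb is not None
            and self._res_a[pa - 1] == self._res_b[pb - 1]
        )
        return n_id / len(self.columns)

    # sequences are attached by global_align for identity computation
    _res_a: str = ""
    _res_b: str = ""

    def partner_of_a(self, pos: int) -> int | None:
        for pa, pb in self.columns:
            if pa == pos:
                return pb
        raise IndexError(f"position {pos} not in aligned sequence a")


def global_align(
    seq_a: str,
    seq_b: str,
    accession_a: str = "a",
    accession_b: str = "b",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Alignment:
    """Optimal global alignment with affine gaps (Gotoh), BLOSUM62 scores.

    A gap of length L scores -(gap_open + (L-1)*gap_extend).  Traceback
    tie-breaking is deterministic: diagonal (match) is preferred, then up
    (gap in ``seq_b``), then left (gap in ``seq_a``).
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    table = _blosum62()
    n, m = len(seq_a), len(seq_b)
    # M: a_i aligned to b_j; IX: a_i aligned to gap; IY: b_j aligned to gap
    M = np.full((n + 1, m + 1), NEG_INF)
    IX = np.full((n + 1, m + 1), NEG_INF)
    IY = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        IX[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        IY[0, j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        si = seq_a[i - 1]
        for j in range(1, m + 1):
            s = _score(si, seq_b[j - 1], table)
            M[i, j] = s + max(M[i - 1, j - 1], IX[i - 1, j - 1],
                              IY[i - 1, j - 1])
            IX[i, j] = max(M[i - 1, j] - gap_open, IX[i - 1, j] - gap_extend)
            IY[i, j] = max(M[i, j - 1] - gap_open, IY[i, j - 1] - gap_extend)

    # traceback; preference order encodes the diagonal > up > left tie-break
    states = [("M", M[n, m]), ("IX", IX[n, m]), ("IY", IY[n, m])]
    state = max(states, key=lambda t: t[1])
    best = state[1]
    state = next(name for name, v in states if v == best)
    i, j = n, m
    cols: list[tuple[int | None, int | None]] = []
    while i > 0 or j > 0:
        if state == "M":
            cols.append((i, j))
            s = _score(seq_a[i - 1], seq_b[j - 1], table)
            prev = M[i, j] - s
            if np.isclose(prev, M[i - 1, j - 1]):
                state = "M"
            elif np.isclose(prev, IX[i - 1, j - 1]):
                state = "IX"
            else:
                state = "IY"
            i, j = i - 1, j - 1
        elif state == "IX":
            cols.append((i, None))
            if i == 1 and j == 0:
                state = "M"
            elif np.isclose(IX[i, j], M[i - 1, j] - gap_open):
                state = "M"
            else:
                state = "IX"
            i -= 1
        else:  # IY
            cols.append((None, j))
            if j == 1 and i == 0:
                state = "M"
            elif np.isclose(IY[i, j], M[i, j - 1] - gap_open):
                state = "M"
            else:
                state = "IY"
            j -= 1
    cols.reverse()
    aln = Alignment(accession_a=accession_a, accession_b=accession_b,
                    columns=cols, score=float(best))
    aln._res_a, aln._res_b = seq_a, seq_b
    return aln


# ---------------------------------------------------------------------------
# Residue transfer


@dataclass
class ResidueTransfer:
    """Maps source-sequence positions onto a target chain's author numbers."""

    source_accession: str
    structure_id: str
    chain_id: str
    mapping: dict[int, int | str] = field(default_factory=dict)

    def transfer(self, pos: int) -> int | str:
        if pos not in self.mapping:
            raise IndexError(f"position {pos} outside the source sequence")
        return self.mapping[pos]


def transfer_residue(
    alignment: Alignment,
    chain: Chain,
    pos: int,
    offset: int | str = "auto",
) -> int | str:
    """Map source position ``pos`` to the aligned residue's author number.

    Returns the author number, ``"unaligned"`` (aligned to a gap) or
    ``"missing_in_structure"`` (aligned but the residue has no coordinate).
    ``offset`` converts target sequence positions to author numbers; "auto"
    assumes the chain's first residue is target-sequence position 1.
    """
    target_pos = alignment.partner_of_a(pos)
    if target_pos is None:
        return UNALIGNED
    if offset == "auto":
        if not chain.residues:
            return MISSING
        offset = chain.residues[0].author_number - 1
    author = target_pos + int(offset)
    res = chain.get(author)
    if res is None or res.ca is None:
        return MISSING
    return author


def build_transfer(
    alignment: Alignment,
    chain: Chain,
    structure_id: str = "",
    min_identity: float = 0.2,
    offset: int | str = "auto",
) -> ResidueTransfer:
    """Precompute the full source-position -> author-number map for a chain.

    Transfers are refused outright (everything ``"unaligned"``) when global
    identity falls below ``min_identity``, guarding against spurious
    cross-species placement.
    """
    src_positions = [pa for pa, _ in alignment.columns if pa is not None]
    rt = ResidueTransfer(alignment.accession_a, structure_id, chain.chain_id)
    refuse = alignment.identity < min_identity
    for pos in src_positions:
        rt.mapping[pos] = (
            UNALIGNED if refuse else transfer_residue(alignment, chain, pos,
                                                      offset=offset)
        )
    return rt


def identity_transfer(accession: str, chain: Chain,
                      structure_id: str = "") -> ResidueTransfer:
    """Direct-numbering transfer: source position == author number.

    Used when the structure's chains already carry the cross-linked
    species' numbering, so no alignment is needed.
    """
    rt = ResidueTransfer(accession, structure_id, chain.chain_id)
    for r in chain.residues:
        rt.mapping[r.author_number] = (
            r.author_number if r.ca is not None else MISSING
        )
    return rt


# ---------------------------------------------------------------------------
# Orthogroup collapsing


@dataclass
class CollapseReport:
    n_records: int = 0
    unmapped_accessions: set[str] = field(default_factory=set)


def collapse_to_orthogroups(
    records: list[CrossLinkRecord],
    orthomap: OrthoMap,
) -> tuple[list[CrossLinkRecord], CollapseReport]:
    """Relabel records by orthogroup; accessions without a group stay as
    singleton groups under their own name and are tallied in the report.

    Record count and order are preserved; original accessions are retained
    in each record's provenance.
    """
    report = CollapseReport(n_records=len(records))
    out: list[CrossLinkRecord] = []
    for rec in records:
        ga = orthomap.group_for(rec.protein_a)
        gb = orthomap.group_for(rec.protein_b)
        if ga is None:
            report.unmapped_accessions.add(rec.protein_a)
            ga = rec.protein_a
        if gb is None:
            report.unmapped_accessions.add(rec.protein_b)
            gb = rec.protein_b
        out.append(CrossLinkRecord(
            protein_a=ga, residue_a=rec.residue_a,
            protein_b=gb, residue_b=rec.residue_b,
            score=rec.score, fdr=rec.fdr, dataset_id=rec.dataset_id,
            spectral_count=rec.spectral_count,
            provenance=(rec.protein_a, rec.protein_b),
        ))
    return out, report
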