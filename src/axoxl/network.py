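"""Unique-link deduplication and residue-resolution interaction networks.

A cross-link table holds one row per spectral match; many matches support
the same residue pair, possibly with swapped endpoints.  This module
canonicalizes records into unique binary amino-acid interactions, applies
the identification filters (FDR <= 1%, score > 40 by default), and computes
the cohort summary counts: records, unique links, incident proteins and the
intra/intermolecular split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from .io_formats import CrossLinkRecord

logger = logging.getLogger(__name__)

Endpoint = tuple[str, int]

INTRA = "intramolecular"
INTER = "intermolecular"


@dataclass(frozen=True)
class UniqueLink:
    """A canonical unordered residue pair with its support.

    ``end_a <= end_b`` lexicographically (group id, then residue); ``kind``
    is intermolecular iff the two groups differ.
    """

    end_a: Endpoint
    end_b: Endpoint
    kind: str
    support: int
    best_score: float

    @property
    def groups(self) -> tuple[str, str]:
        return (self.end_a[0], self.end_b[0])

    @property
    def key(self) -> tuple[Endpoint, Endpoint]:
        return (self.end_a, self.end_b)


@dataclass
class NetworkSummary:
    n_records: int
    n_unique_links: int
    n_proteins: int
    n_intermolecular: int
    n_intramolecular: int
    n_group_pairs: int  # distinct unordered group pairs (protein-level edges)

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class FilterReport:
    n_in: int = 0
    n_passed: int = 0
    n_removed_fdr: int = 0
    n_removed_score: int = 0


def filter_records(
    records: list[CrossLinkRecord],
    fdr_max: float = 0.01,
    score_min: float = 40.0,
) -> tuple[list[CrossLinkRecord], FilterReport]:
    """Keep records with ``fdr <= fdr_max`` and ``score > score_min``.

    The score comparison is strict (a score exactly at the threshold fails);
    the FDR comparison is inclusive.  Order is preserved.
    """
    report = FilterReport(n_in=len(records))
    passed: list[CrossLinkRecord] = []
    for rec in records:
        if rec.fdr > fdr_max:
            report.n_removed_fdr += 1
        elif not rec.score > score_min:
            report.n_removed_score += 1
        else:
            passed.append(rec)
    report.n_passed = len(passed)
    logger.info(
        "filter: %d in, %d passed, %d removed by FDR, %d removed by score",
        report.n_in, report.n_passed, report.n_removed_fdr,
        report.n_removed_score,
    )
    return passed, report


def canonical_pair(rec: CrossLinkRecord) -> tuple[Endpoint, Endpoint]:
    a: Endpoint = (rec.protein_a, rec.residue_a)
    b: Endpoint = (rec.protein_b, rec.residue_b)
    return (a, b) if a <= b else (b, a)


def deduplicate(records: list[CrossLinkRecord]) -> list[UniqueLink]:
    """Collapse records into unique links; endpoint order never matters.

    Support counts the contributing records; ``best_score`` is their
    maximum.  Output is sorted canonically, so permuting the input records
    or swapping endpoints leaves the result unchanged.
    """
    buckets: dict[tuple[Endpoint, Endpoint], list[CrossLinkRecord]] = {}
    for rec in records:
        buckets.setdefault(canonical_pair(rec), []).append(rec)
    links = [
        UniqueLink(
            end_a=a, end_b=b,
            kind=INTER if a[0] != b[0] else INTRA,
            support=len(recs),
            best_score=max(r.score for r in recs),
        )
        for (a, b), recs in buckets.items()
    ]
    links.sort(key=lambda lk: lk.key)
    return links


def summarize(links: list[UniqueLink],
              records: list[CrossLinkRecord]) -> NetworkSummary:
    groups = {g for lk in links for g in lk.groups}
    n_inter = sum(1 for lk in links if lk.kind == INTER)
    group_pairs = {tuple(sorted(lk.groups)) for lk in links}
    return NetworkSummary(
        n_records=len(records),
        n_unique_links=len(links),
        n_proteins=len(groups),
        n_intermolecular=n_inter,
        n_intramolecular=len(links) - n_inter,
        n_group_pairs=len(group_pairs),
    )


def expand(links: list[UniqueLink]) -> list[CrossLinkRecord]:
    """Inverse-ish of deduplicate: one record per unit of support."""
    out: list[CrossLinkRecord] = []
    for lk in links:
        (ga, ra), (gb, rb) = lk.end_a, lk.end_b
        for _ in range(lk.support):
            out.append(CrossLinkRecord(
                protein_a=ga, residue_a=ra, protein_b=gb, residue_b=rb,
                score=lk.best_score, fdr=0.0, provenance=(ga, gb),
            ))
    return out


def build_arc_diagram_data(
    links: list[UniqueLink],
    groups_of_interest: list[str],
    lengths: dict[str, int],
) -> pd.DataFrame:
    """Per-protein arc table for amino-acid-resolution diagrams.

    One row per (protein, arc): intramolecular arcs connect two positions on
    the protein, intermolecular arcs carry the partner protein and position.
    Proteins without a known length (absent from the FASTA-derived map) are
    warned about and omitted.
    """
    rows = []
    for g in groups_of_interest:
        if g not in lengths:
            warnings.warn(f"no sequence length known for {g!r}; skipped")
            continue
        for lk in links:
            (ga, ra), (gb, rb) = lk.end_a, lk.end_b
            if g == ga == gb:
                rows.append(dict(protein=g, length=lengths[g], pos_i=ra,
                                 pos_j=rb, kind="intra", partner=g,
                                 partner_pos=rb))
            elif g == ga and gb != g:
                rows.append(dict(protein=g, length=lengths[g], pos_i=ra,
                                 pos_j=ra, kind="inter", partner=gb,
                                 partner_pos=rb))
            elif g == gb and ga != g:
                rows.append(dict(protein=g, length=lengths[g], pos_i=rb,
                                 pos_j=rb, kind="inter", partner=ga,
                                 partner_pos=ra))
    cols = ["protein", "length", "pos_i", "pos_j", "kind", "partner",
            "partner_pos"]
    return pd.DataFrame(rows, columns=cols)
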