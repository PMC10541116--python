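"""Placing cross-links on structures and classifying distance satisfaction.

The DSSO cross-linker plus two lysine side chains bounds the C-alpha to
C-alpha distance of a genuine link at ~30 A.  Each unique link is resolved
to (chain, author number) endpoints on a structure, its Euclidean C-alpha
distance measured, and the distance classified: satisfied (<= 30 A),
moderate (30-40 A), extreme (> 100 A) or violated otherwise.  For groups
present in multiple chain copies (homo-oligomers) the chain pair giving the
minimal distance is chosen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import Structure
from .network import INTER, UniqueLink
from .orthomap import MISSING, UNALIGNED, ResidueTransfer

SATISFIED = "satisfied"
MODERATE = "moderate"
VIOLATED = "violated"
EXTREME = "extreme"

PROTEIN_ABSENT = "protein_absent"


@dataclass(frozen=True)
class Thresholds:
    """Distance category boundaries in Angstrom.

    satisfied iff d <= ``satisfied``; moderate iff satisfied < d <=
    ``moderate``; extreme iff d > ``extreme``; violated otherwise.
    """

    satisfied: float = 30.0
    moderate: float = 40.0
    extreme: float = 100.0

    def __post_init__(self) -> None:
        if not (self.satisfied <= self.moderate < self.extreme):
            raise ValueError("thresholds must satisfy "
                             "satisfied <= moderate < extreme")


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class MappedLink:
    link: UniqueLink
    structure_id: str
    chain_a: str | None = None
    author_a: int | None = None
    chain_b: str | None = None
    author_b: int | None = None
    distance: float | None = None
    reason: str | None = None  # unaligned | missing_in_structure | protein_absent
    category: str | None = None


@dataclass
class SatisfactionSummary:
    n_mapped: int
    n_unmappable: int
    n_within_satisfied: int
    n_within_moderate: int
    n_extreme: int
    frac_within_satisfied: float
    frac_within_moderate: float
    mean_intra: float
    mean_inter: float
    per_protein: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "per_protein"}
        return d


def ca_distance(structure: Structure, endpoint_a: tuple[str, int],
                endpoint_b: tuple[str, int]) -> float:
    """Euclidean C-alpha distance (A) between (chain_id, author_number)
    endpoints.  Raises LookupError when a residue is absent or lacks a
    C-alpha coordinate."""
    coords = []
    for chain_id, author in (endpoint_a, endpoint_b):
        res = structure.chain(chain_id).get(author)
        if res is None or res.ca is None:
            raise LookupError(
                f"{MISSING}: {structure.id}/{chain_id}:{author}"
            )
        coords.append(res.ca)
    return float(np.linalg.norm(coords[0] - coords[1]))


def classify_distance(d: float, thresholds: Thresholds = DEFAULT_THRESHOLDS
                      ) -> str:
    if not math.isfinite(d) or d < 0:
        raise ValueError(f"invalid distance: {d}")
    if d <= thresholds.satisfied:
        return SATISFIED
    if d <= thresholds.moderate:
        return MODERATE
    if d > thresholds.extreme:
        return EXTREME
    return VIOLATED


def _resolve_endpoint(
    group: str,
    residue: int,
    structure: Structure,
    chain_map: Mapping[str, Sequence[str]],
    transfers: Mapping[tuple[str, str], ResidueTransfer] | None,
) -> tuple[list[tuple[str, int]], str | None]:
    """Candidate (chain_id, author_number) placements for one endpoint.

    Returns (candidates, reason): empty candidates come with the reason the
    endpoint is unmappable.
    """
    if group not in chain_map:
        return [], PROTEIN_ABSENT
    candidates: list[tuple[str, int]] = []
    reasons: set[str] = set()
    for chain_id in chain_map[group]:
        chain = structure.chain(chain_id)
        if transfers and (group, chain_id) in transfers:
            target = transfers[(group, chain_id)].mapping.get(residue,
                                                              UNALIGNED)
        else:
            res = chain.get(residue)
            target = (residue if res is not None and res.ca is not None
                      else MISSING)
        if isinstance(target, int):
            candidates.append((chain_id, target))
        else:
            reasons.add(target)
    if candidates:
        return candidates, None
    # prefer the more informative reason when mixed
    return [], (MISSING if MISSING in reasons else UNALIGNED)


def map_links(
    links: list[UniqueLink],
    structure: Structure,
    chain_map: Mapping[str, Sequence[str]],
    transfers: Mapping[tuple[str, str], ResidueTransfer] | None = None,
) -> list[MappedLink]:
    """Place each unique link on the structure.

    ``chain_map`` assigns each orthogroup the chain ids that carry it (more
    than one for homo-oligomers).  When multiple chain pairings are
    possible, the pair with minimal C-alpha distance is chosen and recorded.
    Every link yields a MappedLink; unmappable ones carry a reason instead
    of a distance.
    """
    out: list[MappedLink] = []
    for lk in links:
        (ga, ra), (gb, rb) = lk.end_a, lk.end_b
        cand_a, reason_a = _resolve_endpoint(ga, ra, structure, chain_map,
                                             transfers)
        cand_b, reason_b = _resolve_endpoint(gb, rb, structure, chain_map,
                                             transfers)
        if not cand_a or not cand_b:
            out.append(MappedLink(link=lk, structure_id=structure.id,
                                  reason=reason_a or reason_b))
            continue
        best: tuple[float, tuple[str, int], tuple[str, int]] | None = None
        for ea in cand_a:
            for eb in cand_b:
                if ea == eb:
                    continue  # the same physical residue cannot self-link
                d = ca_distance(structure, ea, eb)
                if best is None or d < best[0]:
                    best = (d, ea, eb)
        if best is None:
            out.append(MappedLink(link=lk, structure_id=structure.id,
                                  reason=MISSING))
            continue
        d, (ca_id, aa), (cb_id, ab) = best
        out.append(MappedLink(
            link=lk, structure_id=structure.id,
            chain_a=ca_id, author_a=aa, chain_b=cb_id, author_b=ab,
            distance=d, category=classify_distance(d),
        ))
    return out


def satisfaction_summary(
    mapped: list[MappedLink],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    bin_width: float = 5.0,
) -> tuple[SatisfactionSummary, pd.DataFrame]:
    """Cohort satisfaction fractions plus an intra/inter distance histogram.

    Fractions are computed over mapped (numeric-distance) links only;
    unmappable links are tallied separately.  The histogram table has one
    row per (bin, kind) with counts, mirroring the distance-distribution
    plots used to compare intra- vs intermolecular link lengths.
    """
    numeric = [m for m in mapped if m.distance is not None]
    n = len(numeric)
    within_s = sum(1 for m in numeric if m.distance <= thresholds.satisfied)
    within_m = sum(1 for m in numeric if m.distance <= thresholds.moderate)
    n_extreme = sum(1 for m in numeric if m.distance > thresholds.extreme)
    intra = [m.distance for m in numeric if m.link.kind != INTER]
    inter = [m.distance for m in numeric if m.link.kind == INTER]

    rows = []
    for g in sorted({grp for m in numeric for grp in m.link.groups}):
        sub = [m for m in numeric if g in m.link.groups]
        rows.append(dict(
            protein=g,
            n_mapped=len(sub),
            n_within_satisfied=sum(
                1 for m in sub if m.distance <= thresholds.satisfied),
            n_within_moderate=sum(
                1 for m in sub if m.distance <= thresholds.moderate),
        ))
    per_protein = pd.DataFrame(
        rows, columns=["protein", "n_mapped", "n_within_satisfied",
                       "n_within_moderate"])

    summary = SatisfactionSummary(
        n_mapped=n,
        n_unmappable=len(mapped) - n,
        n_within_satisfied=within_s,
        n_within_moderate=within_m,
        n_extreme=n_extreme,
        frac_within_satisfied=within_s / n if n else 0.0,
        frac_within_moderate=within_m / n if n else 0.0,
        mean_intra=float(np.mean(intra)) if intra else float("nan"),
        mean_inter=float(np.mean(inter)) if inter else float("nan"),
        per_protein=per_protein,
    )

    hist_rows = []
    if numeric:
        top = max(m.distance for m in numeric)
        edges = np.arange(0.0, top + bin_width, bin_width)
        for kind, dists in (("intra", intra), ("inter", inter)):
            counts, _ = np.histogram(dists, bins=edges)
            for lo, c in zip(edges[:-1], counts):
                hist_rows.append(dict(bin_low=lo, bin_high=lo + bin_width,
                                      kind=kind, count=int(c)))
    histogram = pd.DataFrame(
        hist_rows, columns=["bin_low", "bin_high", "kind", "count"])
    return summary, histogram


def mapped_links_table(mapped: list[MappedLink]) -> pd.DataFrame:
    """Per-link TSV-ready table (the Supplementary-Data-2 style export)."""
    rows = []
    for m in mapped:
        (ga, ra), (gb, rb) = m.link.end_a, m.link.end_b
        rows.append(dict(
            group_a=ga, residue_a=ra, group_b=gb, residue_b=rb,
            kind=m.link.kind, structure=m.structure_id,
            chain_a=m.chain_a, author_a=m.author_a,
            chain_b=m.chain_b, author_b=m.author_b,
            distance=m.distance, category=m.category, reason=m.reason,
        ))
    return pd.DataFrame(rows, columns=[
        "group_a", "residue_a", "group_b", "residue_b", "kind", "structure",
        "chain_a", "author_a", "chain_b", "author_b", "distance",
        "category", "reason"])
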