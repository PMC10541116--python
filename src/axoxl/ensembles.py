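"""Cross-link evaluation across conformational ensembles and oligomer
lattices.

Motor complexes such as the outer dynein arm are caught in several distinct
conformations; a link violated on one structure is still consistent with
the data if *some* conformation places its endpoints within the linker
span.  Likewise, complexes repeated head-to-tail along the axoneme can turn
an apparently extreme intramolecular violation into a short inter-copy
link.  Both disambiguation steps live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import Chain, ResidueRecord, Structure
from .network import UniqueLink
from .orthomap import ResidueTransfer
from .structmap import map_links


@dataclass
class Ensemble:
    """Alternative conformations of one complex, sharing chain/residue
    naming; members may differ in which residues are resolved."""

    label: str
    members: list[Structure] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.members:
            ids = set(self.members[0].chain_ids())
            for m in self.members[1:]:
                if set(m.chain_ids()) != ids:
                    raise ValueError(
                        f"ensemble {self.label}: members disagree on chains"
                    )


@dataclass
class OligomerLattice:
    """Rigid-body copies of a base complex: copy k = T^k(base)."""

    base: Structure
    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # (3,) in Angstrom
    n_copies: int = 3

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("transform must be a 3x3 rotation and a "
                             "3-vector translation")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3),
                           atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")
        if self.n_copies < 2:
            raise ValueError("a lattice needs at least 2 copies")


@dataclass
class HeatmapResult:
    """links x conformations distance matrix with per-link minima."""

    matrix: pd.DataFrame  # rows: link labels; cols: member ids; NaN unmappable
    min_distance: pd.Series
    best_member: pd.Series  # conformation id of the per-link argmin
    all_unmappable: pd.Series


def _link_label(lk: UniqueLink) -> str:
    (ga, ra), (gb, rb) = lk.end_a, lk.end_b
    return f"{ga}:{ra}--{gb}:{rb}"


def distance_heatmap(
    links: list[UniqueLink],
    ensemble: Ensemble,
    chain_map: Mapping[str, Sequence[str]],
    transfers: Mapping[tuple[str, str], ResidueTransfer] | None = None,
) -> HeatmapResult:
    """Evaluate every link on every conformation.

    Entry (i, j) is the C-alpha distance of link i on member j, NaN where
    the link cannot be mapped on that member.  Unmappable cells are ignored
    by the per-link minimum; a link unmappable everywhere is flagged.
    """
    cols = {}
    for member in ensemble.members:
        mapped = map_links(links, member, chain_map, transfers)
        cols[member.id] = [m.distance if m.distance is not None else np.nan
                           for m in mapped]
    matrix = pd.DataFrame(cols, index=[_link_label(lk) for lk in links])
    all_nan = matrix.isna().all(axis=1)
    min_distance = matrix.min(axis=1, skipna=True)
    best_member = matrix.idxmin(axis=1, skipna=True)
    best_member[all_nan] = None
    return HeatmapResult(matrix=matrix, min_distance=min_distance,
                         best_member=best_member, all_unmappable=all_nan)


def satisfiable_by_any(heatmap: HeatmapResult, cutoff: float = 30.0
                       ) -> pd.DataFrame:
    """Per-link verdict: satisfied by at least one conformation?

    True iff the minimum over numeric cells is <= cutoff; the best
    (minimizing) conformation is reported alongside.
    """
    verdict = (heatmap.min_distance <= cutoff) & ~heatmap.all_unmappable
    return pd.DataFrame({
        "min_distance": heatmap.min_distance,
        "best_member": heatmap.best_member,
        "satisfiable": verdict,
        "all_unmappable": heatmap.all_unmappable,
    })


def _apply_k(rotation: np.ndarray, translation: np.ndarray, k: int,
             coords: np.ndarray) -> np.ndarray:
    out = coords.astype(float)
    for _ in range(k):
        out = out @ rotation.T + translation
    return out


def expand_lattice(lattice: OligomerLattice) -> Structure:
    """Materialize the lattice as one structure; copy k's chains are named
    ``<chain>@<k>`` (copy 0 is the base itself)."""
    chains: list[Chain] = []
    for k in range(lattice.n_copies):
        for ch in lattice.base.chains:
            residues = []
            for r in ch.residues:
                ca = None
                if r.ca is not None:
                    ca = _apply_k(lattice.rotation, lattice.translation, k,
                                  r.ca[None, :])[0]
                residues.append(ResidueRecord(
                    author_number=r.author_number, icode=r.icode,
                    one_letter=r.one_letter, ca=ca))
            chains.append(Chain(chain_id=f"{ch.chain_id}@{k}",
                                residues=residues))
    return Structure(id=f"{lattice.base.id}_x{lattice.n_copies}",
                     chains=chains)


def reinterpret_intralinks(
    violating_links: list[UniqueLink],
    lattice: OligomerLattice,
    chain_map: Mapping[str, Sequence[str]],
    cutoff: float = 30.0,
) -> pd.DataFrame:
    """Re-read intramolecular violations as links between adjacent copies.

    For each link (i, j) the minimal distance over ordered copy pairs
    k != l of d(copy_k.i, copy_l.j) is reported, with the minimizing pair
    and the verdict ``distance <= cutoff``.  ``chain_map`` resolves groups
    to base-structure chain ids; endpoint residue numbers are author
    numbers on those chains.
    """
    expanded = expand_lattice(lattice)
    rows = []
    for lk in violating_links:
        (ga, ra), (gb, rb) = lk.end_a, lk.end_b
        best = None
        for k in range(lattice.n_copies):
            for l in range(lattice.n_copies):
                if k == l:
                    continue
                d = _min_cross_copy(expanded, chain_map, ga, ra, k, gb, rb, l)
                if d is not None and (best is None or d < best[0]):
                    best = (d, k, l)
        if best is None:
            rows.append(dict(link=_link_label(lk), distance=np.nan,
                             copy_a=None, copy_b=None, satisfied=False,
                             unmappable=True))
        else:
            d, k, l = best
            rows.append(dict(link=_link_label(lk), distance=d, copy_a=k,
                             copy_b=l, satisfied=bool(d <= cutoff),
                             unmappable=False))
    return pd.DataFrame(rows, columns=["link", "distance", "copy_a",
                                       "copy_b", "satisfied", "unmappable"])


def _min_cross_copy(expanded: Structure, chain_map, ga, ra, k, gb, rb, l
                    ) -> float | None:
    """Min distance of endpoint a on copy k vs endpoint b on copy l."""
    best = None
    for ca_id in chain_map.get(ga, []):
        for cb_id in chain_map.get(gb, []):
            try:
                ra_res = expanded.chain(f"{ca_id}@{k}").get(ra)
                rb_res = expanded.chain(f"{cb_id}@{l}").get(rb)
            except KeyError:
                continue
            if ra_res is None or ra_res.ca is None:
                continue
            if rb_res is None or rb_res.ca is None:
                continue
            d = float(np.linalg.norm(ra_res.ca - rb_res.ca))
            if best is None or d < best:
                best = d
    return best
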