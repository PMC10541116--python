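"""Synthetic structures, ensembles, lattices and cross-link tables with
known ground truth.

Everything downstream — filtering, deduplication, distance classification,
ensemble disambiguation, lattice reinterpretation, rigid fitting — is
exercised against data generated here, where every link's generating class
(true contact vs false identification) and true C-alpha distance are known.

Chains are C-alpha traces only: either ideal-helix geometry or a
self-avoiding 3.8 A random walk.  No side-chain or Ramachandran realism is
attempted; the generator reproduces the *distance statistics* the pipeline
consumes, not protein physics.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .ensembles import Ensemble, OligomerLattice
from .io_formats import Chain, CrossLinkRecord, OrthoMap, ResidueRecord, Structure
from .network import UniqueLink, INTRA

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

CA_STEP = 3.8  # consecutive C-alpha spacing, Angstrom
MIN_CLEARANCE = 3.0  # self-avoidance radius, Angstrom

HELIX_RADIUS = 2.3  # Angstrom
HELIX_RISE = 1.5  # Angstrom per residue
HELIX_TURN = 100.0  # degrees per residue


def task_rng(seed: int, task: str) -> np.random.Generator:
    """A named generator per sub-task: adding a generator never perturbs
    the streams of the others."""
    return np.random.default_rng([seed, zlib.crc32(task.encode())])


@dataclass
class SynthSpec:
    """Parameters of the synthetic study system.

    Defaults model a small five-protein sub-complex probed by a cleavable
    amine-reactive linker: true links are drawn from residue pairs whose
    C-alpha distance is within the 25 A bulk of the linker's reach, false
    identifications from arbitrary pairs at a controlled rate, and score /
    FDR fields mimic a confident (score ~90) true population against a
    low-scoring false one.
    """

    seed: int = 0
    n_proteins: int = 5
    length_range: tuple[int, int] = (80, 140)
    geometry: str = "random-walk-3.8"  # or "extended-helix"
    n_true_links: int = 120
    true_max_distance: float = 25.0
    false_rate: float = 0.1
    duplicate_rate: float = 0.15
    true_score: tuple[float, float] = (90.0, 20.0)  # normal mu, sigma
    false_score: tuple[float, float] = (35.0, 15.0)
    true_fdr_max: float = 0.009
    false_fdr_max: float = 0.05
    min_seq_separation: int = 3  # same-chain pairs closer in sequence are skipped

    def __post_init__(self) -> None:
        for rate in (self.false_rate, self.duplicate_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Structures


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _random_walk(length: int, rng: np.random.Generator,
                 start: np.ndarray) -> np.ndarray:
    """Self-avoiding 3.8 A-step walk; each new point keeps >= 3.0 A from
    all non-adjacent predecessors (best candidate is accepted if 100 draws
    all clash, which keeps generation total)."""
    pts = [np.asarray(start, float)]
    for _ in range(length - 1):
        cands = pts[-1] + CA_STEP * _random_unit(rng, 100)
        if len(pts) < 2:
            pts.append(cands[0])
            continue
        prev = np.array(pts[:-1])
        clearance = cdist(cands, prev).min(axis=1)
        ok = np.nonzero(clearance >= MIN_CLEARANCE)[0]
        pick = ok[0] if ok.size else int(np.argmax(clearance))
        pts.append(cands[pick])
    return np.array(pts)


def _helix(length: int, start: np.ndarray) -> np.ndarray:
    i = np.arange(length)
    theta = np.deg2rad(HELIX_TURN * i)
    pts = np.column_stack([
        HELIX_RADIUS * np.cos(theta),
        HELIX_RADIUS * np.sin(theta),
        HELIX_RISE * i,
    ])
    return pts + np.asarray(start, float)


def make_structure(
    length: int,
    geometry: str = "random-walk-3.8",
    rng: np.random.Generator | None = None,
    chain_id: str = "A",
    structure_id: str = "synth",
    start: np.ndarray | tuple = (0.0, 0.0, 0.0),
    start_author: int = 1,
) -> tuple[Structure, str]:
    """One synthetic chain with its sequence.

    Consecutive C-alpha spacing is exactly 3.8 A for the random walk and
    the ideal-helix step length for the helix.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if geometry == "random-walk-3.8":
        coords = _random_walk(length, rng, np.asarray(start, float))
    elif geometry == "extended-helix":
        coords = _helix(length, np.asarray(start, float))
    else:
        raise ValueError(f"unknown geometry: {geometry!r}")
    seq = "".join(rng.choice(list(AA_ALPHABET), size=length))
    residues = [
        ResidueRecord(author_number=start_author + i, one_letter=seq[i],
                      ca=coords[i])
        for i in range(length)
    ]
    return Structure(id=structure_id,
                     chains=[Chain(chain_id=chain_id, residues=residues)]), seq


@dataclass
class SynthComplex:
    """A multi-chain synthetic complex plus all the bookkeeping the
    pipeline needs: sequences, orthogroup table and chain assignments."""

    structure: Structure
    seqs: dict[str, str]
    orthomap: OrthoMap
    chain_map: dict[str, list[str]]  # orthogroup -> chain ids
    accession_of_chain: dict[str, str]


def make_complex(spec: SynthSpec) -> SynthComplex:
    """Assemble ``n_proteins`` chains into one loosely packed complex.

    Chain k starts ~10 A from a random residue of chain k-1, so genuinely
    close inter-chain residue pairs always exist.  Accessions are
    SYNP0001.. with orthogroups OG0001.. (one protein per group; paralogy
    is layered on by tests that need it).
    """
    rng = task_rng(spec.seed, "complex")
    chains: list[Chain] = []
    seqs: dict[str, str] = {}
    entries: dict[str, str] = {}
    names: dict[str, str] = {}
    chain_map: dict[str, list[str]] = {}
    acc_of: dict[str, str] = {}
    prev_coords: np.ndarray | None = None
    for k in range(spec.n_proteins):
        length = int(rng.integers(spec.length_range[0],
                                  spec.length_range[1] + 1))
        if prev_coords is None:
            start = np.zeros(3)
        else:
            anchor = prev_coords[rng.integers(len(prev_coords))]
            start = anchor + 10.0 * _random_unit(rng)[0]
        cid = chr(ord("A") + k)
        st, seq = make_structure(length, spec.geometry, rng, chain_id=cid,
                                 start=start)
        chain = st.chains[0]
        chains.append(chain)
        acc = f"SYNP{k + 1:04d}"
        group = f"OG{k + 1:04d}"
        seqs[acc] = seq
        entries[acc] = group
        names[group] = f"GENE{k + 1}"
        chain_map[group] = [cid]
        acc_of[cid] = acc
        prev_coords = chain.ca_array()
    return SynthComplex(
        structure=Structure(id="synth_complex", chains=chains),
        seqs=seqs,
        orthomap=OrthoMap(entries=entries, group_names=names),
        chain_map=chain_map,
        accession_of_chain=acc_of,
    )


# ---------------------------------------------------------------------------
# Cross-link sampling


def _all_pairs(cx: SynthComplex, min_sep: int):
    """All eligible residue pairs with their true distances."""
    entries = []  # (chain_id, author_number, ca)
    for ch in cx.structure.chains:
        for r in ch.resolved():
            entries.append((ch.chain_id, r.author_number, r.ca))
    coords = np.array([e[2] for e in entries])
    dmat = cdist(coords, coords)
    pairs = []
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            ci, ni, _ = entries[i]
            cj, nj, _ = entries[j]
            if ci == cj and abs(ni - nj) < min_sep:
                continue
            pairs.append((i, j, float(dmat[i, j])))
    return entries, pairs


def sample_crosslinks(
    cx: SynthComplex, spec: SynthSpec,
) -> tuple[list[CrossLinkRecord], pd.DataFrame]:
    """Draw a cross-link table plus its ground truth.

    True links are uniform over residue pairs with true distance <=
    ``true_max_distance``; false links are uniform over *all* eligible
    pairs, at a count making the false fraction equal ``false_rate``.
    Duplicate records (possibly endpoint-swapped) are injected at
    ``duplicate_rate``.  Ground truth records each unique pair's class and
    true distance.
    """
    rng = task_rng(spec.seed, "crosslinks")
    entries, pairs = _all_pairs(cx, spec.min_seq_separation)
    close = [p for p in pairs if p[2] <= spec.true_max_distance]
    n_true = min(spec.n_true_links, len(close))
    true_idx = rng.choice(len(close), size=n_true, replace=False)
    chosen_true = [close[i] for i in true_idx]
    if spec.false_rate >= 1.0:
        chosen_true = []
        n_false = spec.n_true_links
    else:
        n_false = int(round(n_true * spec.false_rate / (1 - spec.false_rate)))
    taken = {(p[0], p[1]) for p in chosen_true}
    false_pool = [p for p in pairs if (p[0], p[1]) not in taken]
    false_idx = rng.choice(len(false_pool),
                           size=min(n_false, len(false_pool)), replace=False)
    chosen_false = [false_pool[i] for i in false_idx]

    records: list[CrossLinkRecord] = []
    truth_rows = []

    def emit(pair, label):
        i, j, dist = pair
        ci, ni, _ = entries[i]
        cj, nj, _ = entries[j]
        acc_a, acc_b = cx.accession_of_chain[ci], cx.accession_of_chain[cj]
        mu, sigma = spec.true_score if label == "true" else spec.false_score
        fdr_max = spec.true_fdr_max if label == "true" else spec.false_fdr_max
        n_copies = 1 + (rng.random() < spec.duplicate_rate)
        for c in range(n_copies):
            if c == 0 or rng.random() < 0.5:
                pa, ra, pb, rb = acc_a, ni, acc_b, nj
            else:
                pa, ra, pb, rb = acc_b, nj, acc_a, ni
            records.append(CrossLinkRecord(
                protein_a=pa, residue_a=ra, protein_b=pb, residue_b=rb,
                score=max(0.1, float(rng.normal(mu, sigma))),
                fdr=float(rng.uniform(0.0, fdr_max)),
                dataset_id=f"XL{rng.integers(1, 3)}",
            ))
        truth_rows.append(dict(
            protein_a=acc_a, residue_a=ni, protein_b=acc_b, residue_b=nj,
            label=label, true_distance=dist, n_records=n_copies,
        ))

    for p in chosen_true:
        emit(p, "true")
    for p in chosen_false:
        emit(p, "false")
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = pd.DataFrame(truth_rows, columns=[
        "protein_a", "residue_a", "protein_b", "residue_b", "label",
        "true_distance", "n_records"])
    return records, truth


# ---------------------------------------------------------------------------
# Ensembles (hinge motion)


@dataclass
class HingeSpec:
    """Rigid hinge: residues past ``pivot_author`` rotate by each angle (in
    degrees) about ``axis`` through the pivot's C-alpha."""

    pivot_author: int
    angles: tuple[float, ...] = (35.0,)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    chain_id: str | None = None  # default: first chain


def make_ensemble(structure: Structure, hinge: HingeSpec,
                  label: str = "hinge") -> Ensemble:
    """Base conformation plus one member per hinge angle.

    Pre-pivot coordinates are bitwise identical across members.
    """
    cid = hinge.chain_id or structure.chains[0].chain_id
    members = [_relabel(structure, f"{structure.id}_m0")]
    axis = np.asarray(hinge.axis, float)
    axis = axis / np.linalg.norm(axis)
    base_chain = structure.chain(cid)
    pivot = base_chain.get(hinge.pivot_author)
    if pivot is None or pivot.ca is None:
        raise ValueError(f"pivot residue {hinge.pivot_author} has no C-alpha")
    for mi, angle in enumerate(hinge.angles, start=1):
        rot = Rotation.from_rotvec(np.deg2rad(angle) * axis)
        chains = []
        for ch in structure.chains:
            residues = []
            for r in ch.residues:
                ca = r.ca
                if (ca is not None and ch.chain_id == cid
                        and r.author_number > hinge.pivot_author):
                    ca = rot.apply(ca - pivot.ca) + pivot.ca
                residues.append(ResidueRecord(
                    author_number=r.author_number, icode=r.icode,
                    one_letter=r.one_letter,
                    ca=None if ca is None else np.array(ca)))
            chains.append(Chain(chain_id=ch.chain_id, residues=residues))
        members.append(Structure(id=f"{structure.id}_m{mi}", chains=chains))
    return Ensemble(label=label, members=members)


def _relabel(structure: Structure, new_id: str) -> Structure:
    return Structure(id=new_id, chains=structure.chains)


@dataclass
class HingeTestcase:
    ensemble: Ensemble
    links: list[UniqueLink]
    true_member: dict[str, str]  # link label -> generating member id
    chain_map: dict[str, list[str]]
    group: str


def _hinge_pools(ens: Ensemble, length: int, max_distance: float,
                 margin: float) -> dict[int, list]:
    """Residue-index pairs close in exactly one of two conformations."""
    cas = {mi: m.chains[0].ca_array() for mi, m in enumerate(ens.members)}
    d0 = cdist(cas[0], cas[0])
    d1 = cdist(cas[1], cas[1])
    per_state: dict[int, list] = {0: [], 1: []}
    for i in range(length):
        for j in range(i + 3, length):
            if d0[i, j] <= max_distance and d1[i, j] > margin:
                per_state[0].append((i, j))
            elif d1[i, j] <= max_distance and d0[i, j] > margin:
                per_state[1].append((i, j))
    return per_state if (per_state[0] or per_state[1]) else {}


def make_hinge_testcase(
    seed: int = 0,
    length: int = 120,
    pivot: int = 60,
    angle: float = 150.0,
    n_links_per_state: int = 8,
    max_distance: float = 25.0,
    margin: float = 40.0,
) -> HingeTestcase:
    """Two-state hinge with links planted in exactly one state each.

    Planted links are <= ``max_distance`` in their generating conformation
    and > ``margin`` in the other, so per-link argmin over the ensemble
    identifies the generating state.  Not every random chain offers such
    pairs; chains are regenerated (deterministically) until one does.
    """
    rng = None
    for attempt in range(64):
        rng = task_rng(seed, f"hinge-{attempt}")
        st, _ = make_structure(length, "random-walk-3.8", rng,
                               structure_id="hinge_base")
        ens = make_ensemble(st, HingeSpec(pivot_author=pivot,
                                          angles=(angle,)))
        if _hinge_pools(ens, length, max_distance, margin):
            break
    else:
        raise RuntimeError("no plantable state-specific pairs found")
    group = "OGHINGE"
    chain_map = {group: [st.chains[0].chain_id]}
    links: list[UniqueLink] = []
    true_member: dict[str, str] = {}
    per_state = _hinge_pools(ens, length, max_distance, margin)
    nums = [r.author_number for r in ens.members[0].chains[0].resolved()]
    for state, pool in per_state.items():
        if not pool:
            continue
        take = rng.choice(len(pool),
                          size=min(n_links_per_state, len(pool)),
                          replace=False)
        for t in take:
            i, j = pool[t]
            a, b = (group, nums[i]), (group, nums[j])
            if b < a:
                a, b = b, a
            lk = UniqueLink(end_a=a, end_b=b, kind=INTRA, support=1,
                            best_score=100.0)
            links.append(lk)
            label = f"{a[0]}:{a[1]}--{b[0]}:{b[1]}"
            true_member[label] = ens.members[state].id
    return HingeTestcase(ensemble=ens, links=links, true_member=true_member,
                         chain_map=chain_map, group=group)


# ---------------------------------------------------------------------------
# Oligomer lattice (head-to-tail copies)


@dataclass
class OligomerTestcase:
    base: Structure
    lattice: OligomerLattice
    planted_links: list[UniqueLink]
    negative_links: list[UniqueLink]
    chain_map: dict[str, list[str]]
    group: str


def make_oligomer_testcase(
    seed: int = 0,
    length: int = 110,
    gap: float = 8.0,
    n_links: int = 10,
    n_copies: int = 3,
) -> OligomerTestcase:
    """Head-to-tail translated copies with planted inter-copy links.

    The base is an extended helix spanning > 100 A along z; copies repeat
    at (span + gap) along z.  Planted links join a residue near the head to
    one near the tail: intramolecular distance > 100 A, but the head of
    copy k sits within ~``gap`` + a few A of the tail of copy k+1, so the
    minimal inter-copy distance is <= 25 A by construction.  Negative
    controls are endpoint-shuffled random pairs.
    """
    rng = task_rng(seed, "oligomer")
    base, _ = make_structure(length, "extended-helix", rng,
                             structure_id="oligo_base")
    span = HELIX_RISE * (length - 1)
    if span <= 100.0:
        raise ValueError("base must span > 100 A for extreme violations")
    lattice = OligomerLattice(
        base=base, rotation=np.eye(3),
        translation=np.array([0.0, 0.0, span + gap]),
        n_copies=n_copies,
    )
    group = "OGOLIG"
    chain = base.chains[0]
    cas = chain.ca_array()
    nums = [r.author_number for r in chain.resolved()]
    planted: list[UniqueLink] = []
    head = list(range(length - 5, length))
    tail = list(range(0, 5))
    combos = [(i, j) for i in head for j in tail]
    take = rng.choice(len(combos), size=min(n_links, len(combos)),
                      replace=False)
    for t in take:
        i, j = combos[t]
        intra = float(np.linalg.norm(cas[i] - cas[j]))
        inter = float(np.linalg.norm(
            cas[i] - (cas[j] + lattice.translation)))
        assert intra > 100.0 and inter <= 25.0, "construction invariant"
        a, b = (group, nums[i]), (group, nums[j])
        if b < a:
            a, b = b, a
        planted.append(UniqueLink(end_a=a, end_b=b, kind=INTRA, support=1,
                                  best_score=100.0))
    negatives: list[UniqueLink] = []
    while len(negatives) < n_links:
        i, j = rng.integers(0, length, size=2)
        if abs(int(i) - int(j)) < 3:
            continue
        a, b = (group, nums[int(i)]), (group, nums[int(j)])
        if b < a:
            a, b = b, a
        negatives.append(UniqueLink(end_a=a, end_b=b, kind=INTRA, support=1,
                                    best_score=100.0))
    return OligomerTestcase(base=base, lattice=lattice,
                            planted_links=planted, negative_links=negatives,
                            chain_map={group: [chain.chain_id]}, group=group)
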