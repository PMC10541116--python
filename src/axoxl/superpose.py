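"""Rigid-body superposition (Kabsch) and model-to-backbone fitting.

Used to place a candidate atomic model (e.g. a predicted dimer) onto an
unassigned stretch of backbone in an experimental structure, report the
RMSD of the fit, and check whether the cross-links involving the model are
satisfied by that placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Chain, Structure
from .structmap import Thresholds, DEFAULT_THRESHOLDS, classify_distance


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper (det +1)
    translation: np.ndarray  # (3,) Angstrom; maps model frame onto target
    rmsd: float
    n_atoms: int
    correspondence: str = ""

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray,
           correspondence: str = "") -> SuperpositionResult:
    """Least-squares rigid superposition of A onto B.

    Returns the proper rotation R and translation t minimizing
    RMSD(R A + t, B); reflections are corrected through the sign of the
    smallest singular value.  Requires n >= 3 non-collinear points.
    """
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (n, 3) arrays")
    n = A.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    if np.linalg.matrix_rank(Ac, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinate set")
    H = Ac.T @ Bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = Ac @ R.T - Bc
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               n_atoms=n, correspondence=correspondence)


def fit_model_to_chain(
    model, target_chain: Chain, mode: str = "sliding-window",
) -> tuple[SuperpositionResult, int, pd.DataFrame]:
    """Fit a model C-alpha trace onto a target chain's resolved trace.

    ``model`` is an (n, 3) array or a :class:`Chain`.  In
    ``sliding-window`` mode the model trace is slid along the target's
    resolved C-alphas and Kabsch-fitted at every offset; the minimal-RMSD
    placement wins, smallest offset on ties.  In ``sequence-aligned`` mode
    residues are corresponded by author number (offset reported as 0).
    Returns (best result, best offset, offset-vs-rmsd profile).
    """
    if isinstance(model, Chain):
        model_chain = model
        model_cas = model.ca_array()
    else:
        model_chain = None
        model_cas = np.asarray(model, float)

    if mode == "sequence-aligned":
        if model_chain is None:
            raise ValueError("sequence-aligned mode requires a Chain model")
        target_by_num = {r.author_number: r.ca
                         for r in target_chain.resolved()}
        pairs = [(r.ca, target_by_num[r.author_number])
                 for r in model_chain.resolved()
                 if r.author_number in target_by_num]
        if len(pairs) < 3:
            raise ValueError("fewer than 3 corresponded residues")
        A = np.array([p[0] for p in pairs])
        B = np.array([p[1] for p in pairs])
        res = kabsch(A, B, correspondence="author-number")
        profile = pd.DataFrame({"offset": [0], "rmsd": [res.rmsd]})
        return res, 0, profile

    if mode != "sliding-window":
        raise ValueError(f"unknown mode: {mode!r}")
    target_cas = target_chain.ca_array()
    n, m = len(model_cas), len(target_cas)
    if n > m:
        raise ValueError(
            f"model ({n} residues) longer than target resolved trace ({m})"
        )
    offsets = []
    rmsds = []
    best: tuple[float, int, SuperpositionResult] | None = None
    for off in range(m - n + 1):
        res = kabsch(model_cas, target_cas[off:off + n],
                     correspondence=f"sliding-window offset {off}")
        offsets.append(off)
        rmsds.append(res.rmsd)
        if best is None or res.rmsd < best[0]:
            best = (res.rmsd, off, res)
    profile = pd.DataFrame({"offset": offsets, "rmsd": rmsds})
    return best[2], best[1], profile


def check_crosslink_consistency(
    superposition: SuperpositionResult,
    links: list[tuple[np.ndarray, tuple[str, int]]],
    partner_structure: Structure,
    cutoff: float = 30.0,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Check links between a placed model and a partner structure.

    Each link pairs a model-frame C-alpha coordinate with a
    (chain_id, author_number) endpoint on the partner structure.  The model
    coordinate is moved by the superposition, the C-alpha distance
    computed, and classified with the standard distance rules.
    """
    rows = []
    for i, (model_ca, (chain_id, author)) in enumerate(links):
        placed = superposition.apply(np.asarray(model_ca, float)[None, :])[0]
        res = partner_structure.chain(chain_id).get(author)
        if res is None or res.ca is None:
            rows.append(dict(link=i, distance=np.nan, category=None,
                             satisfied=False, unmappable=True))
            continue
        d = float(np.linalg.norm(placed - res.ca))
        rows.append(dict(link=i, distance=d,
                         category=classify_distance(d, thresholds),
                         satisfied=bool(d <= cutoff), unmappable=False))
    return pd.DataFrame(rows, columns=["link", "distance", "category",
                                       "satisfied", "unmappable"])
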