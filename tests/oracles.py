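"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: alignment scores come
from brute-force path enumeration (and, separately, Biopython's aligner),
not from the package's dynamic program.
"""

from __future__ import annotations

import functools
import itertools

import numpy as np


@functools.lru_cache(maxsize=64)
def alignment_paths(n: int, m: int, gap_open: float, gap_extend: float):
    """Every monotone alignment path through an n x m grid.

    Returns a list of (diagonal_cells, gap_penalty): the substitution part
    of a path's score depends on the sequences only through the diagonal
    cells, while the affine gap part (first gap step costs ``gap_open``,
    each further step ``gap_extend``) is a property of the path shape.
    """
    out = []

    def rec(i, j, last, diag, pen):
        if i == n and j == m:
            out.append((tuple(diag), pen))
            return
        if i < n and j < m:
            rec(i + 1, j + 1, "D", diag + [(i, j)], pen)
        if i < n:
            rec(i + 1, j, "U", diag,
                pen + (gap_extend if last == "U" else gap_open))
        if j < m:
            rec(i, j + 1, "L", diag,
                pen + (gap_extend if last == "L" else gap_open))

    rec(0, 0, None, [], 0.0)
    return out


def brute_force_align_score(seq_a, seq_b, score_fn, gap_open=11.0,
                            gap_extend=1.0):
    """Optimal global alignment score by exhaustive path enumeration."""
    best = -np.inf
    for diag, pen in alignment_paths(len(seq_a), len(seq_b), gap_open,
                                     gap_extend):
        s = -pen + sum(score_fn(seq_a[i], seq_b[j]) for i, j in diag)
        best = max(best, s)
    return best


def all_pair_scores_vectorized(alphabet, max_len, score_matrix, gap_open=11.0,
                               gap_extend=1.0):
    """Brute-force optimal scores for every ordered sequence pair with
    lengths 1..max_len over ``alphabet``, vectorized over pairs.

    ``score_matrix[(a, b)]`` gives substitution scores.  Yields
    (seqs_a, seqs_b, score_grid) per length combination.
    """
    k = len(alphabet)
    S = np.array([[score_matrix[(a, b)] for b in alphabet] for a in alphabet])
    seqs_by_len = {
        n: ["".join(t) for t in itertools.product(alphabet, repeat=n)]
        for n in range(1, max_len + 1)
    }
    idx_by_len = {
        n: np.array([[alphabet.index(c) for c in s] for s in seqs_by_len[n]])
        for n in seqs_by_len
    }
    for n in range(1, max_len + 1):
        for m in range(1, max_len + 1):
            A, B = idx_by_len[n], idx_by_len[m]
            best = np.full((len(A), len(B)), -np.inf)
            for diag, pen in alignment_paths(n, m, gap_open, gap_extend):
                sub = np.zeros((len(A), len(B)))
                for i, j in diag:
                    sub += S[A[:, i][:, None], B[None, :, j]]
                np.maximum(best, sub - pen, out=best)
            yield seqs_by_len[n], seqs_by_len[m], best
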