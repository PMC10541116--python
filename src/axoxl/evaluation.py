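"""Ground-truth recovery metrics on synthetic systems.

Each function runs the real pipeline stages end to end on generated data
and measures how well known truth is recovered: classification of true
links, attribution of state-specific links to their generating
conformation, lattice reinterpretation of planted head-to-tail links, and
planted-offset recovery of the sliding-window fit.  These are the
quantities the package's own validation reports.
"""

from __future__ import annotations

import numpy as np

from .ensembles import distance_heatmap, reinterpret_intralinks, satisfiable_by_any
from .network import deduplicate, filter_records
from .orthomap import collapse_to_orthogroups
from .structmap import SATISFIED, Thresholds, map_links
from .superpose import fit_model_to_chain
from .synthdata import (SynthSpec, make_complex, make_hinge_testcase,
                        make_oligomer_testcase, make_structure,
                        sample_crosslinks, task_rng)


def end_to_end_recovery(
    seed: int,
    false_rate: float = 0.1,
    n_proteins: int = 5,
    thresholds: Thresholds = Thresholds(),
) -> dict:
    """Full pipeline on one synthetic complex: sample -> filter ->
    collapse -> deduplicate -> map -> classify, scored against truth.

    Returns the network summary counts plus the fraction of ground-truth
    true links classified satisfied and of false links classified beyond
    the satisfied cutoff, along with the brute-force geometric expectation
    for the latter (the fraction of all eligible residue pairs farther
    than the cutoff).
    """
    spec = SynthSpec(seed=seed, false_rate=false_rate, n_proteins=n_proteins)
    cx = make_complex(spec)
    records, truth = sample_crosslinks(cx, spec)
    filtered, _ = filter_records(records)
    collapsed, _ = collapse_to_orthogroups(filtered, cx.orthomap)
    links = deduplicate(collapsed)
    mapped = map_links(links, cx.structure, cx.chain_map)
    category = {m.link.key: m.category for m in mapped}

    group_of = cx.orthomap.entries

    def truth_key(row):
        a = (group_of[row.protein_a], row.residue_a)
        b = (group_of[row.protein_b], row.residue_b)
        return (a, b) if a <= b else (b, a)

    # False links mostly carry low scores, so many never reach distance
    # classification; the violated fraction is over classified ones only.
    n_true = n_true_sat = n_false = n_false_classified = n_false_viol = 0
    for row in truth.itertuples():
        cat = category.get(truth_key(row))
        if row.label == "true":
            n_true += 1
            n_true_sat += cat == SATISFIED
        else:
            n_false += 1
            if cat is not None:
                n_false_classified += 1
                n_false_viol += cat != SATISFIED

    # geometric expectation: chance a uniform eligible pair exceeds cutoff
    from .synthdata import _all_pairs

    _, pairs = _all_pairs(cx, spec.min_seq_separation)
    dists = np.array([p[2] for p in pairs])
    expectation = float((dists > thresholds.satisfied).mean())

    from .network import summarize

    summary = summarize(links, collapsed)
    return {
        "n_records": summary.n_records,
        "n_unique_links": summary.n_unique_links,
        "n_proteins": summary.n_proteins,
        "n_intermolecular": summary.n_intermolecular,
        "n_intramolecular": summary.n_intramolecular,
        "n_true_links": n_true,
        "n_false_links": n_false,
        "n_false_classified": n_false_classified,
        "frac_true_satisfied": n_true_sat / n_true if n_true else 0.0,
        "frac_false_violated": (n_false_viol / n_false_classified
                                if n_false_classified else 0.0),
        "geometric_violation_expectation": expectation,
    }


def hinge_attribution(seed: int, cutoff: float = 30.0) -> dict:
    """Planted two-state hinge: are state-specific links satisfied by the
    ensemble, and does the per-link argmin recover the generating state?"""
    tc = make_hinge_testcase(seed=seed)
    hm = distance_heatmap(tc.links, tc.ensemble, tc.chain_map)
    v = satisfiable_by_any(hm, cutoff=cutoff)
    n = len(tc.true_member)
    n_correct = sum(
        1 for label, member in tc.true_member.items()
        if v.loc[label, "best_member"] == member
    )
    return {
        "n_links": n,
        "frac_satisfiable": float(v.satisfiable.mean()),
        "frac_attributed": n_correct / n if n else 0.0,
    }


def lattice_reinterpretation(seed: int, cutoff: float = 30.0) -> dict:
    """Planted head-to-tail lattice links vs shuffled negatives."""
    tc = make_oligomer_testcase(seed=seed)
    planted = reinterpret_intralinks(tc.planted_links, tc.lattice,
                                     tc.chain_map, cutoff)
    negative = reinterpret_intralinks(tc.negative_links, tc.lattice,
                                      tc.chain_map, cutoff)
    return {
        "n_planted": len(planted),
        "frac_planted_satisfied": float(planted.satisfied.mean()),
        "max_planted_distance": float(planted.distance.max()),
        "frac_negative_satisfied": float(negative.satisfied.mean()),
    }


def planted_fit(seed: int, length: int = 60, window: int = 20,
                offset: int = 7, noise_rmsd: float = 1.0) -> dict:
    """Sliding-window fit of a planted excerpt, clean and noisy.

    ``noise_rmsd`` is the target displacement scale in Angstrom; isotropic
    per-axis noise of sigma = noise_rmsd/sqrt(3) produces it.
    """
    rng = task_rng(seed, "planted-fit")
    st, _ = make_structure(length, "random-walk-3.8", rng,
                           structure_id="fit_target")
    chain = st.chains[0]
    excerpt = chain.ca_array()[offset:offset + window]
    clean, clean_offset, _ = fit_model_to_chain(excerpt, chain)
    noisy_model = excerpt + rng.normal(scale=noise_rmsd / np.sqrt(3),
                                       size=excerpt.shape)
    noisy, noisy_offset, _ = fit_model_to_chain(noisy_model, chain)
    return {
        "planted_offset": offset,
        "clean_offset": clean_offset,
        "clean_rmsd": clean.rmsd,
        "noisy_offset": noisy_offset,
        "noisy_rmsd": noisy.rmsd,
    }
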