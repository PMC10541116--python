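"""Small constructors shared across test modules."""

import numpy as np

from axoxl.io_formats import Chain, CrossLinkRecord, ResidueRecord, Structure


def make_chain(coords, chain_id="A", start=1, seq=None):
    """Chain from an (n, 3) coordinate list; None entries become
    missing-CA residues."""
    residues = []
    for i, c in enumerate(coords):
        residues.append(ResidueRecord(
            author_number=start + i,
            one_letter=(seq[i] if seq else "A"),
            ca=None if c is None else np.asarray(c, float),
        ))
    return Chain(chain_id=chain_id, residues=residues)


def rec(pa, ra, pb, rb, score=50.0, fdr=0.005, **kw):
    return CrossLinkRecord(protein_a=pa, residue_a=ra, protein_b=pb,
                           residue_b=rb, score=score, fdr=fdr, **kw)


def structure_from_chains(*chains, sid="synth"):
    return Structure(id=sid, chains=list(chains))
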