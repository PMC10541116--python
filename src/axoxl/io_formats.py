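"""Readers and writers for every external format the pipeline touches.

Cross-link identification tables (CSV/TSV with a configurable column
dialect), atomic structures (PDB / mmCIF via gemmi), FASTA sequence files,
orthogroup membership tables, and network exports (xiView CSV, GraphML,
round-trippable TSV).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import networkx as nx
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}
AA1 = {v: k for k, v in AA3.items()}


# ---------------------------------------------------------------------------
# Cross-link records


@dataclass
class CrossLinkRecord:
    """One identified residue-residue cross-link (one spectral match).

    Residue positions are 1-based in the full protein sequence.  ``score``
    follows "Max XlinkX score" semantics (dimensionless, larger is better);
    ``fdr`` is a fraction in [0, 1].  ``provenance`` optionally retains the
    original accessions after orthogroup collapsing.
    """

    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    score: float
    fdr: float
    dataset_id: str = ""
    spectral_count: int = 1
    provenance: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.residue_a < 1 or self.residue_b < 1:
            raise ValueError("residue positions must be >= 1")
        if not math.isfinite(self.score):
            raise ValueError("score must be finite")
        if self.spectral_count < 1:
            raise ValueError("spectral_count must be positive")
        same_site = (
            self.protein_a == self.protein_b and self.residue_a == self.residue_b
        )
        # Self-links are rejected at parse time (provenance unset).  After
        # orthogroup collapsing two paralogous sites may legitimately
        # coincide; provenance marks such post-parse records.
        if same_site and self.provenance is None:
            raise ValueError(
                f"self-link rejected: {self.protein_a}:{self.residue_a}"
            )


@dataclass
class XlDialect:
    """Names of the columns holding the mandatory cross-link fields.

    ``fdr`` may be None when the exported table was pre-filtered and carries
    no FDR column; such records then pass the FDR filter by default.
    """

    protein_a: str = "ProteinA"
    residue_a: str = "PosA"
    protein_b: str = "ProteinB"
    residue_b: str = "PosB"
    score: str = "Score"
    fdr: str | None = "FDR"
    dataset_id: str | None = None
    delimiter: str | None = None  # None: sniff from extension/content


def _sniff_delimiter(path: Path, header: str) -> str:
    if path.suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_xl_table(
    path: str | Path,
    dialect: XlDialect | None = None,
    dataset_id: str = "",
) -> list[CrossLinkRecord]:
    """Parse a cross-link identification table.

    Every row yields exactly one record or one warning-logged skip; row
    order is preserved.  A missing mandatory column is a hard error naming
    the column; a non-numeric position skips the row with a warning.
    """
    path = Path(path)
    dialect = dialect or XlDialect()
    with open(path, newline="") as fh:
        first = fh.readline()
        delim = dialect.delimiter or _sniff_delimiter(path, first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        cols = reader.fieldnames or []
        mandatory = [
            dialect.protein_a, dialect.residue_a,
            dialect.protein_b, dialect.residue_b, dialect.score,
        ]
        for col in mandatory:
            if col not in cols:
                raise ValueError(f"missing mandatory column: {col!r}")
        has_fdr = dialect.fdr is not None and dialect.fdr in cols
        if dialect.fdr is not None and not has_fdr:
            warnings.warn(
                f"FDR column {dialect.fdr!r} absent; records will pass the "
                "FDR filter by default (table assumed pre-filtered)"
            )
        records: list[CrossLinkRecord] = []
        for i, row in enumerate(reader, start=2):
            try:
                rec = CrossLinkRecord(
                    protein_a=row[dialect.protein_a].strip(),
                    residue_a=int(row[dialect.residue_a]),
                    protein_b=row[dialect.protein_b].strip(),
                    residue_b=int(row[dialect.residue_b]),
                    score=float(row[dialect.score]),
                    fdr=float(row[dialect.fdr]) if has_fdr else 0.0,
                    dataset_id=(
                        row[dialect.dataset_id]
                        if dialect.dataset_id and dialect.dataset_id in cols
                        else dataset_id
                    ),
                )
            except (ValueError, TypeError) as exc:
                warnings.warn(f"{path.name}:{i}: row skipped ({exc})")
                continue
            records.append(rec)
    return records


def write_xl_table(records: Iterable[CrossLinkRecord], path: str | Path) -> None:
    """Write records in the default TSV dialect (read -> write round-trips)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["ProteinA", "PosA", "ProteinB", "PosB", "Score", "FDR",
                    "Dataset"])
        for r in records:
            w.writerow([r.protein_a, r.residue_a, r.protein_b, r.residue_b,
                        repr(r.score), repr(r.fdr), r.dataset_id])


# ---------------------------------------------------------------------------
# Structures


@dataclass
class ResidueRecord:
    """A residue with author numbering and an optional C-alpha coordinate.

    ``ca`` is None when the residue has no C-alpha record (never a sentinel
    coordinate).
    """

    author_number: int
    icode: str = ""
    one_letter: str = "X"
    ca: np.ndarray | None = None

    @property
    def key(self) -> tuple[int, str]:
        return (self.author_number, self.icode)


@dataclass
class Chain:
    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError(
                f"chain {self.chain_id}: author numbering not strictly "
                "increasing"
            )

    def get(self, author_number: int, icode: str = "") -> ResidueRecord | None:
        for r in self.residues:
            if r.key == (author_number, icode):
                return r
        return None

    def resolved(self) -> list[ResidueRecord]:
        """Residues that carry a C-alpha coordinate, in chain order."""
        return [r for r in self.residues if r.ca is not None]

    def ca_array(self) -> np.ndarray:
        return np.array([r.ca for r in self.resolved()], dtype=float)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]


def read_structure(path: str | Path) -> Structure:
    """Read a PDB or mmCIF file into a C-alpha level :class:`Structure`.

    Format is auto-detected.  Only the first model is used.  For alternate
    locations the C-alpha with highest occupancy wins, ties broken
    alphabetically by altloc id.  Residues lacking a C-alpha are kept and
    flagged missing; a chain with zero C-alpha atoms triggers a warning but
    is retained.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unreadable structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    if len(model) == 0:
        raise ValueError(f"no chains parsed from {path}")
    chains: list[Chain] = []
    for ch in model:
        residues: list[ResidueRecord] = []
        for res in ch:
            cas = [a for a in res if a.name == "CA"]
            ca = None
            if cas:
                best = min(cas, key=lambda a: (-a.occ, a.altloc))
                ca = np.array([best.pos.x, best.pos.y, best.pos.z])
            info = gemmi.find_tabulated_residue(res.name)
            one = info.one_letter_code.upper() if info else "X"
            residues.append(ResidueRecord(
                author_number=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                one_letter=one if one.isalpha() else "X",
                ca=ca,
            ))
        residues.sort(key=lambda r: r.key)
        deduped: list[ResidueRecord] = []
        for r in residues:
            if deduped and deduped[-1].key == r.key:
                warnings.warn(
                    f"{path.name}: duplicate residue {r.key} in chain "
                    f"{ch.name}; keeping first"
                )
                continue
            deduped.append(r)
        if not any(r.ca is not None for r in deduped):
            warnings.warn(f"{path.name}: chain {ch.name} has no C-alpha atoms")
        chains.append(Chain(chain_id=ch.name, residues=deduped))
    return Structure(id=path.stem, chains=chains)


def write_structure_pdb(structure: Structure, path: str | Path) -> None:
    """Write a C-alpha-only PDB file (resolved residues only)."""
    lines = []
    serial = 0
    for ch in structure.chains:
        if len(ch.chain_id) != 1:
            raise ValueError(
                f"PDB chain ids are one character; got {ch.chain_id!r}"
            )
        for r in ch.resolved():
            serial += 1
            resname = AA3.get(r.one_letter, "UNK")
            x, y, z = r.ca
            lines.append(
                f"ATOM  {serial:5d}  CA  {resname:>3s} {ch.chain_id}"
                f"{r.author_number:4d}{r.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {'C':>2s}"
            )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA and orthogroup tables


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA; accession is the header token before the first whitespace.

    Duplicate accessions are a hard error.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate accession in FASTA: {rec.id}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=acc, description="") for acc, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class OrthoMap:
    """Protein accession -> orthogroup id, plus human-readable group labels."""

    entries: dict[str, str] = field(default_factory=dict)
    group_names: dict[str, str] = field(default_factory=dict)

    def group_for(self, accession: str) -> str | None:
        return self.entries.get(accession)

    def label(self, group: str) -> str:
        return self.group_names.get(group, group)


def read_orthomap(path: str | Path) -> OrthoMap:
    """Read a TSV of ``accession <TAB> group [<TAB> human_label]``.

    An accession mapped to two different groups is a hard error.
    """
    entries: dict[str, str] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            acc, group = parts[0].strip(), parts[1].strip()
            if acc in entries and entries[acc] != group:
                raise ValueError(
                    f"accession {acc!r} mapped to both {entries[acc]!r} "
                    f"and {group!r}"
                )
            entries[acc] = group
            if len(parts) >= 3 and parts[2].strip():
                names[group] = parts[2].strip()
    return OrthoMap(entries=entries, group_names=names)


def write_orthomap(om: OrthoMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, group in om.entries.items():
            fh.write(f"{acc}\t{group}\t{om.group_names.get(group, '')}\n")


# ---------------------------------------------------------------------------
# Network export


def write_network(links, path: str | Path, format: str = "tsv") -> None:
    """Export unique links.

    ``xiview-csv`` writes the residue-level columns
    Protein1,PepPos1,Protein2,PepPos2,Score; ``tsv`` is the lossless dialect
    re-read by :func:`read_network_tsv`; ``graphml`` writes a multigraph via
    networkx.  An empty link list yields a valid header-only file.
    """
    links = list(links)
    path = Path(path)
    if not links:
        warnings.warn(f"writing empty network to {path.name}")
    if format == "xiview-csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["Protein1", "PepPos1", "Protein2", "PepPos2", "Score"])
            for lk in links:
                (ga, ra), (gb, rb) = lk.end_a, lk.end_b
                w.writerow([ga, ra, gb, rb, repr(lk.best_score)])
    elif format == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["group_a", "residue_a", "group_b", "residue_b",
                        "kind", "support", "best_score"])
            for lk in links:
                (ga, ra), (gb, rb) = lk.end_a, lk.end_b
                w.writerow([ga, ra, gb, rb, lk.kind, lk.support,
                            repr(lk.best_score)])
    elif format == "graphml":
        g = nx.MultiGraph()
        for lk in links:
            (ga, ra), (gb, rb) = lk.end_a, lk.end_b
            g.add_edge(ga, gb, residue_a=ra, residue_b=rb, kind=lk.kind,
                       support=lk.support, best_score=lk.best_score)
        nx.write_graphml(g, str(path))
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network_tsv(path: str | Path):
    """Re-read the lossless ``tsv`` dialect written by :func:`write_network`."""
    from .network import UniqueLink  # local import to avoid a cycle

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(UniqueLink(
                end_a=(row["group_a"], int(row["residue_a"])),
                end_b=(row["group_b"], int(row["residue_b"])),
                kind=row["kind"],
                support=int(row["support"]),
                best_score=float(row["best_score"]),
            ))
    return out
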