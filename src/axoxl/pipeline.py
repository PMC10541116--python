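"""End-to-end orchestration: import -> filter -> collapse -> network ->
structure mapping -> ensemble/lattice disambiguation -> report.

A run is fully described by a :class:`PipelineConfig` (loadable from YAML)
and is deterministic given the config: all orderings are canonical, and the
output bundle carries a provenance block with the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ensembles import (Ensemble, OligomerLattice, distance_heatmap,
                        reinterpret_intralinks, satisfiable_by_any)
from .io_formats import (OrthoMap, XlDialect, read_orthomap, read_structure,
                         read_xl_table, write_network)
from .network import deduplicate, filter_records, summarize
from .orthomap import collapse_to_orthogroups
from .structmap import (Thresholds, map_links, mapped_links_table,
                        satisfaction_summary)

logger = logging.getLogger(__name__)


@dataclass
class StructureTask:
    path: str
    chain_map: dict[str, list[str]]  # orthogroup -> chain ids


@dataclass
class PipelineConfig:
    xl_tables: list[str]
    out_dir: str
    orthomap_path: str | None = None
    dialect: XlDialect = field(default_factory=XlDialect)
    fdr_max: float = 0.01
    score_min: float = 40.0
    thresholds: Thresholds = field(default_factory=Thresholds)
    structures: list[StructureTask] = field(default_factory=list)
    ensemble_paths: list[str] = field(default_factory=list)
    ensemble_chain_map: dict[str, list[str]] = field(default_factory=dict)
    lattice_transform: list[float] | None = None  # 9 rotation + 3 translation
    lattice_copies: int = 3
    seed: int = 0

    def validate(self) -> None:
        for p in list(self.xl_tables) + [
            t.path for t in self.structures
        ] + list(self.ensemble_paths):
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input missing: {p}")
        if self.orthomap_path and not Path(self.orthomap_path).exists():
            raise FileNotFoundError(
                f"configured input missing: {self.orthomap_path}")
        # Thresholds.__post_init__ enforces the ordering invariant
        Thresholds(self.thresholds.satisfied, self.thresholds.moderate,
                   self.thresholds.extreme)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        dialect = XlDialect(**raw.pop("dialect", {}))
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        structures = [StructureTask(**s) for s in raw.pop("structures", [])]
        return cls(dialect=dialect, thresholds=thresholds,
                   structures=structures, **raw)

    def digest(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)
        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(config: PipelineConfig) -> dict:
    """Execute the configured pipeline; returns the report bundle and
    writes machine-readable outputs under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"provenance": {
        "config_hash": config.digest(),
        "tool_version": __version__,
        "seed": config.seed,
    }}

    records = []
    for path in config.xl_tables:
        records.extend(read_xl_table(path, config.dialect,
                                     dataset_id=Path(path).stem))
    logger.info("stage import: %d records", len(records))

    records, filter_report = filter_records(records, config.fdr_max,
                                            config.score_min)

    if config.orthomap_path:
        om = read_orthomap(config.orthomap_path)
    else:
        om = OrthoMap()
    records, collapse_report = collapse_to_orthogroups(records, om)

    links = deduplicate(records)
    summary = summarize(links, records)
    bundle["network_summary"] = summary.as_dict()
    bundle["filter"] = filter_report.__dict__
    bundle["n_unmapped_accessions"] = len(collapse_report.unmapped_accessions)
    (out / "network_summary.json").write_text(
        json.dumps(bundle["network_summary"], indent=2))
    write_network(links, out / "network.tsv", "tsv")
    write_network(links, out / "network_xiview.csv", "xiview-csv")
    write_network(links, out / "network.graphml", "graphml")

    bundle["satisfaction"] = {}
    for task in config.structures:
        st = read_structure(task.path)
        mapped = map_links(links, st, task.chain_map)
        sat, hist = satisfaction_summary(mapped, config.thresholds)
        bundle["satisfaction"][st.id] = sat.as_dict()
        mapped_links_table(mapped).to_csv(
            out / f"mapped_{st.id}.tsv", sep="\t", index=False)
        hist.to_csv(out / f"hist_{st.id}.tsv", sep="\t", index=False)
        (out / f"satisfaction_{st.id}.json").write_text(
            json.dumps(sat.as_dict(), indent=2))
        logger.info("stage map[%s]: %d mapped, %.1f%% within %.0f A",
                    st.id, sat.n_mapped, 100 * sat.frac_within_satisfied,
                    config.thresholds.satisfied)

    if config.ensemble_paths:
        members = [read_structure(p) for p in config.ensemble_paths]
        ens = Ensemble(label="ensemble", members=members)
        hm = distance_heatmap(links, ens, config.ensemble_chain_map)
        verdicts = satisfiable_by_any(hm, config.thresholds.satisfied)
        hm.matrix.to_csv(out / "ensemble_heatmap.tsv", sep="\t")
        verdicts.to_csv(out / "ensemble_verdicts.tsv", sep="\t")
        bundle["ensemble"] = {
            "n_links": int(len(hm.matrix)),
            "n_satisfiable": int(verdicts["satisfiable"].sum()),
        }

    if config.lattice_transform is not None and config.structures:
        nums = config.lattice_transform
        if len(nums) != 12:
            raise ValueError("lattice_transform needs 12 numbers "
                             "(row-major 3x3 rotation then translation)")
        base = read_structure(config.structures[0].path)
        lattice = OligomerLattice(
            base=base,
            rotation=np.array(nums[:9]).reshape(3, 3),
            translation=np.array(nums[9:]),
            n_copies=config.lattice_copies,
        )
        chain_map = config.structures[0].chain_map
        intra_viol = [
            lk for lk in links if lk.kind == "intramolecular"
        ]
        verdicts = reinterpret_intralinks(intra_viol, lattice, chain_map,
                                          config.thresholds.satisfied)
        verdicts.to_csv(out / "lattice_verdicts.tsv", sep="\t", index=False)
        bundle["lattice"] = {
            "n_links": int(len(verdicts)),
            "n_satisfied": int(verdicts["satisfied"].sum()),
        }

    (out / "bundle.json").write_text(json.dumps(bundle, indent=2))
    return bundle


def _pct(x: float) -> str:
    """Percentage rounded half-up to an integer, e.g. 0.835 -> '84%'."""
    return f"{int(Decimal(x * 100).quantize(0, rounding=ROUND_HALF_UP))}%"


def report(bundle: dict) -> str:
    """Human-readable summary of a run bundle."""
    ns = bundle.get("network_summary", {})
    lines = [
        f"axoxl report (config {bundle['provenance']['config_hash']}, "
        f"version {bundle['provenance']['tool_version']})",
        "",
    ]
    if not ns or ns.get("n_unique_links", 0) == 0:
        lines.append("no links passed import and filtering")
        return "\n".join(lines)
    lines += [
        f"cross-link records (after filters): {ns['n_records']}",
        f"unique residue-pair links:          {ns['n_unique_links']}",
        f"proteins (orthogroups) involved:    {ns['n_proteins']}",
        f"intermolecular links:               {ns['n_intermolecular']}",
        f"intramolecular links:               {ns['n_intramolecular']}",
        f"unique protein-pair interactions:   {ns['n_group_pairs']}",
    ]
    for sid, sat in bundle.get("satisfaction", {}).items():
        lines += [
            "",
            f"structure {sid}: {sat['n_mapped']} links mapped "
            f"({sat['n_unmappable']} unmappable)",
            f"  within satisfied cutoff: {sat['n_within_satisfied']} "
            f"({_pct(sat['frac_within_satisfied'])})",
            f"  within moderate cutoff:  {sat['n_within_moderate']} "
            f"({_pct(sat['frac_within_moderate'])})",
            f"  extreme violations:      {sat['n_extreme']}",
        ]
    if "ensemble" in bundle:
        e = bundle["ensemble"]
        lines.append(
            f"\nensemble: {e['n_satisfiable']}/{e['n_links']} links "
            "satisfied by at least one conformation")
    if "lattice" in bundle:
        lt = bundle["lattice"]
        lines.append(
            f"lattice: {lt['n_satisfied']}/{lt['n_links']} intramolecular "
            "links satisfied as inter-copy links")
    return "\n".join(lines)
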