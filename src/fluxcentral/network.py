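"""Metabolic factor-graph data model and I/O.

A factor graph couples metabolites (variables) with reaction modules
(factors).  A reaction module is a lumped set of consecutive reactions
carrying one flux, annotated with the genes encoding its enzymes and
transporters.  All stoichiometric coefficients are +/-1: modules are
curated at the "one unit in, one unit out" level of granularity, and
reversible reactions appear once in their canonical direction.

Intermediate metabolites participate in the flux-balance constraint
(total influx ~ total outflux); end metabolites (sources and sinks such
as extracellular glucose or secreted lactate) do not.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NetworkFormatError, NetworkValidationError

logger = logging.getLogger(__name__)

COMPARTMENTS = ("cytosol", "mitochondria", "extracellular")
MET_ROLES = ("intermediate", "end")


@dataclass(frozen=True)
class Metabolite:
    """A metabolite node.

    ``role='intermediate'`` means the metabolite enters the balance loss;
    ``role='end'`` marks boundary sources/sinks excluded from it.
    """

    id: str
    name: str
    compartment: str
    role: str

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise NetworkValidationError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if self.role not in MET_ROLES:
            raise NetworkValidationError(f"metabolite {self.id!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class ReactionModule:
    """A lumped reaction module with its consumed/produced metabolites and gene set."""

    id: str
    name: str
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise NetworkValidationError(f"module {self.id!r} has an empty gene list")
        if not (self.inputs or self.outputs):
            raise NetworkValidationError(f"module {self.id!r} has no edges")
        overlap = set(self.inputs) & set(self.outputs)
        if overlap:
            raise NetworkValidationError(
                f"module {self.id!r} lists {sorted(overlap)} as both input and output"
            )


@dataclass
class FactorGraph:
    """Bipartite metabolite/reaction-module graph with derived Fin/Fout maps."""

    metabolites: dict[str, Metabolite]
    modules: dict[str, ReactionModule]
    fin: dict[str, list[str]] = field(init=False)   # metabolite -> producing modules
    fout: dict[str, list[str]] = field(init=False)  # metabolite -> consuming modules

    def __post_init__(self):
        self._rebuild_edges()

    def _rebuild_edges(self):
        self.fin = {k: [] for k in self.metabolites}
        self.fout = {k: [] for k in self.metabolites}
        for mod in self.modules.values():
            for met in mod.outputs:
                if met not in self.metabolites:
                    raise NetworkFormatError(
                        f"module {mod.id!r} outputs undeclared metabolite {met!r}"
                    )
                self.fin[met].append(mod.id)
            for met in mod.inputs:
                if met not in self.metabolites:
                    raise NetworkFormatError(
                        f"module {mod.id!r} consumes undeclared metabolite {met!r}"
                    )
                self.fout[met].append(mod.id)

    # -- counts ---------------------------------------------------------
    @property
    def M(self) -> int:
        return len(self.modules)

    @property
    def K(self) -> int:
        return len(self.metabolites)

    @property
    def K_int(self) -> int:
        return len(self.intermediates)

    @property
    def intermediates(self) -> list[str]:
        return [k for k, m in self.metabolites.items() if m.role == "intermediate"]

    @property
    def end_metabolites(self) -> list[str]:
        return [k for k, m in self.metabolites.items() if m.role == "end"]

    @property
    def module_ids(self) -> list[str]:
        return list(self.modules)

    def genes(self) -> list[str]:
        """Union of gene symbols over all modules, in first-seen order."""
        seen: dict[str, None] = {}
        for mod in self.modules.values():
            for g in mod.genes:
                seen.setdefault(g)
        return list(seen)

    # -- serialization --------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "metabolites": [vars(m) for m in self.metabolites.values()],
            "modules": [
                {
                    "id": m.id,
                    "name": m.name,
                    "inputs": list(m.inputs),
                    "outputs": list(m.outputs),
                    "genes": list(m.genes),
                }
                for m in self.modules.values()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FactorGraph":
        payload = json.loads(Path(path).read_text())
        mets = {d["id"]: Metabolite(**d) for d in payload["metabolites"]}
        mods = {
            d["id"]: ReactionModule(
                id=d["id"],
                name=d["name"],
                inputs=tuple(d["inputs"]),
                outputs=tuple(d["outputs"]),
                genes=tuple(d["genes"]),
            )
            for d in payload["modules"]
        }
        return cls(mets, mods)


def validate(graph: FactorGraph) -> list[str]:
    """Report structural problems; an empty list means the graph is usable.

    Checks: every intermediate has at least one producer and one consumer,
    no module has an empty gene list, and all edge endpoints resolve.
    Report-only: never raises.
    """
    report: list[str] = []
    for met_id, met in graph.metabolites.items():
        if met.role != "intermediate":
            continue
        if not graph.fin.get(met_id):
            report.append(f"intermediate {met_id!r} has no producing module (|Fin|=0)")
        if not graph.fout.get(met_id):
            report.append(f"intermediate {met_id!r} has no consuming module (|Fout|=0)")
    for mod in graph.modules.values():
        if not mod.genes:
            report.append(f"module {mod.id!r} has an empty gene list")
    return report


def incidence_matrix(graph: FactorGraph) -> pd.DataFrame:
    """Signed intermediate x module incidence matrix.

    Entry (k, m) is +1 if module m produces intermediate k, -1 if it
    consumes it, 0 otherwise.  Row order follows the declared intermediate
    order, column order the declared module order.
    """
    inter = graph.intermediates
    mods = graph.module_ids
    S = np.zeros((len(inter), len(mods)))
    mod_pos = {m: i for i, m in enumerate(mods)}
    for k, met in enumerate(inter):
        for m in graph.fin[met]:
            S[k, mod_pos[m]] = 1.0
        for m in graph.fout[met]:
            S[k, mod_pos[m]] = -1.0
    return pd.DataFrame(S, index=inter, columns=mods)


def parse_gene_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a module -> genes map from GMT or a two-column TSV.

    GMT lines are ``set_id<TAB>description<TAB>gene...``; the two-column
    dialect is ``module_id<TAB>gene`` with one gene per row.
    """
    path = Path(path)
    gene_map: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise NetworkFormatError(f"gene map {path} is empty")
    is_gmt = path.suffix.lower() == ".gmt" or len(lines[0].split("\t")) > 2
    for i, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if is_gmt:
            if len(fields) < 3:
                raise NetworkFormatError(f"{path}:{i}: GMT line needs >=3 tab-separated fields")
            set_id, desc, genes = fields[0], fields[1], fields[2:]
            names[set_id] = desc
            gene_map.setdefault(set_id, []).extend(g for g in genes if g)
        else:
            if len(fields) != 2:
                raise NetworkFormatError(f"{path}:{i}: expected two tab-separated columns")
            gene_map.setdefault(fields[0], []).append(fields[1])
    out = {}
    for k, genes in gene_map.items():
        dedup = list(dict.fromkeys(genes))
        out[k] = tuple(dedup)
    out_names = {k: names.get(k, k) for k in out}
    parse_gene_map.last_names = out_names  # side-channel for display names
    return out


def load_network(module_table: str | Path, gene_map: str | Path) -> FactorGraph:
    """Build a validated :class:`FactorGraph` from a module table and a gene map.

    The module table is a TSV with columns
    ``module_id, role(input|output), metabolite_id, compartment, met_role``,
    one row per module<->metabolite edge.  Duplicate edges are collapsed
    with a warning.  Every module must have at least one gene in the map.
    """
    module_table = Path(module_table)
    try:
        table = pd.read_csv(module_table, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise NetworkFormatError(f"cannot read module table {module_table}: {exc}") from exc
    required = ["module_id", "role", "metabolite_id", "compartment", "met_role"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise NetworkFormatError(f"{module_table}: missing columns {missing}")

    genes = parse_gene_map(gene_map)
    names = getattr(parse_gene_map, "last_names", {})

    metabolites: dict[str, Metabolite] = {}
    inputs: dict[str, list[str]] = {}
    outputs: dict[str, list[str]] = {}
    for row_num, row in enumerate(table.itertuples(index=False), start=2):
        if row.role not in ("input", "output"):
            raise NetworkFormatError(
                f"{module_table} row {row_num}: role must be input/output, got {row.role!r}"
            )
        met = metabolites.get(row.metabolite_id)
        if met is None:
            try:
                metabolites[row.metabolite_id] = Metabolite(
                    id=row.metabolite_id,
                    name=row.metabolite_id,
                    compartment=row.compartment,
                    role=row.met_role,
                )
            except NetworkValidationError as exc:
                raise NetworkFormatError(f"{module_table} row {row_num}: {exc}") from exc
        elif (met.compartment, met.role) != (row.compartment, row.met_role):
            raise NetworkFormatError(
                f"{module_table} row {row_num}: metabolite {row.metabolite_id!r} re-declared "
                f"with conflicting compartment/role"
            )
        bucket = inputs if row.role == "input" else outputs
        edges = bucket.setdefault(row.module_id, [])
        if row.metabolite_id in edges:
            logger.warning(
                "duplicate %s edge %s -> %s collapsed", row.role, row.module_id, row.metabolite_id
            )
        else:
            edges.append(row.metabolite_id)

    module_ids = list(dict.fromkeys(table["module_id"]))
    missing_genes = [m for m in module_ids if not genes.get(m)]
    if missing_genes:
        raise NetworkValidationError(
            f"modules with no genes in the gene map: {missing_genes}"
        )

    modules = {
        m: ReactionModule(
            id=m,
            name=names.get(m, m),
            inputs=tuple(inputs.get(m, ())),
            outputs=tuple(outputs.get(m, ())),
            genes=genes[m],
        )
        for m in module_ids
    }
    graph = FactorGraph(metabolites, modules)
    report = validate(graph)
    if report:
        raise NetworkValidationError("invalid factor graph:\n" + "\n".join(report))
    return graph


def save_network(graph: FactorGraph, module_table: str | Path, gene_map: str | Path) -> None:
    """Write a graph back to the module-table TSV + GMT pair read by :func:`load_network`."""
    rows = []
    for mod in graph.modules.values():
        for role, mets in (("input", mod.inputs), ("output", mod.outputs)):
            for met_id in mets:
                met = graph.metabolites[met_id]
                rows.append((mod.id, role, met_id, met.compartment, met.role))
    pd.DataFrame(
        rows, columns=["module_id", "role", "metabolite_id", "compartment", "met_role"]
    ).to_csv(module_table, sep="\t", index=False)
    with open(gene_map, "w") as fh:
        for mod in graph.modules.values():
            fh.write("\t".join([mod.id, mod.name, *mod.genes]) + "\n")


def central_metabolism_fixture() -> FactorGraph:
    """The packaged central-metabolism network.

    Covers glycolysis, the upper and lower TCA cycle, glutaminolysis,
    glutamine/glutamate metabolism and glutathione metabolism, plus six
    minor branches (nucleotide synthesis from G3P, serine from 3PG, the
    aspartate-malate shuttle, citrate export to fatty-acid synthesis,
    mitochondria-to-cytosol 2OG transport, and 2OG to 2HG), at subcellular
    (cytosol/mitochondria/extracellular) resolution: 42 reaction modules,
    27 intermediate and 15 end metabolites.  Gene rosters are a curated
    best-effort transcription.
    """
    data = resources.files("fluxcentral") / "data"
    with resources.as_file(data / "central_metabolism_modules.tsv") as mod_path, \
            resources.as_file(data / "central_metabolism_genes.gmt") as gmt_path:
        return load_network(mod_path, gmt_path)
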