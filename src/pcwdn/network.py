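"""Data model, I/O, validation and summarization for the degradation network.

The network is a curation scaffold, not a flux model: reactions carry a
compartment class (extracellular, transport, intracellular), substrate and
product compound sets, pathway tags for the seven polysaccharide pathways,
and an OR-semantics gene set (any listed gene product catalyzes or
transports).  Gene roles and pathway memberships are derived from the
reactions a gene participates in, except where the source table states a
primary role explicitly, in which case the source is trusted.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "COMPARTMENT_CLASSES",
    "PATHWAY_TAGS",
    "Compound",
    "Reaction",
    "Gene",
    "Network",
    "NetworkSummary",
    "ValidationReport",
    "normalize_gene_id",
    "load_network",
    "network_from_json",
    "network_to_json",
    "validate_network",
    "summarize",
    "pathway_genes",
    "mannan_fixture_tables",
]

COMPARTMENT_CLASSES = ("extracellular", "transport", "intracellular")
PATHWAY_TAGS = (
    "cellulose",
    "xylan",
    "xyloglucan",
    "mannan",
    "mixed-linkage glucan",
    "pectin",
    "starch",
)

_GENE_ID_RE = re.compile(r"^NCU\d{5}$")


def normalize_gene_id(raw: str) -> str:
    """Normalize a gene id to upper-case ``NCU`` + zero-padded 5 digits.

    Accepts mixed-case ids and unpadded digit runs (``ncu890`` -> ``NCU00890``).
    Raises ``ValueError`` for anything that is not an NCU-number form.
    """
    s = str(raw).strip().upper()
    m = re.fullmatch(r"NCU0*(\d{1,5})", s)
    if not m:
        raise ValueError(f"gene id {raw!r} does not match the NCU##### pattern")
    return f"NCU{int(m.group(1)):05d}"


@dataclass(frozen=True)
class Compound:
    id: str
    name: str = ""
    is_polymer: bool = False


@dataclass(frozen=True)
class Reaction:
    id: str
    name: str
    compartment: str
    substrates: frozenset[str]
    products: frozenset[str]
    pathways: frozenset[str]
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENT_CLASSES:
            raise ValueError(
                f"reaction {self.id}: unknown compartment {self.compartment!r} "
                f"(expected one of {COMPARTMENT_CLASSES})"
            )
        bad = set(self.pathways) - set(PATHWAY_TAGS)
        if bad:
            raise ValueError(f"reaction {self.id}: unknown pathway tags {sorted(bad)}")
        if not self.pathways:
            raise ValueError(f"reaction {self.id}: at least one pathway tag required")
        if not self.substrates or not self.products:
            raise ValueError(f"reaction {self.id}: substrates and products must be non-empty")


@dataclass
class Gene:
    id: str
    symbol: str = ""
    #: compartment classes of the reactions this gene acts in (or the source's
    #: stated primary role)
    role: frozenset[str] = field(default_factory=frozenset)
    pathways: frozenset[str] = field(default_factory=frozenset)


@dataclass
class Network:
    genes: dict[str, Gene]
    reactions: dict[str, Reaction]
    compounds: dict[str, Compound]
    version: str = "1.0"


@dataclass
class ValidationReport:
    dangling_references: list[str] = field(default_factory=list)
    duplicate_ids: list[str] = field(default_factory=list)
    orphan_reactions: list[str] = field(default_factory=list)
    unused_genes: list[str] = field(default_factory=list)

    @property
    def errors(self) -> list[str]:
        return self.dangling_references + self.duplicate_ids

    @property
    def warnings(self) -> list[str]:
        return self.orphan_reactions + self.unused_genes

    @property
    def ok(self) -> bool:
        return not self.errors and not self.warnings


@dataclass
class NetworkSummary:
    n_reactions: int
    n_genes: int
    n_compounds: int
    reactions_per_compartment: dict[str, int]
    genes_per_role: dict[str, int]
    genes_per_pathway: dict[str, int]
    reactions_per_pathway: dict[str, int]


# --- TSV dialect helpers -------------------------------------------------
# tab-separated, header row, semicolon multi-value cells, "." for empty

def _split_multi(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    s = str(cell).strip()
    if s in {"", "."}:
        return frozenset()
    return frozenset(p.strip() for p in s.split(";") if p.strip())


def _read_table(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    return pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False, na_values=[])


def _check_unique(ids: pd.Series, what: str) -> None:
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate {what} id(s): {', '.join(map(str, dup))}")


def load_network(reaction_table, gene_table, compound_table, version: str = "1.0") -> Network:
    """Build a validated :class:`Network` from three tabular sources.

    Each source is a path to a TSV or an equivalently shaped DataFrame.
    Gene roles and pathways are derived from the reaction table; a ``role``
    column in the gene table, when present and non-empty, overrides the
    derived compartment classes (the curated source's primary-role call).
    """
    rtab, gtab, ctab = map(_read_table, (reaction_table, gene_table, compound_table))

    compounds: dict[str, Compound] = {}
    if len(ctab):
        _check_unique(ctab["compound_id"], "compound")
        for row in ctab.itertuples(index=False):
            cid = str(row.compound_id).strip()
            if not cid:
                raise ValueError("empty compound id")
            compounds[cid] = Compound(
                id=cid,
                name=str(getattr(row, "name", "") or ""),
                is_polymer=str(getattr(row, "is_polymer", "0")).strip() in {"1", "true", "True"},
            )

    genes: dict[str, Gene] = {}
    explicit_roles: dict[str, frozenset[str]] = {}
    if len(gtab):
        norm = gtab["gene_id"].map(normalize_gene_id)
        _check_unique(norm, "gene")
        for row, gid in zip(gtab.itertuples(index=False), norm):
            sym = str(getattr(row, "symbol", "") or "")
            genes[gid] = Gene(id=gid, symbol="" if sym == "." else sym)
            role_cell = getattr(row, "role", None)
            roles = _split_multi(role_cell)
            if roles:
                bad = roles - set(COMPARTMENT_CLASSES)
                if bad:
                    raise ValueError(f"gene {gid}: unknown role label(s) {sorted(bad)}")
                explicit_roles[gid] = roles

    reactions: dict[str, Reaction] = {}
    if len(rtab):
        _check_unique(rtab["reaction_id"], "reaction")
        for row in rtab.itertuples(index=False):
            rid = str(row.reaction_id).strip()
            if not rid:
                raise ValueError("empty reaction id")
            rgenes = frozenset(normalize_gene_id(g) for g in _split_multi(row.genes))
            reactions[rid] = Reaction(
                id=rid,
                name=str(getattr(row, "name", "") or ""),
                compartment=str(row.compartment).strip(),
                substrates=_split_multi(row.substrates),
                products=_split_multi(row.products),
                pathways=_split_multi(row.pathways),
                genes=rgenes,
            )

    net = Network(genes=genes, reactions=reactions, compounds=compounds, version=version)
    _derive_gene_annotations(net, explicit_roles)

    report = validate_network(net)
    if report.errors:
        raise ValueError("invalid network: " + "; ".join(report.errors))
    return net


def _derive_gene_annotations(net: Network, explicit_roles: dict[str, frozenset[str]]) -> None:
    derived_role: dict[str, set[str]] = {g: set() for g in net.genes}
    derived_pw: dict[str, set[str]] = {g: set() for g in net.genes}
    for rxn in net.reactions.values():
        for gid in rxn.genes:
            if gid in derived_role:
                derived_role[gid].add(rxn.compartment)
                derived_pw[gid].update(rxn.pathways)
    for gid, gene in net.genes.items():
        gene.role = explicit_roles.get(gid, frozenset(derived_role[gid]))
        gene.pathways = frozenset(derived_pw[gid])


def validate_network(net: Network) -> ValidationReport:
    """Referential-integrity and curation-hygiene report (never raises)."""
    rep = ValidationReport()
    for rxn in net.reactions.values():
        for cid in sorted(rxn.substrates | rxn.products):
            if cid not in net.compounds:
                rep.dangling_references.append(
                    f"reaction {rxn.id} references unknown compound {cid}"
                )
        for gid in sorted(rxn.genes):
            if gid not in net.genes:
                rep.dangling_references.append(f"reaction {rxn.id} references unknown gene {gid}")
        if not rxn.genes:
            rep.orphan_reactions.append(f"reaction {rxn.id} has no associated gene (orphan)")
    used = {g for rxn in net.reactions.values() for g in rxn.genes}
    for gid in sorted(set(net.genes) - used):
        rep.unused_genes.append(f"gene {gid} participates in no reaction")
    return rep


def summarize(net: Network) -> NetworkSummary:
    """Reaction/gene counts overall, per compartment class, and per pathway.

    A gene with reactions in several compartments is counted once under each
    role, so role counts can exceed the gene total for multi-role genes.
    """
    per_comp = {c: 0 for c in COMPARTMENT_CLASSES}
    rxn_per_pw = {p: 0 for p in PATHWAY_TAGS}
    for rxn in net.reactions.values():
        per_comp[rxn.compartment] += 1
        for p in rxn.pathways:
            rxn_per_pw[p] += 1
    per_role = {c: 0 for c in COMPARTMENT_CLASSES}
    gene_per_pw = {p: 0 for p in PATHWAY_TAGS}
    for gene in net.genes.values():
        for c in gene.role:
            per_role[c] += 1
        for p in gene.pathways:
            gene_per_pw[p] += 1
    return NetworkSummary(
        n_reactions=len(net.reactions),
        n_genes=len(net.genes),
        n_compounds=len(net.compounds),
        reactions_per_compartment=per_comp,
        genes_per_role=per_role,
        genes_per_pathway=gene_per_pw,
        reactions_per_pathway=rxn_per_pw,
    )


def pathway_genes(net: Network, pathway: str) -> set[str]:
    """Union of gene sets over reactions tagged with ``pathway``."""
    if pathway not in PATHWAY_TAGS:
        raise ValueError(f"unknown pathway tag {pathway!r} (expected one of {PATHWAY_TAGS})")
    out: set[str] = set()
    for rxn in net.reactions.values():
        if pathway in rxn.pathways:
            out |= rxn.genes
    return out


# --- JSON round trip -----------------------------------------------------

def network_to_json(net: Network, path: str | Path | None = None) -> str:
    doc = {
        "version": net.version,
        "genes": [
            {
                "id": g.id,
                "symbol": g.symbol,
                "role": sorted(g.role),
                "pathways": sorted(g.pathways),
            }
            for g in sorted(net.genes.values(), key=lambda g: g.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "compartment": r.compartment,
                "substrates": sorted(r.substrates),
                "products": sorted(r.products),
                "pathways": sorted(r.pathways),
                "genes": sorted(r.genes),
            }
            for r in sorted(net.reactions.values(), key=lambda r: r.id)
        ],
        "compounds": [
            {"id": c.id, "name": c.name, "is_polymer": c.is_polymer}
            for c in sorted(net.compounds.values(), key=lambda c: c.id)
        ],
    }
    text = json.dumps(doc, indent=1, sort_keys=False)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def network_from_json(source: str | Path) -> Network:
    doc = json.loads(Path(source).read_text()) if not str(source).lstrip().startswith("{") else json.loads(str(source))
    genes = {
        g["id"]: Gene(
            id=g["id"],
            symbol=g.get("symbol", ""),
            role=frozenset(g.get("role", [])),
            pathways=frozenset(g.get("pathways", [])),
        )
        for g in doc["genes"]
    }
    reactions = {
        r["id"]: Reaction(
            id=r["id"],
            name=r.get("name", ""),
            compartment=r["compartment"],
            substrates=frozenset(r["substrates"]),
            products=frozenset(r["products"]),
            pathways=frozenset(r["pathways"]),
            genes=frozenset(r["genes"]),
        )
        for r in doc["reactions"]
    }
    compounds = {
        c["id"]: Compound(id=c["id"], name=c.get("name", ""), is_polymer=c.get("is_polymer", False))
        for c in doc["compounds"]
    }
    return Network(genes=genes, reactions=reactions, compounds=compounds, version=doc.get("version", "1.0"))


def mannan_fixture_tables() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Small hand-transcribed mannan-pathway fixture.

    Three reactions: the single predicted extracellular endomannanase
    (gh5-7, NCU08412), a mannodextrin transport step with no identified
    transporter gene (orphan), and the intracellular beta-mannosidase
    (gh2-1, NCU00890).  Returns (reactions, genes, compounds) DataFrames in
    the loader's TSV dialect.
    """
    reactions = pd.DataFrame(
        [
            {
                "reaction_id": "R_MAN_ENDO",
                "name": "endo-beta-1,4-mannanase",
                "compartment": "extracellular",
                "substrates": "mannan",
                "products": "mannodextrin",
                "pathways": "mannan",
                "genes": "NCU08412",
            },
            {
                "reaction_id": "R_MAN_TRANS",
                "name": "mannodextrin transport",
                "compartment": "transport",
                "substrates": "mannodextrin",
                "products": "mannodextrin_in",
                "pathways": "mannan",
                "genes": ".",
            },
            {
                "reaction_id": "R_MAN_BMAN",
                "name": "beta-mannosidase",
                "compartment": "intracellular",
                "substrates": "mannodextrin_in",
                "products": "D-mannose",
                "pathways": "mannan",
                "genes": "NCU00890",
            },
        ]
    )
    genes = pd.DataFrame(
        [
            {"gene_id": "NCU08412", "symbol": "gh5-7", "role": "."},
            {"gene_id": "NCU00890", "symbol": "gh2-1", "role": "."},
        ]
    )
    compounds = pd.DataFrame(
        [
            {"compound_id": "mannan", "name": "1,4-beta-D-mannan", "is_polymer": "1"},
            {"compound_id": "mannodextrin", "name": "mannodextrin", "is_polymer": "0"},
            {"compound_id": "mannodextrin_in", "name": "mannodextrin (cytosol)", "is_polymer": "0"},
            {"compound_id": "D-mannose", "name": "D-mannose", "is_polymer": "0"},
        ]
    )
    return reactions, genes, compounds
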