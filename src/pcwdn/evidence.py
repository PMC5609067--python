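"""Five-evidence feature matrix and weighted annotation-confidence scoring.

Each network gene is scored against five heterogeneous evidence types —
functional genomics (f), transcriptomics (t), proteomics (p), genetics (g)
and biochemical characterization (b).  The default weights 1/2/4/8/16 form
a binary encoding: every weight strictly exceeds the sum of all smaller
ones, so biochemical support alone (16/31) outranks the combination of the
four weaker types (15/31), and the 32 flag patterns map to 32 distinct
numerators.  Scores are exact rationals (numerator over 31) internally.

Proteomics carries a re-annotation rule: a protein detected in the
secretome but not annotated as extracellular is re-assigned the
extracellular role, the proteomic observation being considered more
reliable than the in-silico localization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import pandas as pd

from .network import COMPARTMENT_CLASSES, Network, normalize_gene_id

__all__ = [
    "FunctionalGenomicsEvidence",
    "ProteomicsEvidence",
    "TranscriptomicsEvidence",
    "GeneticsEvidence",
    "BiochemEvidence",
    "GeneEvidence",
    "EvidenceFlags",
    "ScoringScheme",
    "DEFAULT_SCHEME",
    "PATHWAY_CONDITION_MAP",
    "derive_functional_genomics_flag",
    "derive_flags",
    "confidence_score",
    "apply_proteomics_priority",
    "score_matrix",
    "read_evidence_table",
]

LOCALIZATION_LABELS = ("extracellular", "intracellular", "membrane", "other")

#: which growth conditions count as "the relevant carbon source" for
#: transcriptomic support of a gene in each degradation pathway
PATHWAY_CONDITION_MAP: dict[str, frozenset[str]] = {
    "cellulose": frozenset({"Avicel", "cellobiose"}),
    "xylan": frozenset({"xylan"}),
    "mannan": frozenset({"mannan"}),
    "xyloglucan": frozenset({"xyloglucan"}),
    "mixed-linkage glucan": frozenset({"MLG"}),
    "pectin": frozenset({"pectin", "orange peel powder"}),
    "starch": frozenset({"starch"}),
}


@dataclass(frozen=True)
class FunctionalGenomicsEvidence:
    db_match: bool = False
    signalp: bool = False
    phobius: bool = False
    loc_wolfpsort: str | None = None
    loc_protcomp: str | None = None

    def __post_init__(self) -> None:
        for loc in (self.loc_wolfpsort, self.loc_protcomp):
            if loc is not None and loc not in LOCALIZATION_LABELS:
                raise ValueError(f"unknown localization label {loc!r}")


@dataclass(frozen=True)
class ProteomicsEvidence:
    detected_in_secretome: frozenset[str] = frozenset()
    increased_abundance_vs_noc: frozenset[str] = frozenset()


@dataclass(frozen=True)
class TranscriptomicsEvidence:
    upregulated_vs_noc: frozenset[str] = frozenset()


@dataclass(frozen=True)
class GeneticsEvidence:
    growth_deficient_on: frozenset[str] = frozenset()


@dataclass(frozen=True)
class BiochemEvidence:
    characterized_direct: bool = False
    characterized_ortholog: bool = False


@dataclass(frozen=True)
class GeneEvidence:
    """All sub-evidence for one gene, plus its assigned compartment role."""

    gene_id: str
    assigned_role: str
    functional: FunctionalGenomicsEvidence = field(default_factory=FunctionalGenomicsEvidence)
    proteomics: ProteomicsEvidence = field(default_factory=ProteomicsEvidence)
    transcriptomics: TranscriptomicsEvidence = field(default_factory=TranscriptomicsEvidence)
    genetics: GeneticsEvidence = field(default_factory=GeneticsEvidence)
    biochem: BiochemEvidence = field(default_factory=BiochemEvidence)


@dataclass(frozen=True)
class EvidenceFlags:
    f: bool = False
    t: bool = False
    p: bool = False
    g: bool = False
    b: bool = False


@dataclass(frozen=True)
class ScoringScheme:
    w_f: int = 1
    w_t: int = 2
    w_p: int = 4
    w_g: int = 8
    w_b: int = 16

    def __post_init__(self) -> None:
        ws = [self.w_f, self.w_t, self.w_p, self.w_g, self.w_b]
        if any(w <= 0 for w in ws):
            raise ValueError("weights must be positive integers")
        # each weight must dominate the sum of all strictly smaller ones so
        # flag patterns map to distinct, order-respecting numerators
        for w in ws:
            smaller = sum(v for v in ws if v < w)
            if w <= smaller:
                raise ValueError(
                    f"weight {w} does not exceed the sum of smaller weights ({smaller})"
                )

    @property
    def max_score(self) -> int:
        return self.w_f + self.w_t + self.w_p + self.w_g + self.w_b


DEFAULT_SCHEME = ScoringScheme()


def derive_functional_genomics_flag(ev: FunctionalGenomicsEvidence, assigned_role: str) -> bool:
    """Three-condition functional-genomics support rule.

    (i) the database annotation matches the assigned function, (ii) the
    signal-peptide predictions are consistent with the role — a peptide from
    at least one of the two predictors for extracellular proteins, from
    neither for transport or intracellular proteins — and (iii) at least one
    subcellular-localization predictor matches the role (transport proteins
    are matched by a membrane prediction).
    """
    if assigned_role not in COMPARTMENT_CLASSES:
        raise ValueError(f"unknown compartment role {assigned_role!r}")
    if not ev.db_match:
        return False
    has_sp = ev.signalp or ev.phobius
    if assigned_role == "extracellular":
        if not has_sp:
            return False
    elif has_sp:
        return False
    expected_loc = "membrane" if assigned_role == "transport" else assigned_role
    return expected_loc in (ev.loc_wolfpsort, ev.loc_protcomp)


def _relevant_conditions(pathways: frozenset[str] | set[str]) -> set[str]:
    out: set[str] = set()
    for p in pathways:
        out |= PATHWAY_CONDITION_MAP.get(p, frozenset())
    return out


def derive_flags(ev: GeneEvidence, gene_pathways: frozenset[str] | set[str]) -> EvidenceFlags:
    """Collapse sub-evidence to the five boolean support flags.

    Transcriptomic support requires up-regulation on at least one carbon
    source relevant to one of the gene's pathways; proteomic support is
    secretome detection or increased abundance anywhere; genetic support is
    any growth-deficient deletion phenotype; biochemical support counts
    direct or ortholog characterization.
    """
    relevant = _relevant_conditions(gene_pathways)
    return EvidenceFlags(
        f=derive_functional_genomics_flag(ev.functional, ev.assigned_role),
        t=bool(set(ev.transcriptomics.upregulated_vs_noc) & relevant),
        p=bool(ev.proteomics.detected_in_secretome or ev.proteomics.increased_abundance_vs_noc),
        g=bool(ev.genetics.growth_deficient_on),
        b=ev.biochem.characterized_direct or ev.biochem.characterized_ortholog,
    )


def confidence_score(flags: EvidenceFlags, scheme: ScoringScheme = DEFAULT_SCHEME) -> tuple[int, Fraction]:
    """Weighted flag sum as (integer numerator, exact score in [0, 1])."""
    num = (
        scheme.w_f * flags.f
        + scheme.w_t * flags.t
        + scheme.w_p * flags.p
        + scheme.w_g * flags.g
        + scheme.w_b * flags.b
    )
    return num, Fraction(num, scheme.max_score)


def apply_proteomics_priority(ev: GeneEvidence) -> tuple[GeneEvidence, bool]:
    """Re-annotate to extracellular on secretome detection; flag the change."""
    if ev.proteomics.detected_in_secretome and ev.assigned_role != "extracellular":
        return replace(ev, assigned_role="extracellular"), True
    return ev, False


def score_matrix(
    evidence: dict[str, GeneEvidence] | list[GeneEvidence],
    net: Network,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    proteomics_priority: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Score every network gene; returns (per-gene table, per-type support counts).

    The table has one row per network gene (missing evidence means all-false
    flags), columns f/t/p/g/b, the integer numerator, the score to six
    decimals, and a re-annotation indicator.  Evidence rows for genes outside
    the network are skipped with a warning column in the counts dict
    (key ``"skipped"``).
    """
    if isinstance(evidence, list):
        evidence = {e.gene_id: e for e in evidence}
    skipped = sorted(set(evidence) - set(net.genes))

    rows = []
    counts = {k: 0 for k in "ftpgb"}
    for gid in sorted(net.genes):
        gene = net.genes[gid]
        role = next(iter(sorted(gene.role)), "extracellular")
        ev = evidence.get(gid, GeneEvidence(gene_id=gid, assigned_role=role))
        reannotated = False
        if proteomics_priority:
            ev, reannotated = apply_proteomics_priority(ev)
        flags = derive_flags(ev, gene.pathways)
        num, score = confidence_score(flags, scheme)
        for key in "ftpgb":
            counts[key] += getattr(flags, key)
        rows.append(
            {
                "gene_id": gid,
                "f": int(flags.f),
                "t": int(flags.t),
                "p": int(flags.p),
                "g": int(flags.g),
                "b": int(flags.b),
                "numerator": num,
                "score": f"{float(score):.6f}",
                "reannotated": int(reannotated),
            }
        )
    counts["skipped"] = len(skipped)
    return pd.DataFrame(rows), counts


# --- TSV interface -------------------------------------------------------

_BOOL = {"1": True, "true": True, "0": False, "false": False, ".": False, "": False}


def _as_bool(cell) -> bool:
    return _BOOL[str(cell).strip().lower()]


def _as_set(cell) -> frozenset[str]:
    s = str(cell).strip()
    if s in {"", "."}:
        return frozenset()
    return frozenset(p.strip() for p in s.split(";") if p.strip())


def _as_loc(cell) -> str | None:
    s = str(cell).strip()
    return None if s in {"", "."} else s


def read_evidence_table(source, net: Network) -> dict[str, GeneEvidence]:
    """Read the per-gene evidence TSV into :class:`GeneEvidence` records.

    The assigned role comes from the network (first role in sorted order when
    a gene has several).
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(
        source, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    out: dict[str, GeneEvidence] = {}
    for row in df.itertuples(index=False):
        gid = normalize_gene_id(row.gene_id)
        gene = net.genes.get(gid)
        role = next(iter(sorted(gene.role)), "extracellular") if gene else "extracellular"
        out[gid] = GeneEvidence(
            gene_id=gid,
            assigned_role=role,
            functional=FunctionalGenomicsEvidence(
                db_match=_as_bool(row.db_match),
                signalp=_as_bool(row.signalp),
                phobius=_as_bool(row.phobius),
                loc_wolfpsort=_as_loc(row.loc_wolfpsort),
                loc_protcomp=_as_loc(row.loc_protcomp),
            ),
            proteomics=ProteomicsEvidence(
                detected_in_secretome=_as_set(row.secretome_conditions),
                increased_abundance_vs_noc=_as_set(row.abundance_conditions),
            ),
            transcriptomics=TranscriptomicsEvidence(
                upregulated_vs_noc=_as_set(row.upregulated_conditions)
            ),
            genetics=GeneticsEvidence(growth_deficient_on=_as_set(row.growth_deficient_conditions)),
            biochem=BiochemEvidence(
                characterized_direct=_as_bool(row.biochem_direct),
                characterized_ortholog=_as_bool(row.biochem_ortholog),
            ),
        )
    return out
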