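"""Seeded generators with planted truth for every pipeline stage.

Each generator is a pure function of (config, seed): a synthetic
degradation network with realistic compartment proportions, log-normal
baseline expression with condition-specific planted induction against the
two controls, Bernoulli evidence tables rendered down to the sub-evidence
columns the scoring rules consume, and TF target sets with a planted
network-overlap share.  The accompanying truth records make recovery
assertions exact (set equality for evidence flags, statistical bounds for
regulon recovery).

The default prevalences and effect sizes mirror the study conditions the
pipeline was designed around: three replicates, log2 induction of 3
against both NoC and sucrose, replicate noise of 0.3 on the log2 scale,
and per-type evidence prevalences (0.86, 0.63, 0.40, 0.11, 0.67)
matching the observed support fractions for the five data types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evidence as ev_mod
from .network import COMPARTMENT_CLASSES, PATHWAY_TAGS, Network, load_network
from .regulons import ExpressionMatrix
from .tf import TFTargetSet

__all__ = ["SimulationConfig", "TruthRecord", "simulate_network", "simulate_expression",
           "simulate_evidence", "simulate_tf_targets", "simulate_bundle"]

#: target compartment proportions for simulated reactions (extracellular,
#: transport, intracellular), approximating the curated network's 101/35/66
COMPARTMENT_PROPORTIONS = (0.50, 0.17, 0.33)

DEFAULT_CONDITIONS = (
    "Avicel", "xylan", "xyloglucan", "mannan", "MLG", "pectin", "starch",
    "NoC", "sucrose",
)

#: per-type evidence prevalence (f, t, p, g, b) matching observed support
#: fractions 145/168, 106/168, 68/168, 19/168, 113/168
DEFAULT_EVIDENCE_PREVALENCE = (0.86, 0.63, 0.40, 0.11, 0.67)


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    n_network_genes: int = 168
    pathway_mixture: tuple[float, ...] = (0.30, 0.15, 0.10, 0.08, 0.07, 0.20, 0.10)
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    replicate_noise_sd: float = 0.3
    induction_log2fc: float = 3.0
    regulon_prevalence: float = 0.3
    evidence_prevalence: tuple[float, ...] = DEFAULT_EVIDENCE_PREVALENCE
    tf_overlap_fraction: float = 0.15
    genome_target_count: int = 300

    def __post_init__(self) -> None:
        if self.n_network_genes > self.n_genes:
            raise ValueError("n_network_genes must not exceed n_genes")
        for p in (*self.pathway_mixture, *self.evidence_prevalence,
                  self.regulon_prevalence, self.tf_overlap_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_genes, self.n_network_genes, self.n_replicates,
               self.genome_target_count) <= 0:
            raise ValueError("counts must be positive")
        if "NoC" not in self.conditions or "sucrose" not in self.conditions:
            raise ValueError("conditions must include the NoC and sucrose controls")
        if len(self.pathway_mixture) != len(PATHWAY_TAGS):
            raise ValueError("pathway_mixture must have one weight per pathway tag")
        if len(self.evidence_prevalence) != 5:
            raise ValueError("evidence_prevalence must have five entries (f, t, p, g, b)")


@dataclass
class TruthRecord:
    planted_regulons: dict[str, frozenset[str]] = field(default_factory=dict)
    planted_flags: dict[str, ev_mod.EvidenceFlags] = field(default_factory=dict)
    tf_network_targets: frozenset[str] = frozenset()


def _genome_gene_ids(n: int) -> list[str]:
    return [f"NCU{i:05d}" for i in range(1, n + 1)]


def network_gene_ids(cfg: SimulationConfig) -> list[str]:
    """The first ``n_network_genes`` genome ids are the network members."""
    return _genome_gene_ids(cfg.n_genes)[: cfg.n_network_genes]


def simulate_network(cfg: SimulationConfig, seed: int) -> tuple[Network, TruthRecord]:
    """Synthetic network: one reaction per gene plus shared-compound chains.

    Compartments are drawn at the curated network's proportions and every
    gene carries exactly one reaction, so the network always validates with
    zero errors and the gene count is exact.
    """
    rng = np.random.default_rng(seed)
    gene_ids = network_gene_ids(cfg)
    mixture = np.asarray(cfg.pathway_mixture, dtype=float)
    mixture = mixture / mixture.sum()

    compounds, reactions, genes = [], [], []
    for i, gid in enumerate(gene_ids):
        comp = rng.choice(COMPARTMENT_CLASSES, p=COMPARTMENT_PROPORTIONS)
        pathway = rng.choice(PATHWAY_TAGS, p=mixture)
        sub, prod = f"C{i:04d}a", f"C{i:04d}b"
        compounds += [
            {"compound_id": sub, "name": f"substrate {i}", "is_polymer": "1"},
            {"compound_id": prod, "name": f"product {i}", "is_polymer": "0"},
        ]
        reactions.append(
            {
                "reaction_id": f"R{i:04d}",
                "name": f"simulated reaction {i}",
                "compartment": str(comp),
                "substrates": sub,
                "products": prod,
                "pathways": str(pathway),
                "genes": gid,
            }
        )
        genes.append({"gene_id": gid, "symbol": ".", "role": "."})
    net = load_network(
        pd.DataFrame(reactions), pd.DataFrame(genes), pd.DataFrame(compounds),
        version="synthetic",
    )
    return net, TruthRecord()


# map pathway -> the condition whose planted regulon should contain its genes
_PATHWAY_TO_CONDITION = {
    "cellulose": "Avicel",
    "xylan": "xylan",
    "xyloglucan": "xyloglucan",
    "mannan": "mannan",
    "mixed-linkage glucan": "MLG",
    "pectin": "pectin",
    "starch": "starch",
}


def simulate_expression(
    cfg: SimulationConfig, net: Network, seed: int
) -> tuple[ExpressionMatrix, TruthRecord]:
    """Log-normal FPKM with condition-specific planted induction.

    Replicate FPKM = 2**(baseline_g + effect * planted + noise), noise
    iid Normal(0, replicate_noise_sd).  For each non-control condition a
    ``regulon_prevalence`` share of network genes is planted; the two
    controls are never induced, so planted genes are true two-control
    regulon members by construction.
    """
    rng = np.random.default_rng(seed)
    genome = _genome_gene_ids(cfg.n_genes)
    net_genes = sorted(net.genes)
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=cfg.n_genes)

    truth = TruthRecord()
    test_conditions = [c for c in cfg.conditions if c not in ("NoC", "sucrose")]
    n_plant = int(round(cfg.regulon_prevalence * len(net_genes)))
    gene_index = {g: i for i, g in enumerate(genome)}
    planted_mask: dict[str, np.ndarray] = {}
    for cond in test_conditions:
        chosen = rng.choice(net_genes, size=n_plant, replace=False) if n_plant else []
        truth.planted_regulons[cond] = frozenset(map(str, chosen))
        mask = np.zeros(cfg.n_genes)
        for g in chosen:
            mask[gene_index[g]] = 1.0
        planted_mask[cond] = mask

    values: dict[str, np.ndarray] = {}
    for cond in cfg.conditions:
        shift = cfg.induction_log2fc * planted_mask.get(cond, np.zeros(cfg.n_genes))
        noise = rng.normal(0.0, cfg.replicate_noise_sd, size=(cfg.n_genes, cfg.n_replicates))
        values[cond] = 2.0 ** (baseline[:, None] + shift[:, None] + noise)
    return ExpressionMatrix(genes=genome, values=values), truth


def simulate_evidence(
    cfg: SimulationConfig, net: Network, seed: int
) -> tuple[dict[str, ev_mod.GeneEvidence], TruthRecord]:
    """Bernoulli per-type flags rendered as consistent sub-evidence columns.

    A planted true flag is rendered so the scoring rules recover it exactly
    (e.g. a functional-genomics flag becomes db_match plus role-consistent
    signal-peptide and localization predictions); a false flag is rendered
    as the minimal inconsistency (no database match, no observation).
    Planted proteomic support for non-extracellular genes is rendered as
    increased abundance rather than secretome detection, so the
    re-annotation rule does not fire on simulated data.
    """
    rng = np.random.default_rng(seed)
    truth = TruthRecord()
    out: dict[str, ev_mod.GeneEvidence] = {}
    pf, pt, pp, pg, pb = cfg.evidence_prevalence
    for gid in sorted(net.genes):
        gene = net.genes[gid]
        role = next(iter(sorted(gene.role)), "extracellular")
        f, t, p, g, b = (rng.random() < q for q in (pf, pt, pp, pg, pb))
        pathways = sorted(gene.pathways)
        relevant = sorted(
            {c for pw in pathways for c in ev_mod.PATHWAY_CONDITION_MAP.get(pw, ())}
        ) or ["Avicel"]
        if not pathways:
            t = False  # no pathway, no relevant carbon source to support
        func = ev_mod.FunctionalGenomicsEvidence(
            db_match=f,
            signalp=f and role == "extracellular",
            phobius=False,
            loc_wolfpsort=("membrane" if role == "transport" else role) if f else None,
            loc_protcomp=None,
        )
        prot = ev_mod.ProteomicsEvidence(
            detected_in_secretome=frozenset({relevant[0]}) if p and role == "extracellular" else frozenset(),
            increased_abundance_vs_noc=frozenset({relevant[0]}) if p and role != "extracellular" else frozenset(),
        )
        out[gid] = ev_mod.GeneEvidence(
            gene_id=gid,
            assigned_role=role,
            functional=func,
            proteomics=prot,
            transcriptomics=ev_mod.TranscriptomicsEvidence(
                upregulated_vs_noc=frozenset({relevant[0]}) if t else frozenset()
            ),
            genetics=ev_mod.GeneticsEvidence(
                growth_deficient_on=frozenset({relevant[0]}) if g else frozenset()
            ),
            biochem=ev_mod.BiochemEvidence(
                characterized_direct=b and bool(rng.random() < 0.3),
                characterized_ortholog=b,
            ),
        )
        truth.planted_flags[gid] = ev_mod.EvidenceFlags(f=f, t=t, p=p, g=g, b=b)
    return out, truth


def simulate_tf_targets(
    cfg: SimulationConfig, net: Network, seed: int, tf_name: str = "SIM-TF"
) -> tuple[TFTargetSet, TruthRecord]:
    """Target set with a planted network-overlap share.

    The number of network-drawn targets is sampled hypergeometrically with
    an effective category of round(tf_overlap_fraction * n_genes) genes, so
    when the fraction equals the network's genome share the overlap is
    exactly null-distributed (enrichment p approximately uniform), while a
    larger fraction plants real enrichment.  The TF's own gene id comes
    from the non-network pool.
    """
    rng = np.random.default_rng(seed)
    genome = _genome_gene_ids(cfg.n_genes)
    net_genes = sorted(net.genes)
    others = [g for g in genome if g not in net.genes]
    n_targets = min(cfg.genome_target_count, cfg.n_genes - 1)  # leave room for the TF gene
    k_eff = int(round(cfg.tf_overlap_fraction * cfg.n_genes))
    n_net = int(rng.hypergeometric(k_eff, cfg.n_genes - k_eff, n_targets)) if k_eff else 0
    n_net = min(n_net, len(net_genes))
    n_other = min(cfg.genome_target_count - n_net, len(others) - 1)
    from_net = rng.choice(net_genes, size=n_net, replace=False) if n_net else []
    from_other = rng.choice(others[1:], size=n_other, replace=False) if n_other else []
    truth = TruthRecord(tf_network_targets=frozenset(map(str, from_net)))
    tf = TFTargetSet(
        tf_gene_id=others[0],
        tf_name=tf_name,
        targets=frozenset(map(str, from_net)) | frozenset(map(str, from_other)),
    )
    return tf, truth


def simulate_bundle(cfg: SimulationConfig, seed: int):
    """Network, expression, evidence and TF targets from one base seed.

    Sub-seeds are derived deterministically (and kept below 2**31) so the
    bundle is a pure function of (cfg, seed).
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    net, _ = simulate_network(cfg, sub[0])
    expr, expr_truth = simulate_expression(cfg, net, sub[1])
    evid, evid_truth = simulate_evidence(cfg, net, sub[2])
    tf, tf_truth = simulate_tf_targets(cfg, net, sub[3])
    truth = TruthRecord(
        planted_regulons=expr_truth.planted_regulons,
        planted_flags=evid_truth.planted_flags,
        tf_network_targets=tf_truth.tf_network_targets,
    )
    return net, expr, evid, tf, truth
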