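"""Transcription-factor target overlap with the network and feed-forward loops.

Consumes flat ChIP-derived target lists (genes whose regulatory regions a
TF binds) and asks two questions: does the TF's genome-wide target set
overlap the degradation network more than chance (hypergeometric upper
tail), and which pathways do the bound network genes serve?  A
feed-forward loop exists when a master TF binds both an intermediate TF's
gene and a target also bound by the intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .enrichment import DEFAULT_ALPHA, EnrichmentResult, enrich_sets
from .network import PATHWAY_TAGS, Network

__all__ = [
    "TFTargetSet",
    "FFLInstance",
    "pcwdn_overlap",
    "pathway_breakdown",
    "detect_ffl",
    "read_tf_targets",
]


@dataclass(frozen=True)
class TFTargetSet:
    tf_gene_id: str
    tf_name: str
    targets: frozenset[str]


@dataclass(frozen=True)
class FFLInstance:
    master_tf: str
    intermediate_tf: str
    target: str


def pcwdn_overlap(
    tf: TFTargetSet, net: Network, universe_size: int, alpha: float = DEFAULT_ALPHA
) -> tuple[set[str], EnrichmentResult]:
    """Bound network genes and their hypergeometric enrichment.

    The category is the network gene set (K = its size), the query the TF's
    genome-wide targets; ``universe_size`` is the genome gene count.
    """
    bound = set(tf.targets) & set(net.genes)
    result = enrich_sets(set(tf.targets), set(net.genes), universe_size, alpha=alpha)
    return bound, result


def pathway_breakdown(bound_genes: set[str], net: Network) -> dict[str, int]:
    """Count bound genes per pathway tag (multi-pathway genes count in each)."""
    unknown = sorted(set(bound_genes) - set(net.genes))
    if unknown:
        raise ValueError(f"gene(s) not in network: {', '.join(unknown)}")
    counts = {p: 0 for p in PATHWAY_TAGS}
    for gid in bound_genes:
        for p in net.genes[gid].pathways:
            counts[p] += 1
    return counts


def detect_ffl(
    master: TFTargetSet,
    intermediate: TFTargetSet,
    restrict_to: set[str] | None = None,
) -> list[FFLInstance]:
    """Feed-forward loops master -> intermediate -> target, master -> target.

    Empty unless the master binds the intermediate TF's own gene; the
    intermediate's gene is excluded from the shared-target list.  Instances
    are returned sorted by target id.
    """
    if intermediate.tf_gene_id not in master.targets:
        return []
    shared = (set(master.targets) & set(intermediate.targets)) - {intermediate.tf_gene_id}
    if restrict_to is not None:
        shared &= set(restrict_to)
    return [
        FFLInstance(master_tf=master.tf_gene_id, intermediate_tf=intermediate.tf_gene_id, target=t)
        for t in sorted(shared)
    ]


def read_tf_targets(source) -> dict[str, TFTargetSet]:
    """Read an edge-list TSV (tf_id, tf_name, target_gene_id) into target sets."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(
        source, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    out: dict[str, TFTargetSet] = {}
    for (tf_id, tf_name), grp in df.groupby(["tf_id", "tf_name"], sort=True):
        out[tf_id] = TFTargetSet(
            tf_gene_id=tf_id, tf_name=tf_name, targets=frozenset(grp["target_gene_id"])
        )
    return out
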