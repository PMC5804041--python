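"""Cross-layer module integration and module-trait correlation.

miRNA and mRNA modules are linked through Pearson correlation of their
eigengenes; a pair is retained when r <= -0.4 with p < 0.05 (negative
regulation hypothesis: an abundant miRNA module suppressing an mRNA module).
Module-trait relationships use an intentionally permissive unadjusted
p < 0.1 screen.  Retained pairs, hub miRNAs and mRNA-module enrichment
results can be assembled into a bipartite hub-miRNA <-> GO-term graph for
export.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .data_model import PhenotypeTable
from .pcit import correlation_p

__all__ = [
    "module_module_correlation",
    "module_trait_correlation",
    "bipartite_network",
]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        raise ValueError("constant vector has no defined correlation")
    return float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))


def module_module_correlation(
    me_mirna: pd.DataFrame,
    me_mrna: pd.DataFrame,
    r_cut: float = -0.4,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Score every miRNA-module x mRNA-module eigengene pair.

    Retains pairs with r <= r_cut and p < p_cut.  Both eigengene frames must
    be module x sample over the same samples (same column order).
    """
    if list(me_mirna.columns) != list(me_mrna.columns):
        raise ValueError("eigengene matrices cover different samples")
    n = me_mirna.shape[1]
    rows = []
    for mi in me_mirna.index:
        for mr in me_mrna.index:
            r = _pearson(me_mirna.loc[mi].to_numpy(), me_mrna.loc[mr].to_numpy())
            p = float(correlation_p(np.array(r), n))
            rows.append(
                {
                    "mirna_module": mi,
                    "mrna_module": mr,
                    "r": r,
                    "p": p,
                    "retained": bool(r <= r_cut and p < p_cut),
                }
            )
    return (
        pd.DataFrame(rows, columns=["mirna_module", "mrna_module", "r", "p", "retained"])
        .sort_values(["mirna_module", "mrna_module"])
        .reset_index(drop=True)
    )


def module_trait_correlation(
    me: pd.DataFrame,
    pheno: PhenotypeTable,
    trait_column: str = "imf_percent",
    p_cut: float = 0.1,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a numeric trait.

    ``sample_ids`` names the phenotype rows matching the eigengene columns
    (defaults to all rows in phenotype-table order).  Modules with p < p_cut
    (unadjusted) are flagged retained.
    """
    if sample_ids is None:
        sample_ids = pheno.sample_ids
    if len(sample_ids) != me.shape[1]:
        raise ValueError("eigengene columns do not match the sample list")
    if len(sample_ids) < 3:
        raise ValueError("need at least 3 samples")
    trait = (
        pd.to_numeric(pheno.column(trait_column), errors="raise")
        .set_axis(pheno.sample_ids)
        .loc[sample_ids]
        .to_numpy(dtype=float)
    )
    if np.std(trait) == 0:
        raise ValueError(f"trait {trait_column!r} is constant")
    n = len(sample_ids)
    rows = []
    for mod in me.index:
        r = _pearson(me.loc[mod].to_numpy(), trait)
        p = float(correlation_p(np.array(r), n))
        rows.append(
            {"module": mod, "trait": trait_column, "r": r, "p": p, "retained": bool(p < p_cut)}
        )
    return (
        pd.DataFrame(rows, columns=["module", "trait", "r", "p", "retained"])
        .sort_values("module")
        .reset_index(drop=True)
    )


def bipartite_network(
    pairs: pd.DataFrame,
    mirna_hubs: dict[str, str],
    mrna_enrichment: dict[str, pd.DataFrame],
) -> nx.Graph:
    """Bipartite graph linking hub miRNAs to GO terms of partner mRNA modules.

    For each retained miRNA-module / mRNA-module pair, every hub of the miRNA
    module is connected to every enriched term of the mRNA module.  Nodes are
    typed (``kind="mirna_hub"`` or ``kind="term"``); an empty graph is valid.
    """
    g = nx.Graph()
    retained = pairs[pairs["retained"]] if "retained" in pairs.columns else pairs
    for _, row in retained.iterrows():
        mi, mr = row["mirna_module"], row["mrna_module"]
        hubs = mirna_hubs.get(mi)
        hub_list = [hubs] if isinstance(hubs, str) else list(hubs or [])
        enr = mrna_enrichment.get(mr)
        if enr is None or not hub_list:
            continue
        terms = enr.loc[enr["enriched"], "term"] if "enriched" in enr.columns else enr["term"]
        for hub in hub_list:
            g.add_node(hub, kind="mirna_hub", module=mi)
            for term in terms:
                g.add_node(term, kind="term", module=mr)
                g.add_edge(hub, term, mirna_module=mi, mrna_module=mr)
    return g
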