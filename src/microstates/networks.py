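"""Permutation-null Spearman co-occurrence networks.

Within a group of samples (typically one community state), pairwise
Spearman correlations between ASV abundance profiles are tested against
a null obtained by independently shuffling each ASV's abundances across
samples and recomputing all correlations (1000 shuffles by default) —
this breaks every pairwise dependence while preserving marginals.
Per-pair permutation p-values get a Benjamini-Hochberg correction;
edges are kept below the significance threshold, on the adjusted q by
default (a ``filter_on`` switch reproduces the raw-p reading).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .tables import CountTable

logger = logging.getLogger(__name__)

__all__ = ["CooccurrenceNetwork", "build_network"]


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph
    nodes: pd.DataFrame          # ASV, mean relative abundance, prevalence
    edges: pd.DataFrame          # all tested pairs with rho, p, q, kept flag
    group: str
    n_perm: int
    alpha: float
    n_skipped_constant: int


def build_network(
    table: CountTable,
    sample_ids=None,
    group: str = "all",
    min_prevalence: int = 2,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    filter_on: str = "q",
) -> CooccurrenceNetwork:
    """Build the co-occurrence network for one sample group.

    ASVs present in fewer than ``min_prevalence`` of the group's samples
    are excluded.  Constant (zero-variance) ASVs are kept as nodes but
    their pairs are skipped — a rank correlation is undefined for them.
    """
    if filter_on not in ("p", "q"):
        raise ValueError("filter_on must be 'p' or 'q'")
    sub = table if sample_ids is None else table.select_samples(sample_ids)
    n = sub.shape[0]
    if n < 4:
        raise ValueError(f"group {group!r} has {n} samples; need at least 4")
    prevalence = (sub.data > 0).sum(axis=0)
    keep = prevalence[prevalence >= min_prevalence].index
    counts = sub.data[keep].to_numpy(dtype=float)
    A = counts.shape[1]
    if A < 2:
        raise ValueError("fewer than 2 ASVs pass the prevalence filter")

    ranks = np.apply_along_axis(rankdata, 0, counts)  # average ranks for ties
    sd = ranks.std(axis=0)
    variable = sd > 0
    Z = np.zeros_like(ranks)
    Z[:, variable] = (ranks[:, variable] - ranks[:, variable].mean(axis=0)) / sd[variable]
    rho = (Z.T @ Z) / n
    iu = np.triu_indices(A, k=1)
    obs = rho[iu]
    valid = variable[iu[0]] & variable[iu[1]]
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.info("build_network: %d pairs skipped (constant ASV)", n_skipped)

    rng = substream(seed, "network", group)
    exceed = np.zeros(obs.shape, dtype=np.int64)
    abs_obs = np.abs(obs) - 1e-12
    for _ in range(n_perm):
        order = np.argsort(rng.random((A, n)), axis=1).T  # independent per column
        Zp = np.take_along_axis(Z, order, axis=0)
        rho_p = (Zp.T @ Zp) / n
        exceed += np.abs(rho_p[iu]) >= abs_obs
    p = (1.0 + exceed) / (n_perm + 1.0)
    p[~valid] = np.nan

    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    crit = p if filter_on == "p" else q
    kept = valid & (crit < alpha)

    asv_ids = list(keep)
    rel = sub.relative_abundance()[keep]
    nodes = pd.DataFrame(
        {
            "mean_relative_abundance": rel.mean(axis=0),
            "prevalence": prevalence[keep].astype(int),
        }
    )
    edges = pd.DataFrame(
        {
            "asv_a": [asv_ids[i] for i in iu[0]],
            "asv_b": [asv_ids[j] for j in iu[1]],
            "spearman_rho": obs,
            "p_value": p,
            "q_value": q,
            "sign": np.sign(obs).astype(int),
            "kept": kept,
        }
    )

    g = nx.Graph(group=group)
    for asv in asv_ids:
        g.add_node(
            asv,
            mean_relative_abundance=float(nodes.loc[asv, "mean_relative_abundance"]),
            prevalence=int(nodes.loc[asv, "prevalence"]),
        )
    for row in edges[edges["kept"]].itertuples():
        g.add_edge(
            row.asv_a, row.asv_b,
            spearman_rho=float(row.spearman_rho),
            p_value=float(row.p_value),
            q_value=float(row.q_value),
            sign=int(row.sign),
        )
    return CooccurrenceNetwork(
        graph=g, nodes=nodes, edges=edges, group=group,
        n_perm=n_perm, alpha=alpha, n_skipped_constant=n_skipped,
    )
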