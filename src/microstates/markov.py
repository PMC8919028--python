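"""Markov models of community-state dynamics and cross-site detection.

Per body site, the observed per-patient state series are pooled into a
transition count matrix; the row-normalised matrix defines a discrete-time
Markov chain over community states.  Stationary (steady-state) frequencies
give the long-run expectation of each state, and states are classified as
recurrent or transient from the closed communicating classes of the
positive-transition digraph.  Cross-site ASV detection is summarised by
empirical conditional probabilities P(detected at one site | detected at
another on the same sampling occasion), which satisfy the Bayes identity
P(s1|s2) P(s2) = P(s2|s1) P(s1) exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .tables import CountTable

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionModel",
    "ConditionalDetection",
    "transition_counts",
    "estimate_transitions",
    "stationary_distribution",
    "classify_states",
    "conditional_detection",
    "transition_graph_summary",
]


@dataclass
class TransitionModel:
    """A fitted per-body-site community-state chain."""

    body_site: str
    states: list[str]
    counts: pd.DataFrame
    probabilities: pd.DataFrame
    stationary: list[pd.Series]
    classification: pd.Series  # state -> "recurrent" | "transient"
    uniform_rows: list[str]    # states never observed as a step origin
    n_steps: int

    @property
    def mean_self_transition(self) -> float:
        """Mean diagonal probability over observed-origin states."""
        observed = self.counts.sum(axis=1) > 0
        if not observed.any():
            return float("nan")
        diag = np.diag(self.probabilities.to_numpy())
        return float(diag[observed.to_numpy()].mean())


def _positive_digraph(P: np.ndarray) -> nx.DiGraph:
    g = nx.DiGraph()
    k = P.shape[0]
    g.add_nodes_from(range(k))
    src, dst = np.nonzero(P > 0)
    g.add_edges_from(zip(src.tolist(), dst.tolist()))
    return g


def _closed_classes(P: np.ndarray) -> list[set[int]]:
    """Closed communicating classes (no positive edge leaving the class)."""
    g = _positive_digraph(P)
    closed = []
    for comp in nx.strongly_connected_components(g):
        if all(dst in comp for node in comp for dst in g.successors(node)):
            closed.append(set(comp))
    return sorted(closed, key=min)


def _check_stochastic(P) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"transition matrix must be square, got {P.shape}")
    if (P < 0).any():
        i, j = np.argwhere(P < 0)[0]
        raise ValueError(f"negative entry at ({i}, {j})")
    rowsums = P.sum(axis=1)
    bad = np.where(np.abs(rowsums - 1.0) > 1e-8)[0]
    if bad.size:
        raise ValueError(f"row {bad[0]} sums to {rowsums[bad[0]]!r}, not 1")
    return P


def stationary_distribution(P) -> list[np.ndarray]:
    """All extremal stationary distributions of a row-stochastic matrix.

    One distribution per closed communicating class, each solving
    pi = pi P with pi >= 0 summing to 1; a single-element list for chains
    with a unique closed class.
    """
    P = _check_stochastic(P)
    k = P.shape[0]
    out = []
    for cls in _closed_classes(P):
        idx = sorted(cls)
        sub = P[np.ix_(idx, idx)]
        m = len(idx)
        # solve pi (sub - I) = 0 with the normalisation replacing one column
        A = (sub - np.eye(m)).T
        A[-1, :] = 1.0
        b = np.zeros(m)
        b[-1] = 1.0
        pi_sub = np.linalg.solve(A, b)
        pi_sub = np.clip(pi_sub, 0.0, None)
        pi_sub /= pi_sub.sum()
        pi = np.zeros(k)
        pi[idx] = pi_sub
        residual = np.abs(pi @ P - pi).max()
        if residual > 1e-10:
            raise ArithmeticError(f"stationary solve residual {residual:.2e}")
        out.append(pi)
    return out


def classify_states(P) -> np.ndarray:
    """Recurrent/transient label per state.

    A state is recurrent iff it lies in a closed communicating class of
    the positive-probability digraph; return probability one is then
    guaranteed for finite chains.
    """
    P = _check_stochastic(P)
    recurrent = set().union(*_closed_classes(P)) if _closed_classes(P) else set()
    return np.array(
        ["recurrent" if i in recurrent else "transient" for i in range(P.shape[0])]
    )


# ---------------------------------------------------------------------------
# Estimation from observed series
# ---------------------------------------------------------------------------

def transition_counts(sequences, states: list[str]) -> pd.DataFrame:
    """Pooled step counts C[i, j] = number of observed i -> j transitions."""
    index = pd.Index(states)
    C = pd.DataFrame(0, index=index, columns=index, dtype=np.int64)
    for seq in sequences:
        seq = list(seq)
        for a, b in zip(seq[:-1], seq[1:]):
            C.loc[a, b] += 1
    return C


def estimate_transitions(
    labels: pd.Series,
    meta: pd.DataFrame,
    site: str,
    smoothing: float = 0.0,
    states: list[str] | None = None,
) -> TransitionModel:
    """Fit a site-level transition model from per-sample state labels.

    ``labels`` maps sample id to state.  Per patient, samples at ``site``
    are ordered by ``time_index``; a step is a pair of samples at adjacent
    occasions (time-index difference of exactly 1 — gaps left by dropped
    samples do not form steps).  Counts are pooled over patients, the
    maximum-likelihood estimate of a shared site chain.  Rows never
    observed as an origin become uniform, with a warning.
    """
    sub = meta[meta["body_site"] == site]
    sequences = []
    for _, grp in sub.groupby("patient_id"):
        grp = grp.sort_values("time_index")
        ids = grp["sample_id"].to_numpy()
        times = grp["time_index"].to_numpy()
        present = [(t, s) for t, s in zip(times, ids) if s in labels.index]
        for (t0, s0), (t1, s1) in zip(present[:-1], present[1:]):
            if t1 - t0 == 1:
                sequences.append([labels[s0], labels[s1]])
            else:
                logger.info(
                    "estimate_transitions: gap %s -> %s at site %s skipped", t0, t1, site
                )
    if states is None:
        observed = sorted({s for seq in sequences for s in seq} | set(labels[labels.index.isin(sub["sample_id"])].unique()))
        states = observed
    if not sequences:
        raise ValueError(f"site {site!r} has no state series of length >= 2")
    C = transition_counts(sequences, states)
    smoothed = C.to_numpy(dtype=float) + smoothing
    rowsums = smoothed.sum(axis=1)
    uniform_rows = [states[i] for i in np.where(rowsums == 0)[0]]
    if uniform_rows:
        logger.warning(
            "estimate_transitions: site %s states %s never observed as origin; "
            "rows set uniform", site, uniform_rows,
        )
        smoothed[rowsums == 0] = 1.0
        rowsums = smoothed.sum(axis=1)
    P = smoothed / rowsums[:, None]
    Pdf = pd.DataFrame(P, index=C.index, columns=C.columns)
    pis = stationary_distribution(P)
    classification = pd.Series(classify_states(P), index=C.index)
    return TransitionModel(
        body_site=site,
        states=list(states),
        counts=C,
        probabilities=Pdf,
        stationary=[pd.Series(pi, index=C.index) for pi in pis],
        classification=classification,
        uniform_rows=uniform_rows,
        n_steps=int(C.to_numpy().sum()),
    )


def transition_graph_summary(model: TransitionModel) -> tuple[pd.DataFrame, float]:
    """Edge list (positive-probability transitions) and mean self-transition."""
    rows = []
    P = model.probabilities
    for a in model.states:
        for b in model.states:
            p = float(P.loc[a, b])
            if p > 0:
                rows.append({"from_state": a, "to_state": b, "probability": p})
    edges = pd.DataFrame(rows, columns=["from_state", "to_state", "probability"])
    return edges, model.mean_self_transition


# ---------------------------------------------------------------------------
# Conditional cross-site detection
# ---------------------------------------------------------------------------

@dataclass
class ConditionalDetection:
    """Empirical conditional detection probabilities across body sites.

    ``per_asv`` holds, per ASV and ordered pair (s1, s2), the probability
    of detection at s1 given detection at s2 on the same (patient,
    occasion); undefined entries (ASV never detected at s2 on a matched
    occasion) are missing, not zero.  ``prevalence`` holds the marginal
    detection frequency of the ASV at each site of the pair over the
    matched occasions.  ``aggregate`` is the unweighted mean of defined
    per-ASV values per ordered pair.
    """

    per_asv: pd.DataFrame          # index ASV, columns MultiIndex (s1, s2)
    prevalence: pd.DataFrame       # index ASV, columns MultiIndex (site, paired-with)
    aggregate: pd.DataFrame        # ordered site pair matrix
    n_matched: dict[tuple[str, str], int] = field(default_factory=dict)
    per_infant: pd.DataFrame | None = None


def conditional_detection(
    table: CountTable,
    meta: pd.DataFrame,
    detection_threshold: int = 1,
    per_infant: bool = True,
) -> ConditionalDetection:
    """Cross-site conditional ASV detection probabilities.

    Detection means count >= ``detection_threshold`` in the (rarefied)
    table.  Occasions are matched on (patient, time_index); both sites
    must have a sample at the occasion for it to enter the pair's
    denominator.
    """
    meta_idx = meta.set_index("sample_id")
    meta_idx = meta_idx.loc[[s for s in table.sample_ids if s in meta_idx.index]]
    detected = table.data.loc[meta_idx.index] >= detection_threshold
    sites = sorted(meta_idx["body_site"].unique())
    occasions = meta_idx.reset_index().set_index(["body_site", "patient_id", "time_index"])[
        "sample_id"
    ]

    per_asv_cols, prev_cols, n_matched = {}, {}, {}
    agg = pd.DataFrame(np.nan, index=sites, columns=sites, dtype=float)
    infant_rows = []
    for s1 in sites:
        for s2 in sites:
            if s1 == s2:
                continue
            occ1 = occasions.loc[s1]
            occ2 = occasions.loc[s2]
            shared = occ1.index.intersection(occ2.index)
            n_matched[(s1, s2)] = len(shared)
            if len(shared) == 0:
                continue
            d1 = detected.loc[occ1.loc[shared].to_numpy()].to_numpy()
            d2 = detected.loc[occ2.loc[shared].to_numpy()].to_numpy()
            n2 = d2.sum(axis=0).astype(float)
            n12 = (d1 & d2).sum(axis=0).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(n2 > 0, n12 / np.maximum(n2, 1), np.nan)
            per_asv_cols[(s1, s2)] = pd.Series(p, index=table.data.columns)
            prev_cols[(s1, s2)] = pd.Series(
                d1.sum(axis=0) / len(shared), index=table.data.columns
            )
            defined = ~np.isnan(p)
            agg.loc[s1, s2] = float(np.nanmean(p)) if defined.any() else np.nan
            if per_infant:
                patients = shared.get_level_values(0)
                for pat in sorted(set(patients)):
                    mask = patients == pat
                    if not mask.any():
                        continue
                    m2 = d2[mask].sum(axis=0).astype(float)
                    m12 = (d1[mask] & d2[mask]).sum(axis=0).astype(float)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        pi = np.where(m2 > 0, m12 / np.maximum(m2, 1), np.nan)
                    infant_rows.append(
                        {
                            "patient_id": pat,
                            "site_detect": s1,
                            "site_given": s2,
                            "mean_conditional_probability": float(np.nanmean(pi))
                            if np.isfinite(pi).any()
                            else np.nan,
                            "n_occasions": int(mask.sum()),
                        }
                    )

    per_asv = pd.DataFrame(per_asv_cols)
    per_asv.columns = pd.MultiIndex.from_tuples(per_asv.columns, names=["detect", "given"])
    prevalence = pd.DataFrame(prev_cols)
    prevalence.columns = pd.MultiIndex.from_tuples(
        prevalence.columns, names=["site", "paired_with"]
    )
    infant_df = pd.DataFrame(infant_rows) if per_infant else None
    return ConditionalDetection(
        per_asv=per_asv,
        prevalence=prevalence,
        aggregate=agg,
        n_matched=n_matched,
        per_infant=infant_df,
    )


def verify_bayes_identity(cd: ConditionalDetection, atol: float = 1e-12) -> float:
    """Max absolute violation of P(s1|s2) P(s2) = P(s2|s1) P(s1).

    Both sides are computed from the empirical estimates; the identity is
    algebraic, so the return value should be at machine precision.
    """
    worst = 0.0
    for (s1, s2) in cd.per_asv.columns:
        if (s2, s1) not in cd.per_asv.columns:
            continue
        p12 = cd.per_asv[(s1, s2)]          # P(detect s1 | detect s2)
        p21 = cd.per_asv[(s2, s1)]          # P(detect s2 | detect s1)
        m1 = cd.prevalence[(s1, s2)]        # P(detect s1) on matched occasions
        m2 = cd.prevalence[(s2, s1)]        # P(detect s2) on matched occasions
        lhs = p12 * m2
        rhs = p21 * m1
        both = lhs.notna() & rhs.notna()
        if both.any():
            worst = max(worst, float((lhs[both] - rhs[both]).abs().max()))
    return worst
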