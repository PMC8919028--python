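"""Null-model inference of community assembly processes.

Phylogenetic turnover between paired communities is measured by the
abundance-weighted beta mean nearest taxon distance (betaMNTD); its
standardized effect size against a tip-shuffling null (taxa randomly
re-assigned to tree tips across the whole tree, 999 replicates by
default) is the beta nearest taxon index (betaNTI).  |betaNTI| > 2 flags
deterministic turnover: > +2 variable selection, < -2 homogeneous
selection.  Pairs left to stochastic processes are split by the
Raup-Crick metric on Bray-Curtis (RC-Bray), whose null reassembles each
community preserving observed richness and reads, with species drawn by
occupancy and reads by metacommunity relative abundance: RC > 0.95 is
dispersal limitation, RC < -0.95 homogenizing dispersal, and the
remainder ecological drift.

The betaMNTD kernel is vectorised: per null replicate, the matrix of
nearest-taxon distances G[m, i] = min_{j in community m} d(i, j) is
assembled once, and the full pairwise betaMNTD matrix follows as
0.5 (F G^T + (F G^T)^T) with F the relative-abundance matrix, because
absent taxa carry zero weight.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency
from skbio import TreeNode

from ._rng import substream
from .tables import CountTable

logger = logging.getLogger(__name__)

__all__ = [
    "ProcessPartition",
    "PROCESS_CATEGORIES",
    "patristic_matrix",
    "beta_mntd",
    "beta_nti",
    "raup_crick_bray",
    "classify_processes",
    "partition_processes",
    "process_chisq",
    "deterministic_odds_ratio",
    "compute_turnover",
]

PROCESS_CATEGORIES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


# ---------------------------------------------------------------------------
# Tree handling
# ---------------------------------------------------------------------------

def _as_tree(tree) -> TreeNode:
    if isinstance(tree, TreeNode):
        return tree
    # keep underscores literal: ASV ids are identifiers, not Newick spaces
    return TreeNode.read(io.StringIO(str(tree)), convert_underscores=False)


def patristic_matrix(tree, asv_ids: list[str]) -> np.ndarray:
    """Tip-to-tip patristic distances for ``asv_ids``, in that order."""
    t = _as_tree(tree)
    tips = {tip.name for tip in t.tips()}
    missing = [a for a in asv_ids if a not in tips]
    if missing:
        raise ValueError(f"ASVs missing from tree: {missing[:5]}")
    dm = t.tip_tip_distances(endpoints=list(asv_ids))
    order = [dm.index(a) for a in asv_ids]
    return np.asarray(dm.data)[np.ix_(order, order)]


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------

def _prepare(table: CountTable, pairs):
    samples = sorted({s for p in pairs for s in p})
    sub = table.data.loc[samples]
    present_any = sub.to_numpy().sum(axis=0) > 0
    asvs = list(sub.columns[present_any])
    counts = sub[asvs].to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = samples[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} is empty")
    F = counts / totals[:, None]
    present = [np.where(counts[i] > 0)[0] for i in range(len(samples))]
    return samples, asvs, F, present


def _bmntd_matrix(D: np.ndarray, F: np.ndarray, present, weighted: bool) -> np.ndarray:
    """Pairwise betaMNTD between all rows of F under distance matrix D."""
    S, A = F.shape
    G = np.empty((S, A))
    for m in range(S):
        G[m] = D[:, present[m]].min(axis=1)
    if weighted:
        W = F
    else:
        W = np.zeros_like(F)
        for i in range(S):
            W[i, present[i]] = 1.0 / len(present[i])
    half = W @ G.T
    return 0.5 * (half + half.T)


def beta_mntd(table: CountTable, tree, pairs, weighted: bool = True) -> pd.Series:
    """Observed betaMNTD per sample pair.

    betaMNTD(k, m) = 0.5 [ sum_i f_ik min_j d_ij + sum_j f_jm min_i d_ij ]
    with f the relative abundances (weighted) or 1/S (unweighted), minima
    taken over taxa present in the partner community.
    """
    pairs = list(pairs)
    samples, asvs, F, present = _prepare(table, pairs)
    D = patristic_matrix(tree, asvs)
    B = _bmntd_matrix(D, F, present, weighted)
    pos = {s: i for i, s in enumerate(samples)}
    return pd.Series(
        [B[pos[a], pos[b]] for a, b in pairs],
        index=pd.MultiIndex.from_tuples(pairs, names=["sample_i", "sample_j"]),
        name="beta_mntd",
    )


def beta_nti(
    table: CountTable,
    tree,
    pairs,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """betaNTI per pair: (observed - null mean) / null SD of betaMNTD.

    The null re-assigns taxa to tree tips by a uniform permutation across
    the whole tree, independently per replicate.  Pairs whose null SD is
    zero get a missing betaNTI (counted in the log).
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    pairs = list(pairs)
    samples, asvs, F, present = _prepare(table, pairs)
    tree = _as_tree(tree)
    tip_ids = [tip.name for tip in tree.tips()]
    D_full = patristic_matrix(tree, tip_ids)
    tip_pos = {t: i for i, t in enumerate(tip_ids)}
    asv_tip = np.array([tip_pos[a] for a in asvs])
    n_tips = len(tip_ids)

    obs = _bmntd_matrix(D_full[np.ix_(asv_tip, asv_tip)], F, present, weighted)
    rng = substream(seed, "beta-nti")
    total = np.zeros_like(obs)
    total_sq = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_tips)
        rowsel = perm[asv_tip]
        B = _bmntd_matrix(D_full[rowsel][:, rowsel], F, present, weighted)
        total += B
        total_sq += B * B
    mean = total / n_null
    var = total_sq / n_null - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))

    pos = {s: i for i, s in enumerate(samples)}
    rows = []
    n_undefined = 0
    for a, b in pairs:
        i, j = pos[a], pos[b]
        if sd[i, j] > 1e-12:
            nti = (obs[i, j] - mean[i, j]) / sd[i, j]
        elif abs(obs[i, j] - mean[i, j]) <= 1e-9:
            # shuffling was a no-op (e.g. a star tree): no deviation at all
            nti = 0.0
        else:
            nti = np.nan
            n_undefined += 1
        rows.append(
            {"beta_mntd_obs": obs[i, j], "null_mean": mean[i, j],
             "null_sd": sd[i, j], "beta_nti": nti}
        )
    if n_undefined:
        logger.warning("beta_nti: %d pairs with zero null SD (missing)", n_undefined)
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(pairs, names=["sample_i", "sample_j"])
    )


# ---------------------------------------------------------------------------
# RC-Bray
# ---------------------------------------------------------------------------

def _weighted_sample_without_replacement(
    weights: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    # exponential-race (Gumbel top-k) weighted sampling without replacement
    keys = rng.exponential(size=weights.size) / weights
    return np.argpartition(keys, size - 1)[:size]


def raup_crick_bray(
    table: CountTable,
    pairs,
    n_null: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Raup-Crick index on Bray-Curtis per pair, in [-1, 1].

    The metacommunity is all samples of ``table``.  Per replicate, every
    involved community is reassembled preserving its observed richness and
    total reads: species are drawn without replacement weighted by
    occupancy (each drawn species receives one read), and the remaining
    reads are assigned multinomially by metacommunity relative abundance
    over the drawn species.  RC = ((#null < obs) + 0.5 #ties) / n_null,
    rescaled to (RC - 0.5) * 2.
    """
    pairs = list(pairs)
    counts_all = table.data.to_numpy(dtype=float)
    occupancy = (counts_all > 0).sum(axis=0).astype(float)
    gamma = counts_all.sum(axis=0)
    pool = occupancy > 0
    occ_w = occupancy[pool]
    gamma_w = gamma[pool] / gamma[pool].sum()

    samples = sorted({s for p in pairs for s in p})
    pos = {s: i for i, s in enumerate(samples)}
    sub = table.data.loc[samples].to_numpy(dtype=float)[:, pool]
    richness = (sub > 0).sum(axis=1)
    reads = sub.sum(axis=1).astype(int)
    if (reads == 0).any():
        bad = samples[int(np.argmax(reads == 0))]
        raise ValueError(f"sample {bad!r} is empty")
    if (richness > pool.sum()).any():
        raise ValueError("sample richer than metacommunity pool")

    obs_bc = squareform(pdist(sub, metric="braycurtis"))
    idx_i = np.array([pos[a] for a, _ in pairs])
    idx_j = np.array([pos[b] for _, b in pairs])
    obs = obs_bc[idx_i, idx_j]

    rng = substream(seed, "rc-bray")
    less = np.zeros(len(pairs))
    ties = np.zeros(len(pairs))
    S, A = sub.shape
    null = np.zeros((S, A))
    for _ in range(n_null):
        null[:] = 0.0
        for s in range(S):
            chosen = _weighted_sample_without_replacement(occ_w, int(richness[s]), rng)
            null[s, chosen] = 1.0
            extra = int(reads[s] - richness[s])
            if extra > 0:
                p = gamma_w[chosen]
                null[s, chosen] += rng.multinomial(extra, p / p.sum())
        null_bc = squareform(pdist(null, metric="braycurtis"))[idx_i, idx_j]
        less += null_bc < obs - 1e-12
        ties += np.abs(null_bc - obs) <= 1e-12
    rc01 = (less + 0.5 * ties) / n_null
    rc = (rc01 - 0.5) * 2.0
    return pd.DataFrame(
        {"bray_curtis_obs": obs, "rc_bray": rc},
        index=pd.MultiIndex.from_tuples(pairs, names=["sample_i", "sample_j"]),
    )


# ---------------------------------------------------------------------------
# Process partitioning
# ---------------------------------------------------------------------------

def classify_processes(
    beta_nti_values,
    rc_values,
    bnti_threshold: float = BNTI_THRESHOLD,
    rc_threshold: float = RC_THRESHOLD,
) -> np.ndarray:
    """Five-way assembly-process category per pair (object array).

    Selection outranks dispersal: |betaNTI| > threshold decides first;
    only stochastic pairs consult RC.  Pairs with a missing value in the
    statistic they need are labelled ``"undefined"``.
    """
    b = np.asarray(beta_nti_values, dtype=float)
    r = np.asarray(rc_values, dtype=float)
    out = np.full(b.shape, "undefined", dtype=object)
    out[b > bnti_threshold] = "variable_selection"
    out[b < -bnti_threshold] = "homogeneous_selection"
    stochastic = np.abs(b) <= bnti_threshold
    out[stochastic & (r > rc_threshold)] = "dispersal_limitation"
    out[stochastic & (r < -rc_threshold)] = "homogenizing_dispersal"
    out[stochastic & (np.abs(r) <= rc_threshold)] = "drift"
    return out


@dataclass
class ProcessPartition:
    """Per-group counts and fractions of the five assembly processes."""

    counts: pd.DataFrame     # group x category (integer pair counts)
    fractions: pd.DataFrame  # rows sum to 1 over defined pairs
    n_missing: pd.Series
    thresholds: dict = field(
        default_factory=lambda: {"beta_nti": BNTI_THRESHOLD, "rc_bray": RC_THRESHOLD}
    )


def partition_processes(
    turnover: pd.DataFrame,
    group_col: str | None = "site",
    bnti_threshold: float = BNTI_THRESHOLD,
    rc_threshold: float = RC_THRESHOLD,
) -> ProcessPartition:
    """Partition pairs into the five processes, per group.

    ``turnover`` must have ``beta_nti`` and ``rc_bray`` columns and,
    unless ``group_col`` is None, a grouping column.  Fractions are over
    classified pairs; missing-value pairs are counted separately.
    """
    df = turnover.copy()
    df["process"] = classify_processes(
        df["beta_nti"], df["rc_bray"], bnti_threshold, rc_threshold
    )
    if group_col is None:
        df["_group"] = "all"
        group_col = "_group"
    counts = (
        df[df["process"] != "undefined"]
        .groupby(group_col)["process"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(PROCESS_CATEGORIES), fill_value=0)
    )
    n_missing = (
        df[df["process"] == "undefined"].groupby(group_col).size()
        .reindex(counts.index, fill_value=0)
    )
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return ProcessPartition(
        counts=counts.astype(int),
        fractions=fractions,
        n_missing=n_missing,
        thresholds={"beta_nti": bnti_threshold, "rc_bray": rc_threshold},
    )


def process_chisq(partition: ProcessPartition) -> pd.DataFrame:
    """Chi-square contrasts of process counts across groups.

    One row per process (that process vs all others, groups x 2 table,
    no continuity correction) plus an ``overall`` row for the full
    group x category table.  Low expected counts are logged.
    """
    counts = partition.counts
    rows = []

    def _test(tab: np.ndarray, name: str):
        tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            return {"contrast": name, "chi2": np.nan, "p_value": np.nan, "dof": 0}
        chi2, p, dof, expected = chi2_contingency(tab, correction=False)
        if (expected < 5).any():
            logger.warning("process_chisq: %s has expected cell < 5", name)
        return {"contrast": name, "chi2": float(chi2), "p_value": float(p), "dof": int(dof)}

    rows.append(_test(counts.to_numpy(), "overall"))
    total = counts.sum(axis=1).to_numpy()
    for cat in PROCESS_CATEGORIES:
        col = counts[cat].to_numpy()
        rows.append(_test(np.column_stack([col, total - col]), cat))
    return pd.DataFrame(rows).set_index("contrast")


# ---------------------------------------------------------------------------
# State contribution to deterministic turnover
# ---------------------------------------------------------------------------

def deterministic_odds_ratio(
    turnover: pd.DataFrame,
    labels: pd.Series,
    site: str | None = None,
    bnti_threshold: float = BNTI_THRESHOLD,
    within_state_only: bool = False,
) -> pd.DataFrame:
    """Odds of deterministic turnover for pairs involving each state.

    Per state X, a 2x2 table of {pair involves X (at either endpoint, or
    both when ``within_state_only``), or not} x {deterministic |betaNTI|
    > threshold, or not}.  OR = ad/bc with a Haldane 0.5 correction when
    any cell is zero; 95% CI on the log scale; significant when the lower
    bound exceeds 1.
    """
    df = turnover
    if site is not None:
        df = df[df["site"] == site]
    df = df[df["beta_nti"].notna()]
    if df.empty:
        raise ValueError(f"no defined betaNTI pairs for site {site!r}")
    si = df.index.get_level_values("sample_i") if "sample_i" in (df.index.names or []) else df["sample_i"]
    sj = df.index.get_level_values("sample_j") if "sample_j" in (df.index.names or []) else df["sample_j"]
    state_i = labels.reindex(si).to_numpy()
    state_j = labels.reindex(sj).to_numpy()
    deterministic = (df["beta_nti"].abs() > bnti_threshold).to_numpy()

    rows = []
    states = sorted(set(state_i) | set(state_j))
    for state in states:
        if within_state_only:
            involves = (state_i == state) & (state_j == state)
        else:
            involves = (state_i == state) | (state_j == state)
        if not involves.any():
            logger.info("deterministic_odds_ratio: state %s absent; skipped", state)
            continue
        a = int((involves & deterministic).sum())
        b = int((involves & ~deterministic).sum())
        c = int((~involves & deterministic).sum())
        d = int((~involves & ~deterministic).sum())
        corrected = 0 in (a, b, c, d)
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
        odds = (aa * dd) / (bb * cc)
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        ci_low = float(np.exp(np.log(odds) - 1.96 * se))
        ci_high = float(np.exp(np.log(odds) + 1.96 * se))
        rows.append(
            {
                "state": state, "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": float(odds), "ci_low": ci_low, "ci_high": ci_high,
                "significant": ci_low > 1.0, "haldane_corrected": corrected,
            }
        )
    return pd.DataFrame(rows).set_index("state")


# ---------------------------------------------------------------------------
# Orchestration over body sites
# ---------------------------------------------------------------------------

def same_site_pairs(meta: pd.DataFrame, sample_ids, site: str) -> list[tuple[str, str]]:
    ids = [
        s for s in sample_ids
        if s in set(meta.loc[meta["body_site"] == site, "sample_id"])
    ]
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


def compute_turnover(
    table: CountTable,
    meta: pd.DataFrame,
    tree,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
    sites: list[str] | None = None,
) -> pd.DataFrame:
    """betaMNTD/betaNTI and RC-Bray for all within-site pairs.

    Returns a long table with one row per same-site sample pair.  The
    RC-Bray metacommunity is the set of samples at that body site.
    """
    if sites is None:
        sites = sorted(meta["body_site"].unique())
    out = []
    for site in sites:
        pairs = same_site_pairs(meta, table.sample_ids, site)
        if not pairs:
            logger.warning("compute_turnover: no pairs at site %s", site)
            continue
        site_samples = sorted({s for p in pairs for s in p})
        nti = beta_nti(table, tree, pairs, n_null=n_null, seed=seed, weighted=weighted)
        rc = raup_crick_bray(table.select_samples(site_samples), pairs,
                             n_null=n_null, seed=seed)
        df = nti.join(rc)
        df["site"] = site
        out.append(df.reset_index())
    return pd.concat(out, ignore_index=True)
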