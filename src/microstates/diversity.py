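"""Alpha/beta diversity, ordination, and permutation association tests.

Shannon diversity is reported in nats by default (a ``base`` argument is
provided).  Beta diversity is Bray-Curtis.  PERMANOVA and the ordination
vector/factor fit support permutations restricted to blocks — here,
patients — so that repeated measures from one infant are never shuffled
across infants.  P-values follow the +1 convention (observed statistic
counted in both numerator and denominator), so the smallest attainable
p is 1 / (n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from ._rng import substream
from .tables import CountTable

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "OrdinationResult",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "permanova",
    "envfit",
    "cohens_d",
    "dissimilarity_contrasts",
]


# ---------------------------------------------------------------------------
# Alpha and beta diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: CountTable, base: float | None = None) -> pd.DataFrame:
    """Per-sample richness, Shannon index, and Pielou evenness.

    Shannon H = -sum p_i log p_i over non-zero p_i (natural log unless
    ``base`` is given); evenness J = H / log S, missing when S = 1.
    """
    counts = table.data.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = table.data.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} is empty")
    if len(set(totals)) > 1:
        logger.warning("alpha_diversity: unequal library sizes; rarefy first?")
    richness = (counts > 0).sum(axis=1)
    shannon = np.array([entropy(row[row > 0], base=base) for row in counts])
    log = np.log if base is None else (lambda x: np.log(x) / np.log(base))
    with np.errstate(divide="ignore", invalid="ignore"):
        evenness = np.where(richness > 1, shannon / log(richness), np.nan)
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon, "evenness": evenness},
        index=table.data.index,
    )


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples."""
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    counts = table.data.to_numpy(dtype=float)
    if (counts.sum(axis=1) == 0).any():
        bad = table.data.index[counts.sum(axis=1) == 0][0]
        raise ValueError(f"sample {bad!r} has zero total; Bray-Curtis undefined")
    condensed = pdist(counts, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Principal-coordinates embedding restricted to positive axes."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """PCoA (Gower double-centering); negative-eigenvalue axes dropped."""
    import warnings

    with warnings.catch_warnings():
        # skbio warns about computing all axes and about the negative
        # eigenvalues that semimetric dissimilarities always produce;
        # negative axes are dropped below by design.
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(d, method="eigh")
    eig = res.eigvals.to_numpy()
    tol = max(1e-10, 1e-10 * abs(eig).max())
    keep = eig > tol
    coords = res.samples.loc[:, keep.tolist()].copy()
    coords.index = pd.Index(d.ids)
    coords.columns = [f"PC{i + 1}" for i in range(keep.sum())]
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=eig[keep],
        proportion_explained=res.proportion_explained.to_numpy()[keep],
    )


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    statistic_name: str
    r2: float
    pseudo_f: float | None
    p_value: float
    n_perm: int
    blocked_by: str | None = None


def _as_blocks(blocks, n: int) -> np.ndarray | None:
    if blocks is None:
        return None
    blocks = np.asarray(blocks)
    if blocks.shape != (n,):
        raise ValueError("blocks must align with samples")
    return blocks


def permuted_indices(
    n: int, blocks: np.ndarray | None, rng: np.random.Generator
) -> np.ndarray:
    """A permutation of range(n); with blocks, shuffle only within blocks."""
    if blocks is None:
        return rng.permutation(n)
    out = np.arange(n)
    for b in pd.unique(blocks):
        members = np.where(blocks == b)[0]
        out[members] = members[rng.permutation(len(members))]
    return out


def _permanova_ss(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = D2.shape[0]
    ss_total = D2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        members = np.where(codes == g)[0]
        ss_within += D2[np.ix_(members, members)].sum() / (2 * len(members))
    return ss_total, ss_within


def permanova(
    d: DistanceMatrix,
    groups,
    blocks=None,
    n_perm: int = 1000,
    seed: int = 0,
) -> AssociationResult:
    """Single-factor PERMANOVA on a distance matrix.

    pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)); r2 is the fraction
    of total sum of squares between groups.  Group labels are permuted,
    within blocks when ``blocks`` is given.
    """
    ids = list(d.ids)
    n = len(ids)
    groups = np.asarray(pd.Series(groups).reindex(ids) if isinstance(groups, pd.Series) else groups)
    if groups.shape != (n,):
        raise ValueError("groups must align with the distance matrix")
    codes, uniques = pd.factorize(groups)
    a = len(uniques)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = uniques[np.argmin(counts)]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    blocks = _as_blocks(blocks, n)

    D2 = np.asarray(d.data, dtype=float) ** 2
    ss_total, ss_within = _permanova_ss(D2, codes, a)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total

    rng = substream(seed, "permanova")
    n_ge = 0
    for _ in range(n_perm):
        perm = permuted_indices(n, blocks, rng)
        _, ssw = _permanova_ss(D2, codes[perm], a)
        f_perm = ((ss_total - ssw) / (a - 1)) / (ssw / (n - a))
        if f_perm >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return AssociationResult("PERMANOVA", float(r2), float(f_obs), p, n_perm,
                             None if blocks is None else "blocks")


def _envfit_r2(coords: np.ndarray, variable: np.ndarray, is_factor: bool) -> float:
    if is_factor:
        codes, _ = pd.factorize(variable)
        center = coords.mean(axis=0)
        ss_total = ((coords - center) ** 2).sum()
        ss_within = 0.0
        for g in np.unique(codes):
            sub = coords[codes == g]
            ss_within += ((sub - sub.mean(axis=0)) ** 2).sum()
        return 1.0 - ss_within / ss_total
    # continuous: squared multiple correlation of the variable with the axes
    y = variable.astype(float)
    X = np.column_stack([np.ones(len(y)), coords])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_total = ((y - y.mean()) ** 2).sum()
    if ss_total == 0:
        raise ValueError("constant variable")
    return 1.0 - (resid ** 2).sum() / ss_total


def envfit(
    ordination: OrdinationResult,
    variable,
    blocks=None,
    n_perm: int = 1000,
    seed: int = 0,
    n_axes: int = 2,
) -> AssociationResult:
    """Fit one variable (continuous vector or factor) to ordination axes.

    Continuous: r2 is the squared multiple correlation of the variable
    with the first ``n_axes`` coordinates.  Factor: r2 = 1 - SS_within /
    SS_total of the coordinates by level.  Significance by permuting the
    variable (within blocks when given).
    """
    coords = ordination.coordinates.to_numpy()[:, : n_axes]
    variable = np.asarray(
        pd.Series(variable).reindex(ordination.coordinates.index)
        if isinstance(variable, pd.Series)
        else variable
    )
    n = coords.shape[0]
    if variable.shape != (n,):
        raise ValueError("variable must align with samples")
    is_factor = not np.issubdtype(variable.dtype, np.number)
    if len(pd.unique(variable)) < 2:
        raise ValueError("constant variable")
    blocks = _as_blocks(blocks, n)

    r2_obs = _envfit_r2(coords, variable, is_factor)
    rng = substream(seed, "envfit")
    n_ge = 0
    for _ in range(n_perm):
        perm = permuted_indices(n, blocks, rng)
        if _envfit_r2(coords, variable[perm], is_factor) >= r2_obs:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return AssociationResult("envfit", float(r2_obs), None, p, n_perm,
                             None if blocks is None else "blocks")


# ---------------------------------------------------------------------------
# Effect sizes and per-patient contrasts
# ---------------------------------------------------------------------------

def cohens_d(x, y) -> float:
    """Cohen's d with the pooled (n-1 weighted) standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    nx, ny = len(x), len(y)
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def dissimilarity_contrasts(
    d: DistanceMatrix, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within- vs between-site dissimilarity, and founder-distance series.

    Returns two long tables.  The first lists every unordered within-patient
    sample pair with its contrast class (same body site or across sites)
    and distance.  The second gives, per patient-site series, each
    sample's distance to that series' founder (the sample at the earliest
    occasion).  Patients with a single sample are excluded (logged).
    """
    ids = list(d.ids)
    meta_idx = meta.set_index("sample_id").loc[ids]
    dmat = pd.DataFrame(np.asarray(d.data), index=ids, columns=ids)

    pair_rows = []
    for patient, grp in meta_idx.groupby("patient_id"):
        samples = list(grp.index)
        if len(samples) < 2:
            logger.info("dissimilarity_contrasts: patient %s has one sample", patient)
            continue
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                si, sj = samples[i], samples[j]
                same = meta_idx.loc[si, "body_site"] == meta_idx.loc[sj, "body_site"]
                pair_rows.append(
                    {
                        "patient_id": patient,
                        "sample_i": si,
                        "sample_j": sj,
                        "contrast": "within_site" if same else "between_site",
                        "distance": float(dmat.loc[si, sj]),
                    }
                )
    pairs = pd.DataFrame(
        pair_rows,
        columns=["patient_id", "sample_i", "sample_j", "contrast", "distance"],
    )

    founder_rows = []
    for (patient, site), grp in meta_idx.groupby(["patient_id", "body_site"]):
        grp = grp.sort_values("time_index")
        founder = grp.index[0]
        for sample_id, row in grp.iterrows():
            founder_rows.append(
                {
                    "patient_id": patient,
                    "body_site": site,
                    "sample_id": sample_id,
                    "time_index": int(row["time_index"]),
                    "elapsed_occasions": int(row["time_index"] - grp["time_index"].iloc[0]),
                    "distance_to_founder": float(dmat.loc[founder, sample_id]),
                }
            )
    founders = pd.DataFrame(
        founder_rows,
        columns=[
            "patient_id", "body_site", "sample_id", "time_index",
            "elapsed_occasions", "distance_to_founder",
        ],
    )
    return pairs, founders
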