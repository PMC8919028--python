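"""Synthetic longitudinal multi-site cohort generator.

Emulates a neonatal intensive-care cohort profiled by 16S amplicon
sequencing: a handful of extremely-low-birthweight infants, each sampled
at gut, oral cavity, and skin over a few occasions in the first two weeks
of life.  Communities are low-diversity and organised into four latent
community states — three mono-dominated by a *Staphylococcus*, an
*Escherichia/Shigella*, and a *Lactobacillus* ASV (SC, EC, LC) and one
higher-evenness mixed state (IC).  Per body site, the latent state follows
a first-order Markov chain over sampling occasions; counts are
Dirichlet-multinomial draws from state-specific composition profiles.

Every generated cohort ships with its ground truth (states, transition
matrices, stationary frequencies, tree, planted correlations, negative
controls) so each downstream stage can be validated against a known
answer.  The observational study this emulates provides no generative
model; all distributional choices here are explicit stand-ins.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._rng import substream
from .tables import CountTable

__all__ = [
    "StateProfile",
    "TreeParams",
    "LibrarySizeModel",
    "ContaminantSpec",
    "PlantedEdge",
    "SynthConfig",
    "SyntheticTruth",
    "simulate_state_sequences",
    "sample_counts",
    "simulate_tree",
    "generate_cohort",
    "default_state_profiles",
    "default_transition_matrices",
]

DOMINANT_ASVS = {
    "ASV_1": "Escherichia-Shigella",
    "ASV_2": "Lactobacillus",
    "ASV_3": "Staphylococcus",
}

#: genera used for the low-abundance tail, typical of NICU skin/oral/gut
#: communities in the first weeks of life
TAIL_GENERA = [
    "Enterococcus", "Klebsiella", "Streptococcus", "Corynebacterium",
    "Acinetobacter", "Enterobacter", "Serratia", "Veillonella", "Rothia",
    "Cutibacterium", "Bacteroides", "Clostridium", "Haemophilus",
    "Neisseria", "Prevotella", "Micrococcus", "Gemella", "Finegoldia",
]


def _taxonomy_string(genus: str) -> str:
    return (
        "d__Bacteria;p__;c__;o__;f__;g__" + genus + ";s__"
    )


@dataclass
class StateProfile:
    """Dirichlet composition profile of one community state.

    ``dominant_mean`` is the expected relative abundance of the dominant
    ASV (``None`` for the even, mixed state, in which case all three
    dominant ASVs share ``dominant_mean`` each).  ``other_dominants`` is
    the total mass spread over the non-dominant named ASVs; the remaining
    mass goes to the tail.  ``concentration`` scales the Dirichlet
    (larger = tighter around the mean).
    """

    name: str
    dominant_asv: str | None
    dominant_mean: float
    other_dominants: float
    concentration: float


def default_state_profiles() -> dict[str, StateProfile]:
    return {
        "SC": StateProfile("SC", "ASV_3", 0.61, 0.15, 40.0),
        "EC": StateProfile("EC", "ASV_1", 0.60, 0.18, 40.0),
        "LC": StateProfile("LC", "ASV_2", 0.91, 0.05, 60.0),
        "IC": StateProfile("IC", None, 0.20, 0.0, 60.0),
    }


def default_transition_matrices() -> dict[str, pd.DataFrame]:
    """Per-site latent transition matrices, states ordered [SC, EC, LC, IC].

    Calibrated to the dynamics the framework is meant to recover: the gut
    is the most stable site (mean self-transition 0.625) with the
    Staphylococcus state equally likely to move anywhere; the oral cavity
    keeps SC stable while LC appears only sporadically and leaves to EC or
    IC; the skin is volatile (mean self-transition 0.225) with a strong
    pull toward SC, whose stationary frequency is about two-thirds.
    """
    states = ["SC", "EC", "LC", "IC"]

    def m(rows):
        return pd.DataFrame(rows, index=states, columns=states, dtype=float)

    return {
        "gut": m([[0.25, 0.25, 0.25, 0.25],
                  [0.10, 0.75, 0.05, 0.10],
                  [0.10, 0.05, 0.75, 0.10],
                  [0.10, 0.10, 0.05, 0.75]]),
        "oral": m([[0.60, 0.15, 0.05, 0.20],
                   [0.20, 0.50, 0.05, 0.25],
                   [0.00, 0.50, 0.00, 0.50],
                   [0.40, 0.15, 0.05, 0.40]]),
        "skin": m([[0.65, 0.15, 0.05, 0.15],
                   [0.70, 0.10, 0.05, 0.15],
                   [0.70, 0.15, 0.05, 0.10],
                   [0.70, 0.15, 0.05, 0.10]]),
    }


@dataclass
class TreeParams:
    """Birth–death parameters and habitat-signal strength for the ASV tree.

    ``habitat_signal`` in [0, 1] blends a tree-independent shared tail
    profile (0) with state-specific tail mass concentrated on contiguous
    clades (1).  At 0, tip labels are exchangeable with respect to
    abundance, which is the regime in which the tip-shuffling null model
    downstream is exactly calibrated.
    """

    birth_rate: float = 1.0
    death_rate: float = 0.5
    habitat_signal: float = 0.5


@dataclass
class LibrarySizeModel:
    """Negative-binomial library sizes, truncated at ``minimum`` by default.

    With ``allow_sub_minimum=True``, raw draws are kept so that samples
    below the rarefaction depth occur and the drop path can be exercised.
    """

    mean: float = 3000.0
    dispersion: float = 5.0
    minimum: int = 600
    allow_sub_minimum: bool = False


@dataclass
class ContaminantSpec:
    """One reagent-borne contaminant genus.

    ``control_rate`` is the Poisson mean of its reads per negative-control
    library; ``sample_rate`` the mean injected into every real sample.
    Genera sharing a ``latent_group`` are driven by a common lognormal
    per-sample intensity and therefore co-vary strongly — this is what the
    correlation-removal rule is meant to catch.
    """

    genus: str
    control_rate: float
    sample_rate: float
    latent_group: str = "reagent"


def default_contaminants() -> list[ContaminantSpec]:
    return [
        ContaminantSpec("Ralstonia", 40.0, 8.0, "reagentA"),
        ContaminantSpec("Burkholderia", 2.0, 6.0, "reagentA"),
        ContaminantSpec("Sphingomonas", 25.0, 3.0, "reagentB"),
    ]


@dataclass
class PlantedEdge:
    """A pair of tail ASVs with a planted monotone abundance coupling."""

    asv_a: str
    asv_b: str
    strength: float = 1.0


@dataclass
class SynthConfig:
    n_patients: int = 15
    body_sites: tuple[str, ...] = ("gut", "oral", "skin")
    time_indices: tuple[int, ...] = (1, 2, 3, 4)
    nominal_days: tuple[int, ...] = (1, 3, 7, 14)
    n_asvs: int = 300
    state_profiles: dict[str, StateProfile] = field(default_factory=default_state_profiles)
    transition_matrices: dict[str, pd.DataFrame] = field(
        default_factory=default_transition_matrices
    )
    initial_distribution: dict[str, np.ndarray] | None = None
    library_size: LibrarySizeModel = field(default_factory=LibrarySizeModel)
    tree_params: TreeParams = field(default_factory=TreeParams)
    contamination: list[ContaminantSpec] = field(default_factory=default_contaminants)
    planted_edges: list[PlantedEdge] = field(default_factory=list)
    n_negative_controls: int = 2
    seed: int = 0

    @property
    def states(self) -> list[str]:
        return list(self.state_profiles)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_asvs < len(DOMINANT_ASVS):
            raise ValueError(
                f"n_asvs must be >= {len(DOMINANT_ASVS)} (the dominant ASVs)"
            )
        if len(self.time_indices) != len(self.nominal_days):
            raise ValueError("time_indices and nominal_days must align")
        states = self.states
        for site in self.body_sites:
            if site not in self.transition_matrices:
                raise ValueError(f"no transition matrix for body site {site!r}")
            P = self.transition_matrices[site]
            if list(P.index) != states or list(P.columns) != states:
                raise ValueError(f"transition matrix for {site!r} not indexed by states")
            _check_stochastic(P.to_numpy())
        if self.initial_distribution is not None:
            for site, pi0 in self.initial_distribution.items():
                pi0 = np.asarray(pi0, dtype=float)
                if pi0.min() < 0 or abs(pi0.sum() - 1.0) > 1e-9:
                    raise ValueError(f"initial distribution for {site!r} is not a simplex")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated cohort."""

    state_per_sample: pd.Series
    transition_matrices: dict[str, pd.DataFrame]
    stationary: dict[str, pd.Series]
    tree_newick: str
    planted_edges: list[PlantedEdge]
    negative_controls: pd.Series
    state_mean_profiles: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "state_per_sample": self.state_per_sample.to_dict(),
            "transition_matrices": {
                s: m.to_dict(orient="split") for s, m in self.transition_matrices.items()
            },
            "stationary": {s: v.to_dict() for s, v in self.stationary.items()},
            "tree_newick": self.tree_newick,
            "planted_edges": [
                {"asv_a": e.asv_a, "asv_b": e.asv_b, "strength": e.strength}
                for e in self.planted_edges
            ],
            "negative_controls": self.negative_controls.to_dict(),
        }


# ---------------------------------------------------------------------------
# Markov state sequences
# ---------------------------------------------------------------------------

def _check_stochastic(P: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {P.shape}")
    if (P < -tol).any():
        i, j = np.argwhere(P < -tol)[0]
        raise ValueError(f"negative transition probability at ({i}, {j})")
    rowsums = P.sum(axis=1)
    bad = np.where(np.abs(rowsums - 1.0) > 1e-8)[0]
    if bad.size:
        raise ValueError(
            f"transition matrix row {bad[0]} sums to {rowsums[bad[0]]!r}, not 1"
        )
    return P


def simulate_state_sequences(
    P,
    pi0,
    n_steps: int,
    n_series: int = 1,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Simulate ``n_series`` state-index sequences of length ``n_steps``.

    The first element of each sequence is drawn from ``pi0``; subsequent
    elements follow the row-stochastic matrix ``P``.
    """
    P = _check_stochastic(P)
    pi0 = np.asarray(pi0, dtype=float)
    if pi0.shape != (P.shape[0],) or pi0.min() < 0 or abs(pi0.sum() - 1.0) > 1e-9:
        raise ValueError("pi0 must be a simplex vector matching P")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if rng is None:
        rng = substream(seed, "state-sequences")
    k = P.shape[0]
    # row-wise inverse-CDF sampling, vectorised over series
    cum_P = np.cumsum(P, axis=1)
    cum_pi0 = np.cumsum(pi0)
    seqs = np.empty((n_series, n_steps), dtype=np.int64)
    u = rng.random(n_series)
    seqs[:, 0] = np.searchsorted(cum_pi0, u, side="right").clip(max=k - 1)
    for t in range(1, n_steps):
        u = rng.random(n_series)
        rows = cum_P[seqs[:, t - 1]]
        seqs[:, t] = (u[:, None] < rows).argmax(axis=1)
    return list(seqs)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def sample_counts(
    mean,
    concentration: float,
    library_size: int,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One Dirichlet-multinomial count vector.

    ``mean`` is a simplex of expected relative abundances; the Dirichlet
    parameter is ``concentration * mean`` (zero-mean taxa stay at zero).
    """
    mean = np.asarray(mean, dtype=float)
    if mean.size == 0:
        raise ValueError("state profile must be non-empty")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if mean.min() < 0 or abs(mean.sum() - 1.0) > 1e-9:
        raise ValueError("profile mean must be a simplex")
    if rng is None:
        rng = substream(seed, "sample-counts")
    p = np.zeros_like(mean)
    pos = mean > 0
    if pos.sum() == 1:
        p[pos] = 1.0
    else:
        p[pos] = rng.dirichlet(concentration * mean[pos])
    return rng.multinomial(library_size, p)


def neutral_metacommunity_counts(
    n_samples: int,
    pool_size: int = 100,
    richness: int = 40,
    library_size: int = 600,
    abundance_sigma: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Counts assembled under species equivalence (ecological neutrality).

    Every sample receives ``richness`` species drawn uniformly from the
    pool (equal fitness, no selection) and ``library_size`` reads
    allocated by one shared lognormal metacommunity abundance vector.
    This is the generative process the Raup-Crick null hypothesises, so
    turnover statistics computed on these data calibrate the null: drift
    alone should explain (nearly) every pairwise comparison.
    """
    if richness > pool_size:
        raise ValueError("richness cannot exceed pool size")
    rng = substream(seed, "neutral-metacommunity")
    abundance = rng.lognormal(0.0, abundance_sigma, pool_size)
    counts = np.zeros((n_samples, pool_size), dtype=np.int64)
    for s in range(n_samples):
        chosen = rng.choice(pool_size, size=richness, replace=False)
        counts[s, chosen] = 1
        p = abundance[chosen] / abundance[chosen].sum()
        counts[s, chosen] += rng.multinomial(library_size - richness, p)
    return counts


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def simulate_tree(
    n_taxa: int,
    tree_params: TreeParams | None = None,
    seed: int = 0,
    labels: list[str] | None = None,
) -> str:
    """Simulate a rooted birth–death tree and return its Newick string.

    Tip labels are the ASV ids (default ``ASV_1 .. ASV_n``), assigned to
    tips by a seed-determined random permutation so that, absent habitat
    signal, an ASV's abundance carries no information about its placement.
    """
    newick, _ = _simulate_tree_with_positions(n_taxa, tree_params, seed, labels)
    return newick


def _simulate_tree_with_positions(
    n_taxa: int,
    tree_params: TreeParams | None = None,
    seed: int = 0,
    labels: list[str] | None = None,
) -> tuple[str, dict[str, float]]:
    if n_taxa < 2:
        raise ValueError("a tree needs at least 2 taxa")
    params = tree_params or TreeParams()
    if labels is None:
        labels = [f"ASV_{i + 1}" for i in range(n_taxa)]
    if len(labels) != n_taxa or len(set(labels)) != n_taxa:
        raise ValueError("labels must be unique and match n_taxa")
    rng = substream(seed, "tree")
    py_rng = random.Random(int(rng.integers(0, 2**31 - 1)))
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=params.birth_rate,
        death_rate=params.death_rate,
        num_extant_tips=n_taxa,
        rng=py_rng,
        repeat_until_success=True,
    )
    leaves = list(tree.leaf_node_iter())  # stable left-to-right traversal order
    perm = rng.permutation(n_taxa)
    positions: dict[str, float] = {}
    denom = max(n_taxa - 1, 1)
    for tip_index, leaf in enumerate(leaves):
        asv = labels[perm[tip_index]]
        leaf.taxon.label = asv
        if leaf.edge.length is None or leaf.edge.length <= 0:
            leaf.edge.length = 1e-8
        positions[asv] = tip_index / denom
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return newick, positions


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _state_mean_profiles(
    config: SynthConfig, positions: dict[str, float]
) -> pd.DataFrame:
    """State x ASV matrix of Dirichlet means.

    The three dominant ASVs carry the state-defining mass; the remainder
    goes to a tail whose weights are, per state, a blend of a shared
    tree-independent decaying profile and (for habitat signal > 0) a
    Gaussian bump over a state-specific stretch of the tip order.
    """
    asv_ids = [f"ASV_{i + 1}" for i in range(config.n_asvs)]
    dominants = list(DOMINANT_ASVS)
    tail = [a for a in asv_ids if a not in dominants]
    rng = substream(config.seed, "tail-profile")
    # shared decaying tail weights, shuffled so rank is unrelated to id order
    shared = np.exp(-0.15 * np.arange(len(tail)))
    rng.shuffle(shared)
    shared /= shared.sum()
    signal = config.tree_params.habitat_signal
    pos = np.array([positions[a] for a in tail]) if tail else np.empty(0)

    rows = {}
    states = config.states
    for s_index, (name, prof) in enumerate(config.state_profiles.items()):
        mean = pd.Series(0.0, index=asv_ids)
        if prof.dominant_asv is None:
            for d in dominants:
                mean[d] = prof.dominant_mean
            tail_mass = 1.0 - prof.dominant_mean * len(dominants)
        else:
            mean[prof.dominant_asv] = prof.dominant_mean
            others = [d for d in dominants if d != prof.dominant_asv]
            for d in others:
                mean[d] = prof.other_dominants / len(others)
            tail_mass = 1.0 - prof.dominant_mean - prof.other_dominants
        if tail_mass < -1e-9:
            raise ValueError(f"state {name!r}: dominant means exceed 1")
        if tail:
            center = (s_index + 0.5) / len(states)
            bump = np.exp(-(((pos - center) / 0.12) ** 2))
            bump = bump / bump.sum() if bump.sum() > 0 else shared
            weights = (1.0 - signal) * shared + signal * bump
            mean[tail] = tail_mass * weights / weights.sum()
        rows[name] = mean
    profiles = pd.DataFrame(rows).T
    np.testing.assert_allclose(profiles.sum(axis=1), 1.0, atol=1e-9)
    return profiles


def _library_sizes(config: SynthConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    m = config.library_size
    shape = m.dispersion
    p = shape / (shape + m.mean)
    sizes = rng.negative_binomial(shape, p, size=n)
    if not m.allow_sub_minimum:
        low = sizes < m.minimum
        while low.any():
            sizes[low] = rng.negative_binomial(shape, p, size=int(low.sum()))
            low = sizes < m.minimum
    return np.maximum(sizes, 1)


def _clinical_covariates(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Plausible per-patient clinical metadata (flags with realistic cohort
    frequencies; cumulative exposures grow with day of life)."""
    n = config.n_patients
    return pd.DataFrame(
        {
            "gestational_age_weeks": np.round(rng.normal(24.67, 1.12, n), 1),
            "delivery_mode": np.where(rng.random(n) < 0.73, "cesarean", "vaginal"),
            "ventilation_rate": rng.uniform(0.2, 1.0, n),
            "oxygen_rate": rng.uniform(0.3, 1.0, n),
            "antibiotic_rate": rng.uniform(0.5, 2.0, n),
            "rop": rng.random(n) < 0.73,
            "ivh": rng.random(n) < 0.33,
            "bpd": rng.random(n) < 0.33,
        },
        index=[f"P{i + 1:02d}" for i in range(n)],
    )


def generate_cohort(config: SynthConfig) -> tuple[CountTable, pd.DataFrame, SyntheticTruth]:
    """Generate a cohort: count table, sample metadata, and ground truth.

    One sample per (patient, body site, occasion).  Identical configs
    (including seed) produce bit-identical outputs.
    """
    config.validate()
    from .markov import stationary_distribution  # local import avoids a cycle

    seed = config.seed
    states = config.states
    asv_ids = [f"ASV_{i + 1}" for i in range(config.n_asvs)]
    contaminant_ids = [f"ASV_C{i + 1}" for i in range(len(config.contamination))]

    # the tree spans every emitted ASV, contaminants included, so the
    # table stays analysable even if a contaminant slips past filtering
    newick, positions = _simulate_tree_with_positions(
        config.n_asvs + len(contaminant_ids),
        config.tree_params,
        seed=seed,
        labels=asv_ids + contaminant_ids,
    )
    profiles = _state_mean_profiles(config, positions)

    # latent state sequences per patient x site
    n_steps = len(config.time_indices)
    seq: dict[tuple[str, str], np.ndarray] = {}
    for site in config.body_sites:
        P = config.transition_matrices[site].to_numpy()
        if config.initial_distribution is not None:
            pi0 = np.asarray(config.initial_distribution[site], dtype=float)
        else:
            pi0 = np.full(len(states), 1.0 / len(states))
        rng_site = substream(seed, "states", site)
        series = simulate_state_sequences(P, pi0, n_steps, config.n_patients, rng=rng_site)
        for p_index in range(config.n_patients):
            seq[(f"P{p_index + 1:02d}", site)] = series[p_index]

    # counts
    rng_lib = substream(seed, "library")
    rng_counts = substream(seed, "counts")
    sample_ids, meta_rows, count_rows, truth_states = [], [], [], []
    n_samples = config.n_patients * len(config.body_sites) * len(config.time_indices)
    lib_sizes = _library_sizes(config, n_samples, rng_lib)
    covars = _clinical_covariates(config, substream(seed, "clinical"))

    i = 0
    for p_index in range(config.n_patients):
        patient = f"P{p_index + 1:02d}"
        for site in config.body_sites:
            for t_pos, t_index in enumerate(config.time_indices):
                state = states[seq[(patient, site)][t_pos]]
                prof = config.state_profiles[state]
                counts = sample_counts(
                    profiles.loc[state].to_numpy(),
                    prof.concentration,
                    int(lib_sizes[i]),
                    rng=rng_counts,
                )
                sample_id = f"{patient}_{site}_T{t_index}"
                day = config.nominal_days[t_pos]
                sample_ids.append(sample_id)
                count_rows.append(counts)
                truth_states.append(state)
                cv = covars.loc[patient]
                meta_rows.append(
                    {
                        "sample_id": sample_id,
                        "patient_id": patient,
                        "body_site": site,
                        "time_index": t_index,
                        "day_of_life": day,
                        "days_mechanical_ventilation": round(cv["ventilation_rate"] * day, 1),
                        "days_oxygen_support": round(cv["oxygen_rate"] * day, 1),
                        "antibiotics_index": round(cv["antibiotic_rate"] * day, 1),
                        "elevated_il6": bool(
                            substream(seed, "il6", patient, t_index).random() < 0.3
                        ),
                        "gestational_age_weeks": cv["gestational_age_weeks"],
                        "delivery_mode": cv["delivery_mode"],
                        "rop": bool(cv["rop"]),
                        "ivh": bool(cv["ivh"]),
                        "bpd": bool(cv["bpd"]),
                    }
                )
                i += 1

    data = pd.DataFrame(
        np.vstack(count_rows), index=pd.Index(sample_ids, name="sample_id"),
        columns=asv_ids, dtype=np.int64,
    )

    # planted monotone pairs overwrite the two tail ASVs they name
    rng_edges = substream(seed, "planted-edges")
    for edge in config.planted_edges:
        for asv in (edge.asv_a, edge.asv_b):
            if asv not in data.columns:
                raise ValueError(f"planted edge names unknown ASV {asv!r}")
            if asv in DOMINANT_ASVS:
                raise ValueError(f"planted edge may not use dominant ASV {asv!r}")
        u = rng_edges.random(len(data))
        jitter_a = rng_edges.poisson(1.0, len(data))
        jitter_b = rng_edges.poisson(1.0, len(data))
        scale = 100.0 * edge.strength
        data[edge.asv_a] = np.floor(10 + scale * u).astype(np.int64) + jitter_a
        data[edge.asv_b] = np.floor(8 + 0.9 * scale * u).astype(np.int64) + jitter_b

    # contamination: shared lognormal reagent intensity per (sample, group)
    rng_cont = substream(seed, "contamination")
    tax = {a: _taxonomy_string(g) for a, g in DOMINANT_ASVS.items()}
    for j, asv in enumerate(a for a in asv_ids if a not in DOMINANT_ASVS):
        tax[asv] = _taxonomy_string(TAIL_GENERA[j % len(TAIL_GENERA)])
    groups = sorted({c.latent_group for c in config.contamination})
    latents = {
        g: rng_cont.lognormal(mean=-0.72, sigma=1.2, size=len(data)) for g in groups
    }
    for c_index, spec in enumerate(config.contamination):
        asv = f"ASV_C{c_index + 1}"
        lam = spec.sample_rate * latents[spec.latent_group]
        data[asv] = rng_cont.poisson(lam).astype(np.int64)
        tax[asv] = _taxonomy_string(spec.genus)

    neg = pd.Series(
        {
            spec.genus: int(
                rng_cont.poisson(spec.control_rate, size=config.n_negative_controls).sum()
            )
            for spec in config.contamination
        },
        dtype=int,
    )

    taxonomy = pd.Series({a: tax[a] for a in data.columns})
    table = CountTable(data, taxonomy)
    meta = pd.DataFrame(meta_rows)

    stationary = {}
    for site in config.body_sites:
        P = config.transition_matrices[site]
        pis = stationary_distribution(P.to_numpy())
        if len(pis) == 1:
            stationary[site] = pd.Series(pis[0], index=states)
        else:  # reducible chain: report the extremal solutions stacked
            stationary[site] = pd.Series(np.mean(pis, axis=0), index=states)

    truth = SyntheticTruth(
        state_per_sample=pd.Series(truth_states, index=sample_ids, name="true_state"),
        transition_matrices={s: config.transition_matrices[s].copy() for s in config.body_sites},
        stationary=stationary,
        tree_newick=newick,
        planted_edges=list(config.planted_edges),
        negative_controls=neg,
        state_mean_profiles=profiles,
    )
    return table, meta, truth
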