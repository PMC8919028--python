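"""End-to-end orchestration: synthetic or user data through every stage.

Stages run in dependency order (io -> preprocess -> diversity -> states ->
markov / processes / networks); a stage failure halts its dependents but
independent stages continue, and the machine-readable run report is
written regardless.  Given the same config and seed, all tabular outputs
are byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as div
from . import markov as mk
from . import networks as nw
from . import processes as pr
from . import states as st
from . import synth
from . import tables as tb

logger = logging.getLogger(__name__)

STAGE_ORDER = ("io", "preprocess", "diversity", "states", "markov", "processes", "networks")
STAGE_DEPS = {
    "io": (),
    "preprocess": ("io",),
    "diversity": ("preprocess",),
    "states": ("diversity",),
    "markov": ("states",),
    "processes": ("preprocess", "states"),
    "networks": ("preprocess", "states"),
}


@dataclass
class PipelineConfig:
    # inputs: either synthetic=True (with synth_config) or explicit paths
    synthetic: bool = True
    synth_config: synth.SynthConfig | None = None
    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    neg_controls_path: str | None = None

    stages: tuple[str, ...] = STAGE_ORDER
    outdir: str = "microstates_out"
    seed: int = 0

    # preprocessing
    rarefaction_depth: int = 600
    read_threshold: int = 10
    r_threshold: float = 0.9
    reagent_list: tuple[str, ...] = ()
    exclude_asvs: tuple[str, ...] = ()

    # diversity / association
    n_perm: int = 1000

    # states
    k_range: tuple[int, ...] = tuple(range(2, 9))
    n_init: int = 100
    cluster_method: str = "kmeans"

    # markov
    smoothing: float = 0.0
    detection_threshold: int = 1

    # processes
    n_null: int = 999
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    weighted_bmntd: bool = True

    # networks
    min_prevalence: int = 2
    network_alpha: float = 0.01
    network_filter_on: str = "q"

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.synthetic:
            (self.synth_config or synth.SynthConfig(seed=self.seed)).validate()
        else:
            for name in ("counts_path", "metadata_path"):
                if getattr(self, name) is None:
                    raise ValueError(f"non-synthetic run requires {name}")
                if not Path(getattr(self, name)).exists():
                    raise FileNotFoundError(f"{name}: {getattr(self, name)}")
            if "processes" in self.stages:
                if self.tree_path is None:
                    raise ValueError("processes stage enabled but tree_path missing")
                if not Path(self.tree_path).exists():
                    raise FileNotFoundError(f"tree_path: {self.tree_path}")
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be positive")
        if self.n_null < 99:
            raise ValueError("n_null must be >= 99")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sc = d.pop("synth_config", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        if sc is not None:
            cfg.synth_config = synth.SynthConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in sc.items()
            })
        return cfg


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)   # relative path -> sha256
    warnings: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "outputs": self.outputs,
            "warnings": self.warnings,
            "parameters": self.parameters,
            "metrics": self.metrics,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


class _Runner:
    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.outdir)
        self.report = RunReport(parameters={
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
            if isinstance(v, (int, float, str, bool, tuple, type(None)))
        })
        self.state: dict = {}

    # ---- stages ----------------------------------------------------------
    def stage_io(self):
        cfg = self.cfg
        d = self.out / "io"
        d.mkdir(parents=True, exist_ok=True)
        if cfg.synthetic:
            sc = cfg.synth_config or synth.SynthConfig(seed=cfg.seed)
            table, meta, truth = synth.generate_cohort(sc)
            self.state.update(table=table, meta=meta, truth=truth,
                              tree=truth.tree_newick,
                              neg_controls=truth.negative_controls)
            (d / "tree.nwk").write_text(truth.tree_newick + "\n")
            with open(d / "truth.json", "w") as fh:
                json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        else:
            table = tb.read_count_table(cfg.counts_path, cfg.taxonomy_path)
            meta = tb.read_metadata(cfg.metadata_path)
            tb.validate_metadata(meta, table)
            tree = Path(cfg.tree_path).read_text().strip() if cfg.tree_path else None
            neg = (
                pd.read_csv(cfg.neg_controls_path, sep="\t", index_col=0).iloc[:, 0]
                if cfg.neg_controls_path else None
            )
            self.state.update(table=table, meta=meta, truth=None, tree=tree,
                              neg_controls=neg)
        tb.write_count_table(self.state["table"], d / "counts.tsv", d / "taxonomy.tsv")
        tb.write_metadata(self.state["meta"], d / "metadata.tsv")
        if self.state["neg_controls"] is not None:
            _write_tsv(self.state["neg_controls"].rename("reads").to_frame(),
                       d / "negative_controls.tsv")

    def stage_preprocess(self):
        cfg = self.cfg
        d = self.out / "preprocess"
        d.mkdir(parents=True, exist_ok=True)
        filtered, rep = tb.filter_contaminants(
            self.state["table"],
            neg_controls=self.state["neg_controls"],
            reagent_list=cfg.reagent_list,
            r_threshold=cfg.r_threshold,
            read_threshold=cfg.read_threshold,
            exclude_asvs=cfg.exclude_asvs,
        )
        with open(d / "contaminant_report.json", "w") as fh:
            json.dump(rep.to_dict(), fh, indent=1, sort_keys=True)
        rarefied = tb.rarefy(filtered, depth=cfg.rarefaction_depth, seed=cfg.seed)
        dropped = sorted(set(filtered.sample_ids) - set(rarefied.sample_ids))
        if dropped:
            self.report.warnings.append(
                f"preprocess: {len(dropped)} samples below depth dropped: {dropped[:5]}"
            )
        coverage = tb.goods_coverage(rarefied)
        tb.write_count_table(rarefied, d / "rarefied.tsv")
        _write_tsv(coverage.to_frame(), d / "coverage.tsv")
        meta = self.state["meta"]
        self.state.update(
            rarefied=rarefied,
            meta_r=meta[meta["sample_id"].isin(rarefied.sample_ids)].reset_index(drop=True),
        )
        self.report.metrics["n_samples_rarefied"] = int(rarefied.shape[0])
        self.report.metrics["goods_coverage_min"] = float(coverage.min())

    def stage_diversity(self):
        cfg = self.cfg
        d = self.out / "diversity"
        rarefied, meta = self.state["rarefied"], self.state["meta_r"]
        alpha = div.alpha_diversity(rarefied)
        _write_tsv(alpha, d / "alpha.tsv")
        bc = div.bray_curtis(rarefied)
        _write_tsv(pd.DataFrame(np.asarray(bc.data), index=bc.ids, columns=bc.ids),
                   d / "bray_curtis.tsv")
        ordination = div.pcoa(bc)
        _write_tsv(ordination.coordinates, d / "pcoa_coordinates.tsv")
        meta_idx = meta.set_index("sample_id").loc[list(bc.ids)]
        res = div.permanova(
            bc, meta_idx["body_site"], blocks=meta_idx["patient_id"].to_numpy(),
            n_perm=cfg.n_perm, seed=cfg.seed,
        )
        assoc = pd.DataFrame(
            [{"variable": "body_site", "statistic": res.statistic_name, "r2": res.r2,
              "pseudo_f": res.pseudo_f, "p_value": res.p_value, "n_perm": res.n_perm}]
        )
        _write_tsv(assoc, d / "associations.tsv", index=False)
        pairs, founders = div.dissimilarity_contrasts(bc, meta)
        _write_tsv(pairs, d / "dissimilarity_contrasts.tsv", index=False)
        _write_tsv(founders, d / "founder_distances.tsv", index=False)
        self.state.update(bc=bc, ordination=ordination)
        self.report.metrics["permanova_body_site_r2"] = res.r2
        self.report.metrics["permanova_body_site_p"] = res.p_value

    def stage_states(self):
        cfg = self.cfg
        d = self.out / "states"
        bc, rarefied = self.state["bc"], self.state["rarefied"]
        k, scores = st.select_k(bc, k_range=cfg.k_range, seed=cfg.seed,
                                n_init=cfg.n_init, table=rarefied,
                                method=cfg.cluster_method)
        assignment = st.assign_states(bc, k, seed=cfg.seed, n_init=cfg.n_init,
                                      table=rarefied, method=cfg.cluster_method)
        _write_tsv(scores, d / "k_scores.tsv")
        out = pd.DataFrame({"state": assignment.labels,
                            "silhouette": assignment.silhouette})
        out.index.name = "sample_id"
        _write_tsv(out, d / "assignment.tsv")
        rep = st.site_representation(assignment, self.state["meta_r"])
        _write_tsv(rep.percentages, d / "site_representation.tsv")
        _write_tsv(rep.deviation, d / "site_deviation.tsv")
        self.state["assignment"] = assignment
        self.report.metrics["chosen_k"] = k
        self.report.metrics["mean_silhouette"] = assignment.mean_silhouette
        truth = self.state.get("truth")
        if truth is not None:
            agreement = st.label_agreement(assignment.labels, truth.state_per_sample)
            self.report.metrics["state_recovery_agreement"] = agreement

    def stage_markov(self):
        cfg = self.cfg
        d = self.out / "markov"
        d.mkdir(parents=True, exist_ok=True)
        assignment, meta = self.state["assignment"], self.state["meta_r"]
        states = sorted(assignment.labels.unique())
        stabilities = {}
        for site in sorted(meta["body_site"].unique()):
            model = mk.estimate_transitions(
                assignment.labels, meta, site,
                smoothing=cfg.smoothing, states=states,
            )
            _write_tsv(model.counts, d / f"transition_counts_{site}.tsv")
            _write_tsv(model.probabilities, d / f"transition_probabilities_{site}.tsv")
            stat = pd.DataFrame({f"pi_{i}": pi for i, pi in enumerate(model.stationary)})
            _write_tsv(stat, d / f"stationary_{site}.tsv")
            _write_tsv(model.classification.rename("class").to_frame(),
                       d / f"classification_{site}.tsv")
            edges, stability = mk.transition_graph_summary(model)
            _write_tsv(edges, d / f"transition_edges_{site}.tsv", index=False)
            stabilities[site] = stability
            if model.uniform_rows:
                self.report.warnings.append(
                    f"markov/{site}: uniform rows for unobserved origins {model.uniform_rows}"
                )
        self.report.metrics["mean_self_transition"] = stabilities
        cd = mk.conditional_detection(
            self.state["rarefied"], meta, detection_threshold=cfg.detection_threshold
        )
        _write_tsv(cd.aggregate, d / "conditional_detection_aggregate.tsv")
        flat = cd.per_asv.copy()
        flat.columns = [f"{a}|{b}" for a, b in flat.columns]
        _write_tsv(flat, d / "conditional_detection_per_asv.tsv")
        if cd.per_infant is not None:
            _write_tsv(cd.per_infant, d / "conditional_detection_per_infant.tsv", index=False)
        self.report.metrics["bayes_identity_max_violation"] = mk.verify_bayes_identity(cd)
        self.state["conditional"] = cd

    def stage_processes(self):
        cfg = self.cfg
        d = self.out / "processes"
        tree = self.state.get("tree")
        if tree is None:
            raise ValueError("processes stage requires a phylogenetic tree")
        turnover = pr.compute_turnover(
            self.state["rarefied"], self.state["meta_r"], tree,
            n_null=cfg.n_null, seed=cfg.seed, weighted=cfg.weighted_bmntd,
        )
        _write_tsv(turnover, d / "turnover.tsv", index=False)
        partition = pr.partition_processes(
            turnover, group_col="site",
            bnti_threshold=cfg.bnti_threshold, rc_threshold=cfg.rc_threshold,
        )
        _write_tsv(partition.counts, d / "partition_counts.tsv")
        _write_tsv(partition.fractions, d / "partition_fractions.tsv")
        _write_tsv(pr.process_chisq(partition), d / "process_chisq.tsv")
        assignment = self.state.get("assignment")
        if assignment is not None:
            ors = []
            for site in partition.counts.index:
                o = pr.deterministic_odds_ratio(
                    turnover.set_index(["sample_i", "sample_j"]), assignment.labels,
                    site=site, bnti_threshold=cfg.bnti_threshold,
                ).reset_index()
                o.insert(0, "site", site)
                ors.append(o)
            _write_tsv(pd.concat(ors, ignore_index=True), d / "odds_ratios.tsv", index=False)
        self.state["turnover"] = turnover
        self.report.metrics["process_fractions"] = {
            site: {k: float(v) for k, v in row.items()}
            for site, row in partition.fractions.iterrows()
        }

    def stage_networks(self):
        cfg = self.cfg
        d = self.out / "networks"
        d.mkdir(parents=True, exist_ok=True)
        assignment = self.state["assignment"]
        rarefied = self.state["rarefied"]
        n_edges = {}
        for state in sorted(assignment.labels.unique()):
            members = assignment.labels.index[assignment.labels == state]
            if len(members) < 4:
                self.report.warnings.append(
                    f"networks: state {state} has {len(members)} samples; skipped"
                )
                continue
            net = nw.build_network(
                rarefied, sample_ids=list(members), group=state,
                min_prevalence=cfg.min_prevalence, n_perm=cfg.n_perm,
                alpha=cfg.network_alpha, seed=cfg.seed,
                filter_on=cfg.network_filter_on,
            )
            _write_tsv(net.edges, d / f"edges_{state}.tsv", index=False)
            _write_tsv(net.nodes, d / f"nodes_{state}.tsv")
            import networkx as nx
            nx.write_graphml(net.graph, d / f"network_{state}.graphml")
            n_edges[state] = int(net.edges["kept"].sum())
        self.report.metrics["network_edges_kept"] = n_edges

    # ---- driver ----------------------------------------------------------
    def run(self) -> RunReport:
        status: dict[str, str] = {}
        for stage in STAGE_ORDER:
            t0 = time.perf_counter()
            if stage not in self.cfg.stages:
                status[stage] = "skipped"
            elif any(dep not in self.cfg.stages for dep in STAGE_DEPS[stage]):
                status[stage] = "skipped_missing_dependency"
            elif any(status.get(dep) != "ok" for dep in STAGE_DEPS[stage]):
                status[stage] = "halted_dependency_failed"
            else:
                try:
                    getattr(self, f"stage_{stage}")()
                    status[stage] = "ok"
                except Exception as exc:  # noqa: BLE001 - report and continue
                    logger.exception("stage %s failed", stage)
                    status[stage] = f"failed: {exc}"
            self.report.stages[stage] = {
                "status": status[stage],
                "seconds": round(time.perf_counter() - t0, 3),
            }
        for path in sorted(self.out.rglob("*")):
            if path.is_file() and path.name != "run_report.json":
                self.report.outputs[str(path.relative_to(self.out))] = _sha256(path)
        with open(self.out / "run_report.json", "w") as fh:
            json.dump(self.report.to_dict(), fh, indent=1, sort_keys=True, default=str)
        return self.report


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Validate the config, run all enabled stages, and write the report.

    Raises on config errors before any stage runs (fail-fast, no partial
    outputs); stage-level failures are recorded in the report instead.
    """
    config.validate()
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    return _Runner(config).run()


def pipeline_succeeded(report: RunReport) -> bool:
    return all(
        info["status"] in ("ok", "skipped", "skipped_missing_dependency")
        for info in report.stages.values()
    )
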