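"""Count tables, sample metadata, and pre-processing.

The universal currency of the pipeline is an integer sample x ASV count
table with a taxonomy string per ASV, plus a metadata table keyed by
sample id.  Pre-processing follows the standard playbook for low-biomass
16S data: contaminant removal driven by negative-control libraries,
rarefaction to a common depth, and Good's coverage as a completeness
check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

logger = logging.getLogger(__name__)

#: Sentinel genus for ASVs without a genus-level classification.  These are
#: exempt from the correlation-based contaminant rule: the pool of
#: unclassified reads aggregates many unrelated organisms and correlating
#: it against a contaminant genus would remove all of them at once.
UNCLASSIFIED_GENUS = "unclassified"

REQUIRED_METADATA_COLUMNS = ("sample_id", "patient_id", "body_site", "time_index")


class CountTableError(ValueError):
    """Raised for malformed count tables or metadata."""


@dataclass
class CountTable:
    """Sample x ASV integer abundance matrix with per-ASV taxonomy.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and ASV ids as columns;
        entries are non-negative integers.
    taxonomy:
        Series mapping every ASV id to a semicolon-delimited rank string
        (domain;phylum;class;order;family;genus;species — individual ranks
        may be empty).
    """

    data: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise CountTableError(f"duplicate sample id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise CountTableError(f"duplicate ASV id: {dup!r}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise CountTableError("counts must be integral")
            self.data = self.data.astype(np.int64)
            values = self.data.to_numpy()
        if values.size and (values < 0).any():
            raise CountTableError("counts must be non-negative")
        missing = cols.difference(self.taxonomy.index)
        if len(missing):
            raise CountTableError(f"taxonomy missing for ASVs: {list(missing)[:5]}")
        self.taxonomy = self.taxonomy.reindex(cols).fillna("")

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise CountTableError(f"sample {bad!r} has zero total reads")
        return self.data.div(totals, axis=0)

    def genus(self) -> pd.Series:
        """Genus per ASV: 6th semicolon field, rank prefix stripped."""
        return self.taxonomy.map(extract_genus)

    def genus_table(self) -> pd.DataFrame:
        """Counts aggregated to genus level (samples x genera)."""
        return self.data.T.groupby(self.genus()).sum().T

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data.loc[list(sample_ids)].copy(), self.taxonomy.copy())

    def drop_asvs(self, asv_ids) -> "CountTable":
        keep = [a for a in self.data.columns if a not in set(asv_ids)]
        return CountTable(self.data[keep].copy(), self.taxonomy.loc[keep].copy())

    def copy(self) -> "CountTable":
        return CountTable(self.data.copy(), self.taxonomy.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.data.equals(other.data) and self.taxonomy.equals(other.taxonomy)


def extract_genus(taxonomy_string: str) -> str:
    """Genus from a semicolon-delimited rank string (6th field).

    A missing, empty, or ``g__``-only field maps to ``"unclassified"``.
    """
    parts = [p.strip() for p in str(taxonomy_string).split(";")]
    genus = parts[5] if len(parts) > 5 else ""
    if genus.startswith("g__"):
        genus = genus[3:]
    return genus if genus else UNCLASSIFIED_GENUS


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_count_table(path, taxonomy_path=None) -> CountTable:
    """Read a TSV count table (rows = samples, columns = ASV ids).

    The first column holds sample ids.  ``taxonomy_path`` points to a
    two-column TSV (``asv_id``, ``taxonomy``); when absent, all taxonomy
    strings are empty.
    """
    data = pd.read_csv(path, sep="\t", index_col=0)
    data.index = data.index.astype(str)
    data.columns = data.columns.astype(str)
    if data.index.duplicated().any():
        dup = data.index[data.index.duplicated()][0]
        raise CountTableError(f"duplicate sample id in {path}: {dup!r}")
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str,
                          keep_default_na=False)
        taxonomy = tax.iloc[:, 0]
        taxonomy.index = taxonomy.index.astype(str)
    else:
        taxonomy = pd.Series("", index=data.columns)
    return CountTable(data, taxonomy)


def write_count_table(table: CountTable, path, taxonomy_path=None) -> None:
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
    if taxonomy_path is not None:
        tax = table.taxonomy.rename("taxonomy").to_frame()
        tax.index.name = "asv_id"
        tax.to_csv(taxonomy_path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def validate_metadata(meta: pd.DataFrame, table: CountTable | None = None) -> pd.DataFrame:
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise CountTableError(f"metadata missing required columns: {missing}")
    key = meta[["patient_id", "body_site", "time_index"]]
    if key.duplicated().any():
        row = key[key.duplicated()].iloc[0]
        raise CountTableError(
            f"duplicate (patient, site, time) triple: {tuple(row)}"
        )
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise CountTableError(f"duplicate sample id in metadata: {dup!r}")
    if table is not None:
        absent = set(table.sample_ids) - set(meta["sample_id"])
        if absent:
            raise CountTableError(f"samples without metadata: {sorted(absent)[:5]}")
    return meta


# ---------------------------------------------------------------------------
# Contaminant filtering
# ---------------------------------------------------------------------------

@dataclass
class ContaminantReport:
    """Per-rule accounting of removed taxa and reads.

    Rules are applied in order; each genus is attributed to the first rule
    that removes it.  Read fractions are relative to the pre-filter total,
    and reconcile exactly: ``total_before == total_after + reads removed``.
    """

    control_genera: list[str] = field(default_factory=list)
    correlated_genera: dict[str, tuple[str, float]] = field(default_factory=dict)
    reagent_genera: list[str] = field(default_factory=list)
    excluded_asvs: list[str] = field(default_factory=list)
    reads_removed: dict[str, int] = field(default_factory=dict)
    total_before: int = 0
    total_after: int = 0

    @property
    def fraction_removed(self) -> dict[str, float]:
        if self.total_before == 0:
            return {rule: 0.0 for rule in self.reads_removed}
        return {r: n / self.total_before for r, n in self.reads_removed.items()}

    def to_dict(self) -> dict:
        return {
            "control_genera": self.control_genera,
            "correlated_genera": {
                g: {"partner": p, "pearson_r": r}
                for g, (p, r) in self.correlated_genera.items()
            },
            "reagent_genera": self.reagent_genera,
            "excluded_asvs": self.excluded_asvs,
            "reads_removed": self.reads_removed,
            "fraction_removed": self.fraction_removed,
            "total_before": self.total_before,
            "total_after": self.total_after,
        }


def filter_contaminants(
    table: CountTable,
    neg_controls: pd.Series | dict | None = None,
    reagent_list=(),
    r_threshold: float = 0.9,
    read_threshold: int = 10,
    exclude_asvs=(),
) -> tuple[CountTable, ContaminantReport]:
    """Remove contaminant taxa using negative controls and a reagent list.

    Three genus-level rules plus one explicit ASV rule, in order:

    1. genera with strictly more than ``read_threshold`` reads in the
       pooled negative controls;
    2. genera whose relative-abundance profile across samples has a
       Pearson correlation above ``r_threshold`` with any rule-1 genus
       (unclassified reads are exempt);
    3. genera on the user-supplied reagent-contaminant list;
    4. explicitly excluded ASV ids (e.g. suspected cross-contamination
       from other libraries in the same run).

    Returns the filtered table and a :class:`ContaminantReport`.
    """
    if neg_controls is None:
        neg_controls = pd.Series(dtype=float)
    neg_controls = pd.Series(neg_controls, dtype=float)

    report = ContaminantReport(total_before=int(table.data.to_numpy().sum()))
    genus = table.genus()
    genus_counts = table.genus_table()

    control_hits = sorted(
        g for g, n in neg_controls.items() if n > read_threshold and g != UNCLASSIFIED_GENUS
    )
    report.control_genera = [g for g in control_hits if g in set(genus)]

    # rule 2: Pearson r on relative abundances, against genera actually hit
    correlated: dict[str, tuple[str, float]] = {}
    present_hits = [g for g in report.control_genera if g in genus_counts.columns]
    if present_hits:
        totals = genus_counts.sum(axis=1)
        nonzero = totals > 0
        rel = genus_counts.loc[nonzero].div(totals[nonzero], axis=0)
        for g in rel.columns:
            if g in present_hits or g == UNCLASSIFIED_GENUS:
                continue
            for hit in present_hits:
                x, y = rel[g].to_numpy(), rel[hit].to_numpy()
                if x.std() == 0 or y.std() == 0:
                    continue
                r = float(np.corrcoef(x, y)[0, 1])
                if r > r_threshold:
                    best = correlated.get(g)
                    if best is None or r > best[1]:
                        correlated[g] = (hit, r)
    report.correlated_genera = dict(sorted(correlated.items()))

    removed_so_far = set(report.control_genera) | set(report.correlated_genera)
    report.reagent_genera = sorted(
        (set(reagent_list) & set(genus)) - removed_so_far - {UNCLASSIFIED_GENUS}
    )

    def _reads_for(genera: set[str]) -> int:
        asvs = genus.index[genus.isin(genera)]
        return int(table.data[asvs].to_numpy().sum())

    report.reads_removed["negative_control"] = _reads_for(set(report.control_genera))
    report.reads_removed["correlation"] = _reads_for(set(report.correlated_genera))
    report.reads_removed["reagent_list"] = _reads_for(set(report.reagent_genera))

    drop_genera = removed_so_far | set(report.reagent_genera)
    drop_asvs = set(genus.index[genus.isin(drop_genera)])
    explicit = set(exclude_asvs) - drop_asvs
    report.excluded_asvs = sorted(a for a in explicit if a in table.data.columns)
    report.reads_removed["explicit_asvs"] = int(
        table.data[report.excluded_asvs].to_numpy().sum()
    )
    drop_asvs |= set(report.excluded_asvs)

    filtered = table.drop_asvs(drop_asvs)
    if filtered.data.shape[1] == 0:
        raise CountTableError("contaminant filtering removed every ASV")
    report.total_after = int(filtered.data.to_numpy().sum())
    assert report.total_before == report.total_after + sum(report.reads_removed.values())
    return filtered, report


# ---------------------------------------------------------------------------
# Rarefaction and coverage
# ---------------------------------------------------------------------------

def rarefy(table: CountTable, depth: int = 600, seed: int = 0) -> CountTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Sampling is multivariate hypergeometric per sample.  Samples with
    fewer than ``depth`` total reads are dropped (and logged).
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = substream(seed, "rarefy", depth)
    totals = table.sample_sums()
    kept_rows = []
    kept_ids = []
    for sample_id in table.sample_ids:
        total = int(totals[sample_id])
        counts = table.data.loc[sample_id].to_numpy(dtype=np.int64)
        if total < depth:
            logger.warning(
                "rarefy: dropping sample %r (%d reads < depth %d)",
                sample_id, total, depth,
            )
            continue
        if total == depth:
            kept_rows.append(counts)
        else:
            kept_rows.append(rng.multivariate_hypergeometric(counts, depth))
        kept_ids.append(sample_id)
    if not kept_ids:
        raise CountTableError(f"no sample reaches rarefaction depth {depth}")
    data = pd.DataFrame(
        np.vstack(kept_rows), index=pd.Index(kept_ids, name=table.data.index.name),
        columns=table.data.columns, dtype=np.int64,
    )
    return CountTable(data, table.taxonomy.copy())


def goods_coverage(table: CountTable) -> pd.Series:
    """Good's coverage per sample: 1 - singletons / total reads."""
    totals = table.sample_sums()
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise CountTableError(f"sample {bad!r} is empty")
    singletons = (table.data == 1).sum(axis=1)
    return (1.0 - singletons / totals).rename("goods_coverage")
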