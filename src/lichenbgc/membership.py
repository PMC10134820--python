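"""Gene-cluster-family membership analytics over BiG-SLiCE distances.

Each BGC carries a distance ``d`` to the centroid of its assigned gene
cluster family (GCF).  Membership strata follow the BiG-SLiCE
convention at the clustering threshold 900:

    core      d <= 900
    putative  900 < d <= 1800
    orphan    d > 1800

Orphan BGCs diverge strongly from everything in the reference models and
are the prime candidates for novel chemistry.  This module classifies
distances, tabulates membership breakdowns by chemical class / taxon /
source, compares GCF content across datasets (Venn-style) and ranks the
most prevalent GCFs by how many genomes carry them.

Assignment tables are plain DataFrames with the columns in
:data:`GCF_COLUMNS`; ``d`` is the only mandatory numeric column.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

GCF_COLUMNS = ("bgc_id", "gcf_id", "d", "chem_class", "genome_id", "dataset_label")

DEFAULT_T_CORE = 900.0
DEFAULT_T_PUTATIVE = 1800.0

GROUP_KEYS = {"chem_class", "genome_taxon", "source_label", "none"}


class MembershipClass(enum.Enum):
    CORE = "core"
    PUTATIVE = "putative"
    ORPHAN = "orphan"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def classify_membership(
    d: float, t_core: float = DEFAULT_T_CORE, t_putative: float = DEFAULT_T_PUTATIVE
) -> MembershipClass:
    """Stratify one centroid distance; boundaries are inclusive on the left class."""
    if d < 0:
        raise ValueError(f"distance d must be non-negative, got {d}")
    if t_core >= t_putative:
        raise ValueError("t_core must be smaller than t_putative")
    if d <= t_core:
        return MembershipClass.CORE
    if d <= t_putative:
        return MembershipClass.PUTATIVE
    return MembershipClass.ORPHAN


def _round2(x: float) -> float:
    """Half-up rounding to 2 decimals (the usual printed-percentage style)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = {"bgc_id", "gcf_id", "d"} - set(df.columns)
    if missing:
        raise ValueError(f"assignment table missing columns: {sorted(missing)}")
    if (df["d"] < 0).any():
        raise ValueError("assignment table contains negative distances")
    return df


def add_membership(
    df: pd.DataFrame,
    t_core: float = DEFAULT_T_CORE,
    t_putative: float = DEFAULT_T_PUTATIVE,
) -> pd.DataFrame:
    """Copy of the table with a ``membership`` column added."""
    _validate(df)
    out = df.copy()
    out["membership"] = [
        classify_membership(d, t_core, t_putative).value for d in out["d"]
    ]
    return out


def membership_summary(
    assignments: pd.DataFrame,
    group_by: str = "none",
    metadata: pd.DataFrame | None = None,
    t_core: float = DEFAULT_T_CORE,
    t_putative: float = DEFAULT_T_PUTATIVE,
) -> pd.DataFrame:
    """Counts and percentages of core/putative/orphan BGCs per group.

    ``group_by`` is one of ``chem_class`` (a table column),
    ``genome_taxon`` or ``source_label`` (looked up per genome_id in
    ``metadata``), or ``none`` for a single overall row.  Percentages
    are rounded half-up to two decimals.
    """
    if group_by not in GROUP_KEYS:
        raise ValueError(f"group_by must be one of {sorted(GROUP_KEYS)}")
    df = add_membership(assignments, t_core, t_putative)
    if group_by == "none":
        df["_group"] = "all"
    elif group_by == "chem_class":
        df["_group"] = df["chem_class"]
    else:
        if metadata is None or group_by not in metadata.columns:
            raise ValueError(f"metadata with a {group_by!r} column is required")
        lut = metadata.set_index("genome_id")[group_by]
        mapped = df["genome_id"].map(lut)
        if mapped.isna().any():
            offenders = sorted(df.loc[mapped.isna(), "bgc_id"])
            raise ValueError(f"metadata missing {group_by!r} for bgcs: {offenders}")
        df["_group"] = mapped
    rows = []
    for group, sub in df.groupby("_group", sort=True):
        n = len(sub)
        counts = sub["membership"].value_counts()
        row = {"group": group, "n": n}
        for m in MembershipClass:
            c = int(counts.get(m.value, 0))
            row[f"n_{m.value}"] = c
            row[f"pct_{m.value}"] = _round2(100.0 * c / n)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DatasetComparison:
    """GCF-content comparison across datasets (Venn-style)."""

    labels: tuple[str, ...]
    gcf_sets: Mapping[str, frozenset]
    intersections: Mapping[tuple[str, ...], int]  # every label combination
    unique_fractions: Mapping[str, float]  # |only in this dataset| / |dataset|
    unique_counts: Mapping[str, int]
    membership_distribution: Mapping[str, Mapping[str, int]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": list(self.labels),
                "set_sizes": {l: len(s) for l, s in self.gcf_sets.items()},
                "intersections": {
                    "&".join(k): v for k, v in self.intersections.items()
                },
                "unique_counts": dict(self.unique_counts),
                "unique_fractions": dict(self.unique_fractions),
                "membership_distribution": {
                    l: dict(m) for l, m in self.membership_distribution.items()
                },
            },
            indent=1,
        )


def dataset_comparison(
    assignment_sets: Sequence[tuple[str, pd.DataFrame]],
    t_core: float = DEFAULT_T_CORE,
    t_putative: float = DEFAULT_T_PUTATIVE,
) -> DatasetComparison:
    """Shared and unique GCFs among two or more datasets."""
    if len(assignment_sets) < 2:
        raise ValueError("need at least two datasets")
    labels = tuple(label for label, _ in assignment_sets)
    if len(set(labels)) != len(labels):
        raise ValueError("dataset labels must be unique")
    gcf_sets = {
        label: frozenset(_validate(df)["gcf_id"]) for label, df in assignment_sets
    }
    intersections: dict[tuple[str, ...], int] = {}
    for r in range(2, len(labels) + 1):
        for combo in combinations(labels, r):
            inter = frozenset.intersection(*(gcf_sets[l] for l in combo))
            intersections[combo] = len(inter)
    unique_counts, unique_fractions = {}, {}
    for label in labels:
        others = frozenset().union(*(gcf_sets[l] for l in labels if l != label))
        only = gcf_sets[label] - others
        unique_counts[label] = len(only)
        unique_fractions[label] = (
            len(only) / len(gcf_sets[label]) if gcf_sets[label] else 0.0
        )
    distribution = {}
    for label, df in assignment_sets:
        mem = add_membership(df, t_core, t_putative)["membership"].value_counts()
        distribution[label] = {m.value: int(mem.get(m.value, 0)) for m in MembershipClass}
    return DatasetComparison(
        labels=labels,
        gcf_sets=gcf_sets,
        intersections=intersections,
        unique_fractions=unique_fractions,
        unique_counts=unique_counts,
        membership_distribution=distribution,
    )


def prevalent_gcfs(assignments: pd.DataFrame, top_n: int = 5) -> pd.DataFrame:
    """GCFs ranked by the number of distinct genomes carrying a member BGC.

    Ties are broken lexicographically by gcf_id.  Columns: gcf_id,
    n_genomes, n_bgcs, d_values (list of member distances).
    """
    if top_n < 1:
        raise ValueError("top_n must be at least 1")
    df = _validate(assignments)
    if "genome_id" not in df.columns:
        raise ValueError("assignment table requires a genome_id column")
    grouped = df.groupby("gcf_id")
    stats = pd.DataFrame(
        {
            "n_genomes": grouped["genome_id"].nunique(),
            "n_bgcs": grouped.size(),
            "d_values": grouped["d"].apply(list),
        }
    ).reset_index()
    stats = stats.sort_values(
        ["n_genomes", "gcf_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return stats.head(top_n)


# ---------------------------------------------------------------------------
# I/O and converters


def read_assignments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"bgc_id": str, "gcf_id": str})
    return _validate(df)


def write_assignments(df: pd.DataFrame, path: str | Path) -> None:
    _validate(df).to_csv(path, sep="\t", index=False)


def from_bigslice_export(df: pd.DataFrame, dataset_label: str = "") -> pd.DataFrame:
    """Normalize a BiG-SLiCE SQLite-export table to :data:`GCF_COLUMNS`.

    Accepts the common export headers (``bgc_id``/``bgc``/``orig_filename``,
    ``gcf_id``/``gcf``, ``membership_value``/``distance``/``d``,
    ``class``/``chem_class``) case-insensitively.
    """
    lower = {c.lower(): c for c in df.columns}

    def pick(*names):
        for n in names:
            if n in lower:
                return df[lower[n]]
        return None

    out = pd.DataFrame(
        {
            "bgc_id": pick("bgc_id", "bgc", "orig_filename", "name"),
            "gcf_id": pick("gcf_id", "gcf"),
            "d": pd.to_numeric(pick("d", "membership_value", "distance", "gcf_value")),
            "chem_class": pick("chem_class", "class", "chem class"),
            "genome_id": pick("genome_id", "genome", "assembly"),
            "dataset_label": dataset_label,
        }
    )
    if out["bgc_id"].isna().all() or out["gcf_id"].isna().all() or out["d"].isna().all():
        raise ValueError("could not locate bgc/gcf/distance columns in export table")
    return _validate(out)


def read_dataset_s2(path: str | Path, dataset_label: str = "lichen") -> pd.DataFrame:
    """Ingest a study-supplement spreadsheet (BiG-SLiCE summary layout).

    Reads the first sheet of an ``.xlsx`` (or a TSV) whose columns carry
    the BGC id, chemical class, GCF id, distance and contig-edge flag,
    matching them case-insensitively, and returns a normalized
    assignment table with an extra ``on_contig_edge`` column when the
    spreadsheet provides one.
    """
    p = Path(path)
    if p.suffix.lower() in {".xlsx", ".xls"}:
        raw = pd.read_excel(p)
    else:
        raw = pd.read_csv(p, sep="\t")
    out = from_bigslice_export(raw, dataset_label=dataset_label)
    lower = {c.lower(): c for c in raw.columns}
    for name in ("contig_edge", "on_contig_edge", "contig edge"):
        if name in lower:
            col = raw[lower[name]]
            out["on_contig_edge"] = col.astype(str).str.strip().str.lower().isin(
                {"true", "1", "yes"}
            )
            break
    return out
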