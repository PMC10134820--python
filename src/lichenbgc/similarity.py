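"""Region-to-reference similarity from gene-level hit tables.

A hit table records which query genes of a BGC region have homologs in
which reference clusters (KnownClusterBlast / cblaster style).  The
similarity of a region to a reference is

    score = (number of distinct query genes with >= 1 hit to the
             reference) / denominator,

capped at 1, where the denominator is the region's gene count (mode
``"query-genes"``, the default) or the number of distinct reference
genes hit (mode ``"reference-genes"``).  Counting distinct genes rather
than raw hits makes the score invariant to duplicated HSP rows and
bounds it by 1 before capping in the default mode.

The best reference per region is the maximum-scoring one (ties broken
by smallest accession), and a link table keeps regions whose best score
reaches a cutoff (default 0.2, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .catalog import BGCRegion

HIT_COLUMNS = (
    "region_id",
    "query_locus_tag",
    "reference_accession",
    "reference_gene_id",
    "bitscore",
)

MODES = ("query-genes", "reference-genes")
DEFAULT_LINK_CUTOFF = 0.2


@dataclass(frozen=True)
class SimilarityScore:
    region_id: str
    reference_accession: str
    score: float
    numerator: int
    denominator: int
    mode: str

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


def _validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    missing = set(HIT_COLUMNS) - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return hits


def knowncluster_similarity(
    hits: pd.DataFrame,
    region: BGCRegion,
    reference_accession: str,
    mode: str = "query-genes",
) -> SimilarityScore:
    """Similarity of one region to one reference cluster."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not region.genes:
        raise ValueError(f"region {region.region_id!r} has no genes")
    _validate_hits(hits)
    sub = hits[
        (hits["region_id"] == region.region_id)
        & (hits["reference_accession"] == reference_accession)
    ]
    region_tags = {g.locus_tag for g in region.genes}
    numerator = int(sub["query_locus_tag"][sub["query_locus_tag"].isin(region_tags)].nunique())
    if mode == "query-genes":
        denominator = len(region.genes)
    else:
        denominator = int(sub["reference_gene_id"].nunique())
    score = min(1.0, numerator / denominator) if denominator else 0.0
    return SimilarityScore(
        region_id=region.region_id,
        reference_accession=reference_accession,
        score=score,
        numerator=numerator,
        denominator=denominator,
        mode=mode,
    )


def best_reference(
    hits: pd.DataFrame, region: BGCRegion, mode: str = "query-genes"
) -> tuple[str, float]:
    """Highest-scoring reference for a region; ('', 0.0) when it has no hits.

    Ties are broken by the lexicographically smallest accession.
    """
    _validate_hits(hits)
    accs = sorted(hits.loc[hits["region_id"] == region.region_id, "reference_accession"].unique())
    best_acc, best_score = "", 0.0
    for acc in accs:
        s = knowncluster_similarity(hits, region, acc, mode=mode).score
        if s > best_score:
            best_acc, best_score = acc, s
    return best_acc, best_score


def link_table(
    hits: pd.DataFrame,
    regions: Sequence[BGCRegion],
    cutoff: float = DEFAULT_LINK_CUTOFF,
    mode: str = "query-genes",
) -> pd.DataFrame:
    """One row per region whose best reference score reaches ``cutoff``.

    Columns: region_id, reference_accession, score.  The cutoff is
    inclusive; regions with genes but no qualifying reference are
    omitted.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    rows = []
    for region in regions:
        if not region.genes:
            continue
        acc, score = best_reference(hits, region, mode=mode)
        if acc and score >= cutoff:
            rows.append((region.region_id, acc, score))
    return pd.DataFrame(rows, columns=["region_id", "reference_accession", "score"])


# ---------------------------------------------------------------------------
# I/O


def read_hits(path: str | Path) -> pd.DataFrame:
    hits = pd.read_csv(path, sep="\t", comment="#")
    return _validate_hits(hits)


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    _validate_hits(hits).to_csv(path, sep="\t", index=False)


def write_links(links: pd.DataFrame, path: str | Path) -> None:
    links.to_csv(path, sep="\t", index=False)


def read_links(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"region_id": str, "reference_accession": str},
    )
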