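"""BGC region records: parsing, chemical classification, completeness.

Regions follow an antiSMASH-5-like dialect reduced to the fields this
pipeline consumes: coordinates, product types, the contig-edge flag and
a gene list.  Product subtypes (the antiSMASH vocabulary: NRPS, T1PKS,
lanthipeptide, ...) map onto seven chemical classes — NRP, Polyketide,
RiPP, Terpene, Saccharide, Other, and "hybrid" for regions whose product
types span more than one class.  A region flagged ``on_contig_edge`` is
truncated by an assembly break and counted as incomplete.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Contigs at or below this length are excluded from analysis, matching
#: the usual practice of running antiSMASH only on contigs > 5 kb.
MIN_CONTIG_BP = 5000

CHEMICAL_CLASSES = ("NRP", "Polyketide", "RiPP", "Terpene", "Saccharide", "Other", "hybrid")

#: antiSMASH product subtype -> chemical class (lower-cased keys).
PRODUCT_CLASS = {
    # NRP
    "cdps": "NRP",
    "nrps": "NRP",
    "nrps-like": "NRP",
    # Polyketide
    "pks-like": "Polyketide",
    "t1pks": "Polyketide",
    "t2pks": "Polyketide",
    "t3pks": "Polyketide",
    "hgle-ks": "Polyketide",
    "transat-pks": "Polyketide",
    "transat-pks-like": "Polyketide",
    # RiPP
    "lap": "RiPP",
    "tfua-related": "RiPP",
    "bacteriocin": "RiPP",
    "lanthipeptide": "RiPP",
    "lassopeptide": "RiPP",
    "linaridin": "RiPP",
    "thiopeptide": "RiPP",
    # Saccharide
    "amglyccycl": "Saccharide",
    "oligosaccharide": "Saccharide",
    # Terpene
    "terpene": "Terpene",
    # Other
    "naggn": "Other",
    "arylpolyene": "Other",
    "betalactone": "Other",
    "blactam": "Other",
    "butyrolactone": "Other",
    "ectoine": "Other",
    "furan": "Other",
    "fused": "Other",
    "hserlactone": "Other",
    "indole": "Other",
    "ladderane": "Other",
    "melanin": "Other",
    "nucleoside": "Other",
    "other": "Other",
    "phenazine": "Other",
    "phosphonate": "Other",
    "siderophore": "Other",
    "resorcinol": "Other",
}


@dataclass(frozen=True)
class GeneRecord:
    """One gene stub inside a region (0-based half-open coordinates)."""

    locus_tag: str
    start: int
    end: int
    strand: int = 1
    role_label: str = ""

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.locus_tag!r}: need 0 <= start < end")
        if self.strand not in (1, -1):
            raise ValueError(f"gene {self.locus_tag!r}: strand must be +1 or -1")


@dataclass(frozen=True)
class BGCRegion:
    """One antiSMASH-style biosynthetic region."""

    region_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    products: tuple[str, ...]
    on_contig_edge: bool
    genes: tuple[GeneRecord, ...] = ()
    contig_length: int | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"region {self.region_id!r}: end must exceed start")
        if not self.products:
            raise ValueError(f"region {self.region_id!r}: products must be non-empty")
        tags = [g.locus_tag for g in self.genes]
        if len(set(tags)) != len(tags):
            raise ValueError(f"region {self.region_id!r}: duplicate locus tags")
        for g in self.genes:
            if g.start < self.start or g.end > self.end:
                raise ValueError(
                    f"region {self.region_id!r}: gene {g.locus_tag!r} outside region span"
                )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ClassSummary:
    """Per-class total/complete/incomplete counts plus the overall complete rate."""

    table: pd.DataFrame  # index: chemical class; columns: total, complete, incomplete
    complete_fraction: float

    @property
    def n_regions(self) -> int:
        return int(self.table["total"].sum())


@dataclass(frozen=True)
class LengthStats:
    mean_kb: float
    max_kb: float
    longest_region_id: str


def classify_region(products: Sequence[str]) -> str:
    """Chemical class of a region from its product-type list.

    A single product maps through the subtype table; several products
    whose classes differ yield "hybrid"; several products within one
    class yield that class.  Unknown subtypes are classified "Other"
    with a warning.  The result does not depend on product order.
    """
    if not products:
        raise ValueError("products list must be non-empty")
    classes = set()
    for p in products:
        cls = PRODUCT_CLASS.get(p.lower())
        if cls is None:
            logger.warning("unknown product type %r classified as Other", p)
            cls = "Other"
        classes.add(cls)
    return classes.pop() if len(classes) == 1 else "hybrid"


def completeness_summary(regions: Sequence[BGCRegion]) -> ClassSummary:
    """Per-class counts of complete (not on a contig edge) regions."""
    counts: dict[str, list[int]] = {c: [0, 0, 0] for c in CHEMICAL_CLASSES}
    for r in regions:
        cls = classify_region(r.products)
        row = counts[cls]
        row[0] += 1
        row[2 if r.on_contig_edge else 1] += 1
    table = pd.DataFrame.from_dict(
        counts, orient="index", columns=["total", "complete", "incomplete"]
    )
    n = int(table["total"].sum())
    frac = float(table["complete"].sum() / n) if n else 0.0
    return ClassSummary(table=table, complete_fraction=frac)


def length_stats(regions: Sequence[BGCRegion]) -> LengthStats:
    """Mean and maximum region length in kb (1 decimal) and the longest region."""
    if not regions:
        raise ValueError("length_stats requires at least one region")
    lengths = [r.length for r in regions]
    imax = max(range(len(regions)), key=lambda i: (lengths[i], regions[i].region_id))
    return LengthStats(
        mean_kb=round(sum(lengths) / len(lengths) / 1000, 1),
        max_kb=round(lengths[imax] / 1000, 1),
        longest_region_id=regions[imax].region_id,
    )


# ---------------------------------------------------------------------------
# Region-JSON dialect I/O


def _region_to_dict(r: BGCRegion) -> dict:
    return {
        "region_id": r.region_id,
        "genome_id": r.genome_id,
        "contig_id": r.contig_id,
        "start": r.start,
        "end": r.end,
        "products": list(r.products),
        "on_contig_edge": r.on_contig_edge,
        "contig_length": r.contig_length,
        "genes": [
            {
                "locus_tag": g.locus_tag,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "role_label": g.role_label,
            }
            for g in r.genes
        ],
    }


def _region_from_dict(d: dict, index: int) -> BGCRegion:
    try:
        return BGCRegion(
            region_id=d["region_id"],
            genome_id=d.get("genome_id", ""),
            contig_id=d.get("contig_id", ""),
            start=int(d["start"]),
            end=int(d["end"]),
            products=tuple(d["products"]),
            on_contig_edge=bool(d["on_contig_edge"]),
            genes=tuple(
                GeneRecord(
                    locus_tag=g["locus_tag"],
                    start=int(g["start"]),
                    end=int(g["end"]),
                    strand=int(g.get("strand", 1)),
                    role_label=g.get("role_label", ""),
                )
                for g in d.get("genes", ())
            ),
            contig_length=d.get("contig_length"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        rid = d.get("region_id", f"<record {index}>")
        raise ValueError(f"malformed region record {rid!r}: {exc}") from exc


def write_regions(regions: Sequence[BGCRegion], path: str | Path) -> None:
    Path(path).write_text(json.dumps([_region_to_dict(r) for r in regions], indent=1) + "\n")


def load_regions(path: str | Path, min_contig_bp: int = MIN_CONTIG_BP) -> list[BGCRegion]:
    """Load regions, excluding those on contigs <= ``min_contig_bp``.

    Records without a recorded contig length are retained (their
    assembly is assumed pre-filtered).  The number of excluded records
    is logged.
    """
    text = Path(path).read_text()
    raw = json.loads(text) if text.strip() else []
    regions = [_region_from_dict(d, i) for i, d in enumerate(raw)]
    kept = [
        r
        for r in regions
        if r.contig_length is None or r.contig_length > min_contig_bp
    ]
    excluded = len(regions) - len(kept)
    if excluded:
        logger.info(
            "excluded %d of %d regions on contigs <= %d bp", excluded, len(regions), min_contig_bp
        )
    return kept


def load_antismash5_regions(path: str | Path, genome_id: str = "") -> list[BGCRegion]:
    """Extract regions from a genuine antiSMASH 5 result JSON.

    Pulls exactly the fields this pipeline uses from each record's
    ``areas``/feature annotations: region coordinates, ``products`` and
    ``contig_edge``, plus CDS coordinates falling inside the region.
    antiSMASH coordinates are already 0-based half-open.
    """
    doc = json.loads(Path(path).read_text())
    regions: list[BGCRegion] = []
    for rec in doc.get("records", []):
        contig_id = rec.get("id", "")
        contig_length = len(rec.get("seq", {}).get("data", "")) or None
        features = rec.get("features", [])
        region_feats = [f for f in features if f.get("type") == "region"]
        cds_feats = [f for f in features if f.get("type") == "CDS"]
        for i, f in enumerate(region_feats, start=1):
            start, end = _parse_location(f["location"])
            quals = f.get("qualifiers", {})
            products = tuple(quals.get("product", ["other"]))
            edge = quals.get("contig_edge", ["False"])[0] == "True"
            genes = []
            for c in cds_feats:
                cs, ce = _parse_location(c["location"])
                if cs >= start and ce <= end:
                    tag = c.get("qualifiers", {}).get("locus_tag", [f"cds_{cs}"])[0]
                    strand = -1 if "(-)" in c["location"] else 1
                    genes.append(GeneRecord(locus_tag=tag, start=cs, end=ce, strand=strand))
            regions.append(
                BGCRegion(
                    region_id=f"{contig_id}.region{i:03d}",
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    products=products,
                    on_contig_edge=edge,
                    genes=tuple(genes),
                    contig_length=contig_length,
                )
            )
    return regions


def _parse_location(loc: str) -> tuple[int, int]:
    inner = loc.strip("[]").split("]")[0]
    a, b = inner.split(":")
    return int(a.strip("<>")), int(b.split("](")[0].strip("<>"))


def write_class_summary(summary: ClassSummary, path: str | Path) -> None:
    df = summary.table.copy()
    df.index.name = "chem_class"
    df.to_csv(path, sep="\t")
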