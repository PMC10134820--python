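"""Chemical-space-guided molecular-family (MF) networking.

Query BGCs are linked to reference BGCs through genomic similarity
(thresholded hit-table scores), and reference BGCs are linked to each
other when any pair of their annotated compounds reaches a Tanimoto
similarity of 0.5 on Morgan radius-2 fingerprints.  Connected components
of the union graph that contain at least one query node *and* one
reference node are molecular families: groups of BGCs anchored to a
shared region of chemical space.  Comparing this partition against a
GCF partition quantifies how differently gene-content clustering and
chemistry-guided clustering group the same BGCs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048
DEFAULT_TANIMOTO_THRESHOLD = 0.5

QUERY_NODE = "query_bgc"
REFERENCE_NODE = "reference_bgc"
GENOMIC_EDGE = "genomic"
CHEMICAL_EDGE = "chemical"


@dataclass(frozen=True)
class ReferenceBGC:
    """A MIBiG-like reference entry: genes plus zero or more compound SMILES."""

    accession: str
    genes: tuple = ()
    compounds: tuple[str, ...] = ()
    taxon_label: str = ""


@dataclass(frozen=True)
class Fingerprint:
    """Sparse hashed circular-substructure fingerprint."""

    bits: frozenset[int]
    n_bits: int = DEFAULT_N_BITS
    radius: int = DEFAULT_RADIUS

    def __post_init__(self):
        if any(b < 0 or b >= self.n_bits for b in self.bits):
            raise ValueError("bit index outside [0, n_bits)")


def fingerprint(smiles: str, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS) -> Fingerprint:
    """Morgan fingerprint of a molecule given as SMILES.

    Raises ValueError for unparsable SMILES; callers building networks
    may catch and skip (with a warning) per reference compound.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(fp.GetOnBits()), n_bits=n_bits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A ∩ B| / |A ∪ B| over fingerprint bits; 0 when both are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprint widths differ")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def compound_edges(
    refs: Sequence[ReferenceBGC],
    threshold: float = DEFAULT_TANIMOTO_THRESHOLD,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> list[tuple[str, str, float]]:
    """Chemical edges between references.

    Two references are joined iff the *maximum* Tanimoto over their
    compound pairs reaches ``threshold`` (inclusive) — one edge decision
    per reference pair regardless of how many compounds each carries.
    Unparsable compounds are logged and skipped; references with no
    parsable compound form no edges.
    """
    fps: dict[str, list[Fingerprint]] = {}
    for ref in refs:
        parsed = []
        for smiles in ref.compounds:
            try:
                parsed.append(fingerprint(smiles, radius=radius, n_bits=n_bits))
            except ValueError:
                logger.warning("skipping unparsable compound of %s: %r", ref.accession, smiles)
        fps[ref.accession] = parsed
    edges = []
    accs = [r.accession for r in refs]
    for i in range(len(accs)):
        for j in range(i + 1, len(accs)):
            fa, fb = fps[accs[i]], fps[accs[j]]
            if not fa or not fb:
                continue
            best = max(tanimoto(x, y) for x in fa for y in fb)
            if best >= threshold:
                edges.append((accs[i], accs[j], best))
    return edges


def build_network(
    links: pd.DataFrame,
    chem_edges: Iterable[tuple[str, str, float]],
    query_ids: Iterable[str] | None = None,
    reference_ids: Iterable[str] | None = None,
) -> nx.Graph:
    """Union graph of genomic (query↔reference) and chemical (reference↔reference) edges.

    ``links`` is a link-table DataFrame (region_id, reference_accession,
    score).  Optional ``query_ids`` / ``reference_ids`` add unlinked
    nodes as isolates so component statistics see the full collection.
    """
    g = nx.Graph()
    for qid in query_ids or ():
        g.add_node(qid, node_type=QUERY_NODE)
    for rid in reference_ids or ():
        g.add_node(rid, node_type=REFERENCE_NODE)
    for row in links.itertuples(index=False):
        g.add_node(row.region_id, node_type=QUERY_NODE)
        g.add_node(row.reference_accession, node_type=REFERENCE_NODE)
        g.add_edge(
            row.region_id,
            row.reference_accession,
            edge_type=GENOMIC_EDGE,
            weight=float(row.score),
        )
    for a, b, w in chem_edges:
        g.add_node(a, node_type=REFERENCE_NODE)
        g.add_node(b, node_type=REFERENCE_NODE)
        g.add_edge(a, b, edge_type=CHEMICAL_EDGE, weight=float(w))
    return g


@dataclass(frozen=True)
class MolecularFamily:
    members: frozenset[str]
    query_members: frozenset[str]
    reference_members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MFReport:
    """Molecular families of a network plus summary counts.

    ``families`` lists every MF (components holding at least one query
    and one reference node); ``reported`` is the same list filtered to
    components of at least ``min_size`` nodes — a display convention —
    while the totals always refer to the unfiltered list.
    """

    families: tuple[MolecularFamily, ...]
    reported: tuple[MolecularFamily, ...]
    min_size: int
    n_isolated_queries: int

    @property
    def n_mfs(self) -> int:
        return len(self.families)

    @property
    def n_mfs_reported(self) -> int:
        return len(self.reported)

    @property
    def n_query_bgcs(self) -> int:
        return sum(len(f.query_members) for f in self.families)

    @property
    def n_reference_bgcs(self) -> int:
        return sum(len(f.reference_members) for f in self.families)

    def query_ids(self) -> frozenset[str]:
        return frozenset().union(*(f.query_members for f in self.families)) if self.families else frozenset()

    def reference_ids(self) -> frozenset[str]:
        return frozenset().union(*(f.reference_members for f in self.families)) if self.families else frozenset()


def molecular_families(net: nx.Graph, min_size: int = 1) -> MFReport:
    """Extract molecular families from a built network.

    An MF is a connected component containing at least one query node
    and at least one reference node; components made only of queries
    (unlinked regions) or only of references (chemistry with no genomic
    anchor) are not MFs.  ``min_size`` filters the reported list only.
    """
    if min_size < 1:
        raise ValueError("min_size must be at least 1")
    families = []
    isolated_queries = 0
    for comp in nx.connected_components(net):
        q = frozenset(n for n in comp if net.nodes[n]["node_type"] == QUERY_NODE)
        r = frozenset(n for n in comp if net.nodes[n]["node_type"] == REFERENCE_NODE)
        if q and r:
            families.append(
                MolecularFamily(members=frozenset(comp), query_members=q, reference_members=r)
            )
        elif q and not r:
            isolated_queries += len(q)
    families.sort(key=lambda f: (-f.size, min(f.members)))
    reported = tuple(f for f in families if f.size >= min_size)
    return MFReport(
        families=tuple(families),
        reported=reported,
        min_size=min_size,
        n_isolated_queries=isolated_queries,
    )


@dataclass(frozen=True)
class GroupingComparison:
    """Overlap between MF grouping and GCF grouping of the same collections."""

    mf_query_ids: frozenset[str]
    mf_reference_ids: frozenset[str]
    gcf_query_ids: frozenset[str]
    gcf_reference_ids: frozenset[str]

    @property
    def query_intersection(self) -> int:
        return len(self.mf_query_ids & self.gcf_query_ids)

    @property
    def reference_intersection(self) -> int:
        return len(self.mf_reference_ids & self.gcf_reference_ids)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mf": {
                    "n_query_grouped": len(self.mf_query_ids),
                    "n_reference_grouped": len(self.mf_reference_ids),
                },
                "gcf": {
                    "n_query_grouped": len(self.gcf_query_ids),
                    "n_reference_grouped": len(self.gcf_reference_ids),
                },
                "intersection": {
                    "query": self.query_intersection,
                    "reference": self.reference_intersection,
                },
            },
            indent=1,
        )


def compare_grouping(
    mf_report: MFReport,
    gcf_assignments: pd.DataFrame,
    reference_gcf_assignments: pd.DataFrame,
) -> GroupingComparison:
    """Compare query/reference co-grouping under the MF and GCF schemes.

    Under GCF, a query BGC counts as grouped with references when its
    gcf_id is shared by at least one reference BGC (and vice versa).
    Under MF, membership in any molecular family counts.
    """
    q_gcfs = dict(zip(gcf_assignments["bgc_id"], gcf_assignments["gcf_id"]))
    r_gcfs = dict(
        zip(reference_gcf_assignments["bgc_id"], reference_gcf_assignments["gcf_id"])
    )
    shared = set(q_gcfs.values()) & set(r_gcfs.values())
    return GroupingComparison(
        mf_query_ids=mf_report.query_ids(),
        mf_reference_ids=mf_report.reference_ids(),
        gcf_query_ids=frozenset(b for b, g in q_gcfs.items() if g in shared),
        gcf_reference_ids=frozenset(b for b, g in r_gcfs.items() if g in shared),
    )


# ---------------------------------------------------------------------------
# I/O


def write_reference_library(refs: Sequence[ReferenceBGC], path: str | Path) -> None:
    payload = [
        {
            "accession": r.accession,
            "taxon_label": r.taxon_label,
            "compounds": list(r.compounds),
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
        for r in refs
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_reference_library(path: str | Path) -> list[ReferenceBGC]:
    from .catalog import GeneRecord

    raw = json.loads(Path(path).read_text())
    return [
        ReferenceBGC(
            accession=d["accession"],
            taxon_label=d.get("taxon_label", ""),
            compounds=tuple(d.get("compounds", ())),
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
        )
        for d in raw
    ]


def from_mibig_entry(entry: Mapping) -> ReferenceBGC:
    """Convert one MIBiG 2.0 JSON entry to a :class:`ReferenceBGC`.

    Extracts the accession and the ``chem_struct`` SMILES of each listed
    compound; entries without parsable structures keep an empty compound
    list (and will form no chemical edges).
    """
    cluster = entry.get("cluster", entry)
    accession = cluster.get("mibig_accession", cluster.get("accession", ""))
    compounds = tuple(
        c["chem_struct"].strip()
        for c in cluster.get("compounds", ())
        if c.get("chem_struct")
    )
    taxon = cluster.get("organism_name", "")
    return ReferenceBGC(accession=accession, compounds=compounds, taxon_label=taxon)


def write_network(net: nx.Graph, edge_path: str | Path, graphml_path: str | Path | None = None) -> None:
    """Edge-list TSV (with node types) and optional GraphML export."""
    with open(edge_path, "w") as fh:
        fh.write("source\tsource_type\ttarget\ttarget_type\tedge_type\tweight\n")
        for a, b, data in sorted(net.edges(data=True)):
            fh.write(
                f"{a}\t{net.nodes[a]['node_type']}\t{b}\t{net.nodes[b]['node_type']}"
                f"\t{data['edge_type']}\t{data['weight']:.4f}\n"
            )
    if graphml_path is not None:
        nx.write_graphml(net, str(graphml_path))


def write_mf_report(report: MFReport, path: str | Path) -> None:
    payload = {
        "n_mfs": report.n_mfs,
        "n_mfs_reported": report.n_mfs_reported,
        "min_size": report.min_size,
        "n_query_bgcs_in_mfs": report.n_query_bgcs,
        "n_reference_bgcs_in_mfs": report.n_reference_bgcs,
        "n_isolated_queries": report.n_isolated_queries,
        "families": [
            {
                "size": f.size,
                "query_members": sorted(f.query_members),
                "reference_members": sorted(f.reference_members),
            }
            for f in report.families
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")
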