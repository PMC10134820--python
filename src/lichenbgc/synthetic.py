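"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the artifacts of a culture-collection genome-mining
study: draft genome assemblies, antiSMASH-style BGC region records,
MIBiG-like reference entries with compound SMILES, KnownClusterBlast-style
hit tables, and BiG-SLiCE-style GCF assignment tables.  Each generator
plants a recoverable truth (species structure, gene homology, compound
families, membership fractions) so downstream stages can be validated
end to end without any external download.

Every generator draws from a single ``numpy.random.default_rng`` seeded
per call; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: antiSMASH-style product vocabulary grouped by chemical class; mirrors the
#: subclass->class table in :mod:`lichenbgc.catalog`.
DEFAULT_PRODUCT_TYPES = (
    "NRPS",
    "T1PKS",
    "lanthipeptide",
    "terpene",
    "siderophore",
)

#: Non-hybrid chemical-class weights observed in large actinomycete surveys
#: (NRP/PK/RiPP/terpene-heavy, saccharides rare).
DEFAULT_CLASS_WEIGHTS = {
    "NRPS": 0.24,
    "T1PKS": 0.21,
    "lanthipeptide": 0.16,
    "terpene": 0.17,
    "amglyccycl": 0.002,
    "siderophore": 0.218,
}


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class GenomeRecord:
    """A (possibly multi-contig) genome assembly."""

    genome_id: str
    contigs: tuple[tuple[str, str], ...]  # (contig_id, sequence)
    taxon_label: str = ""

    def __post_init__(self):
        ids = [cid for cid, _ in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate contig ids in genome {self.genome_id!r}")
        for cid, seq in self.contigs:
            if not seq:
                raise ValueError(f"empty contig {cid!r} in genome {self.genome_id!r}")
            if set(seq) - set("ACGTN"):
                raise ValueError(f"contig {cid!r} contains symbols outside A,C,G,T,N")

    @property
    def length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)


@dataclass(frozen=True)
class PanelTruth:
    """Planted ground truth for a strain panel."""

    species_of: Mapping[str, str]  # genome_id -> planted species id
    within_rate: float
    between_rate: float


# ---------------------------------------------------------------------------
# Genomes


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def generate_genome(
    length: int,
    gc: float = 0.7,
    seed: int = 0,
    genome_id: str = "G0",
    n_contigs: int = 1,
    taxon_label: str = "",
) -> GenomeRecord:
    """Pseudorandom genome with expected GC content ``gc``.

    The default GC of 0.7 reflects high-GC actinomycete genomes.  The
    sequence is split evenly into ``n_contigs`` contigs.
    """
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must lie strictly between 0 and 1")
    if n_contigs < 1 or n_contigs > length:
        raise ValueError("n_contigs must be in [1, length]")
    rng = np.random.default_rng(seed)
    seq = _random_sequence(rng, length, gc)
    bounds = np.linspace(0, length, n_contigs + 1).astype(int)
    contigs = tuple(
        (f"{genome_id}_c{i}", seq[bounds[i] : bounds[i + 1]])
        for i in range(n_contigs)
    )
    return GenomeRecord(genome_id=genome_id, contigs=contigs, taxon_label=taxon_label)


def mutate_genome(genome: GenomeRecord, rate: float, seed: int = 0,
                  genome_id: str | None = None) -> GenomeRecord:
    """Independent per-site substitutions at probability ``rate``.

    Each selected A/C/G/T site is replaced by a uniformly chosen
    *different* base; N sites are left untouched.  Contig structure is
    preserved.
    """
    if not 0.0 <= rate <= 0.3:
        raise ValueError(f"substitution rate must lie in [0, 0.3], got {rate}")
    rng = np.random.default_rng(seed)
    new_id = genome_id if genome_id is not None else genome.genome_id
    contigs = []
    for cid, seq in genome.contigs:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        acgt = arr != ord("N")
        hit = acgt & (rng.random(len(arr)) < rate)
        if hit.any():
            code = np.zeros(len(arr), dtype=np.uint8)
            for i, b in enumerate(_BASES):
                code[arr == b] = i
            shift = rng.integers(1, 4, size=int(hit.sum()))
            code[hit] = (code[hit] + shift) % 4
            arr[hit] = _BASES[code[hit]]
        new_cid = cid if genome_id is None else cid.replace(genome.genome_id, new_id, 1)
        contigs.append((new_cid, arr.tobytes().decode("ascii")))
    return GenomeRecord(genome_id=new_id, contigs=tuple(contigs),
                        taxon_label=genome.taxon_label)


def generate_strain_panel(
    n_species: int,
    strains_per_species: int,
    within_rate: float = 0.002,
    between_rate: float = 0.08,
    seed: int = 0,
    genome_length: int = 100_000,
    gc: float = 0.7,
) -> tuple[list[GenomeRecord], PanelTruth]:
    """Strain panel with planted species structure.

    One ancestor per species is derived from a common root at
    ``between_rate``; strains are derived from their ancestor at
    ``within_rate``.  Two strains of one species then differ at roughly
    ``2 * within_rate`` while strains of different species differ at
    roughly ``2 * between_rate`` — well separated for the default
    dereplication (0.005) and species (0.04) cutoffs.
    """
    if n_species < 1 or strains_per_species < 1:
        raise ValueError("panel dimensions must be positive")
    if between_rate <= within_rate:
        raise ValueError("between_rate must exceed within_rate")
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=n_species * (strains_per_species + 1) + 1)
    root = generate_genome(genome_length, gc=gc, seed=int(sub[0]), genome_id="root")
    genomes: list[GenomeRecord] = []
    species_of: dict[str, str] = {}
    idx = 1
    for sp in range(n_species):
        sp_id = f"sp{sp:03d}"
        ancestor = mutate_genome(root, between_rate, seed=int(sub[idx]), genome_id=sp_id)
        idx += 1
        for st in range(strains_per_species):
            gid = f"{sp_id}_st{st:02d}"
            genomes.append(
                mutate_genome(ancestor, within_rate, seed=int(sub[idx]), genome_id=gid)
            )
            species_of[gid] = sp_id
            idx += 1
    return genomes, PanelTruth(species_of=species_of, within_rate=within_rate,
                               between_rate=between_rate)


# ---------------------------------------------------------------------------
# BGC regions


def generate_bgc_collection(
    n_regions: int,
    class_weights: Mapping[str, float] | None = None,
    edge_fraction: float = 0.372,
    seed: int = 0,
    hybrid_prob: float = 0.2,
    n_genomes: int | None = None,
    length_range_kb: tuple[float, float] = (5.0, 60.0),
):
    """antiSMASH-style region records with planted class and edge structure.

    Product types are drawn per ``class_weights``; with probability
    ``hybrid_prob`` a region receives two distinct product types,
    mirroring antiSMASH multi-product (hybrid) regions.  The default
    ``edge_fraction`` of 0.372 matches the contig-edge rate typical of
    short-read actinomycete assemblies; region lengths are uniform on
    ``length_range_kb``.  Gene stubs are laid down every ~2.5 kb.

    Returns a list of :class:`lichenbgc.catalog.BGCRegion`.
    """
    from .catalog import BGCRegion, GeneRecord

    if n_regions < 0:
        raise ValueError("n_regions must be non-negative")
    weights = dict(class_weights) if class_weights is not None else dict(DEFAULT_CLASS_WEIGHTS)
    if any(w < 0 for w in weights.values()):
        raise ValueError("class weights must be non-negative")
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class weights must sum to 1, got {total}")
    if not 0.0 <= edge_fraction <= 1.0:
        raise ValueError("edge_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    types = sorted(weights)
    probs = np.array([weights[t] for t in types])
    if n_genomes is None:
        n_genomes = max(1, n_regions // 25)
    regions = []
    per_genome_count: dict[str, int] = {}
    for _ in range(n_regions):
        genome_id = f"G{int(rng.integers(0, n_genomes)):04d}"
        r_idx = per_genome_count.get(genome_id, 0)
        per_genome_count[genome_id] = r_idx + 1
        region_id = f"{genome_id}_r{r_idx}c1"
        length = int(rng.uniform(*length_range_kb) * 1000)
        products = [types[int(rng.choice(len(types), p=probs))]]
        if len(types) > 1 and rng.random() < hybrid_prob:
            second = products[0]
            while second == products[0]:
                second = types[int(rng.choice(len(types), p=probs))]
            products.append(second)
        on_edge = bool(rng.random() < edge_fraction)
        # edge regions sit at the contig start; complete ones are interior
        start = 0 if on_edge else int(rng.integers(100, 5000))
        end = start + length
        contig_length = end + (0 if on_edge else int(rng.integers(100, 5000)))
        n_genes = max(3, length // 2500)
        gene_bounds = np.linspace(start, end, n_genes + 1).astype(int)
        genes = tuple(
            GeneRecord(
                locus_tag=f"{region_id}_g{gi}",
                start=int(gene_bounds[gi]),
                end=int(gene_bounds[gi + 1]),
                strand=1 if rng.random() < 0.5 else -1,
                role_label=products[0],
            )
            for gi in range(n_genes)
        )
        regions.append(
            BGCRegion(
                region_id=region_id,
                genome_id=genome_id,
                contig_id=f"{genome_id}_c{r_idx}",
                start=start,
                end=end,
                products=tuple(products),
                on_contig_edge=on_edge,
                genes=genes,
                contig_length=contig_length,
            )
        )
    return regions


# ---------------------------------------------------------------------------
# Reference library with planted compound families


def load_scaffold_templates() -> list[tuple[str, str]]:
    """Packaged (SMILES, name) scaffold templates for compound families."""
    text = resources.files("lichenbgc.data").joinpath("scaffolds.smi").read_text()
    out = []
    for line in text.strip().splitlines():
        smiles, name = line.split("\t")
        out.append((smiles, name))
    return out


def _decorate(smiles: str, rng: np.random.Generator) -> str:
    """Attach a small substituent to a random position of a molecule.

    Produces a close structural analogue (high Morgan/Tanimoto similarity
    to the parent), emulating natural-product congeners within a family.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    rw = Chem.RWMol(mol)
    candidates = [a.GetIdx() for a in rw.GetAtoms() if a.GetTotalNumHs() > 0]
    if not candidates:
        return smiles
    target = int(rng.choice(candidates))
    substituent = [("C",), ("O",), ("N",), ("F",), ("Cl",), ("C", "C")][int(rng.integers(0, 6))]
    prev = target
    for sym in substituent:
        new_idx = rw.AddAtom(Chem.Atom(sym))
        rw.AddBond(prev, new_idx, Chem.BondType.SINGLE)
        prev = new_idx
    try:
        Chem.SanitizeMol(rw)
    except Exception:
        return smiles
    return Chem.MolToSmiles(rw)


def generate_reference_library(n_families: int, refs_per_family: int, seed: int = 0):
    """MIBiG-like reference entries grouped into planted compound families.

    Each family is anchored on one packaged scaffold; members carry small
    decorations of that scaffold.  The planted property — maximum
    pairwise Tanimoto >= 0.5 within a family and < 0.5 between families
    (Morgan radius 2, 2048 bits) — is verified at generation time;
    offending members are re-decorated and, failing that, the family is
    rebuilt on a fresh scaffold.

    Returns a list of :class:`lichenbgc.molfam.ReferenceBGC`.
    """
    from .molfam import ReferenceBGC, fingerprint, tanimoto
    from .catalog import GeneRecord

    if n_families < 1 or refs_per_family < 1:
        raise ValueError("n_families and refs_per_family must be positive")
    templates = load_scaffold_templates()
    if n_families > len(templates):
        raise ValueError(
            f"only {len(templates)} scaffold templates packaged; "
            f"cannot plant {n_families} families"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(templates))
    family_fps: list[list] = []
    refs = []
    acc_counter = 1
    template_cursor = 0

    def family_ok(fps_new):
        for fps_old in family_fps:
            for fa in fps_new:
                for fb in fps_old:
                    if tanimoto(fa, fb) >= 0.5:
                        return False
        within = all(
            max(tanimoto(fps_new[i], fps_new[jj]) for jj in range(len(fps_new)) if jj != i)
            >= 0.5
            for i in range(len(fps_new))
        ) if len(fps_new) > 1 else True
        return within

    for fam in range(n_families):
        placed = False
        while not placed:
            if template_cursor >= len(order):
                raise ValueError("scaffold template list exhausted")
            scaffold, name = templates[order[template_cursor]]
            template_cursor += 1
            for _attempt in range(5):
                compounds = [scaffold] + [
                    _decorate(scaffold, rng) for _ in range(refs_per_family - 1)
                ]
                fps = [fingerprint(c) for c in compounds]
                if family_ok(fps):
                    placed = True
                    break
            if not placed:
                continue
            family_fps.append(fps)
            for member, smiles in enumerate(compounds):
                acc = f"BGC{acc_counter:07d}"
                acc_counter += 1
                n_genes = int(rng.integers(4, 15))
                genes = tuple(
                    GeneRecord(
                        locus_tag=f"{acc}_g{gi}",
                        start=gi * 1500,
                        end=(gi + 1) * 1500,
                        strand=1,
                        role_label="biosynthetic",
                    )
                    for gi in range(n_genes)
                )
                refs.append(
                    ReferenceBGC(
                        accession=acc,
                        genes=genes,
                        compounds=(smiles,),
                        taxon_label=f"family_{name}",
                    )
                )
    return refs


# ---------------------------------------------------------------------------
# Hit tables


def generate_hit_table(
    regions,
    refs,
    planted_links: Mapping[str, tuple[str, float]],
    noise_links: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """KnownClusterBlast-style hit table with planted similarity scores.

    For each planted ``region_id -> (accession, score)`` exactly
    ``ceil(score * n_query_genes)`` distinct query genes receive one hit
    each to the named reference, so the recomputed query-gene similarity
    equals the planted score exactly whenever ``score * n_query_genes``
    is an integer (and rounds up to the next attainable score otherwise).
    Noise links touch a single gene of regions with > 5 genes, keeping
    every noise score strictly below 0.2.
    """
    rng = np.random.default_rng(seed)
    region_by_id = {r.region_id: r for r in regions}
    ref_by_acc = {r.accession: r for r in refs}
    rows = []
    for region_id, (acc, score) in planted_links.items():
        region = region_by_id[region_id]
        ref = ref_by_acc[acc]
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"planted score {score} outside [0, 1]")
        n_genes = len(region.genes)
        if n_genes == 0:
            raise ValueError(f"region {region_id!r} has no genes; score unrealizable")
        n_hit = math.ceil(score * n_genes - 1e-12)
        chosen = rng.choice(n_genes, size=n_hit, replace=False)
        for qi in sorted(chosen):
            ref_gene = ref.genes[qi % len(ref.genes)] if ref.genes else None
            rows.append(
                (
                    region_id,
                    region.genes[qi].locus_tag,
                    acc,
                    ref_gene.locus_tag if ref_gene else f"{acc}_g0",
                    float(rng.uniform(80, 800)),
                )
            )
    planted_pairs = {(rid, acc) for rid, (acc, _) in planted_links.items()}
    eligible = [r for r in regions if len(r.genes) > 5 and r.region_id not in planted_links]
    used = set()
    attempts = 0
    made = 0
    while made < noise_links and attempts < 50 * max(noise_links, 1):
        attempts += 1
        if not eligible:
            break
        region = eligible[int(rng.integers(0, len(eligible)))]
        ref = refs[int(rng.integers(0, len(refs)))]
        key = (region.region_id, ref.accession)
        if key in used or key in planted_pairs:
            continue
        used.add(key)
        gene = region.genes[int(rng.integers(0, len(region.genes)))]
        ref_gene = ref.genes[0].locus_tag if ref.genes else f"{ref.accession}_g0"
        rows.append((region.region_id, gene.locus_tag, ref.accession, ref_gene,
                     float(rng.uniform(40, 120))))
        made += 1
    if made < noise_links:
        raise ValueError("could not place the requested number of noise links")
    from .similarity import HIT_COLUMNS

    return pd.DataFrame(rows, columns=list(HIT_COLUMNS))


# ---------------------------------------------------------------------------
# GCF assignment tables

_STRATA = {"core": (0.0, 900.0), "putative": (900.0, 1800.0), "orphan": (1800.0, 3000.0)}
_CHEM_CLASSES = ("NRP", "Polyketide", "RiPP", "Terpene", "Saccharide", "Other")


#: Default (core, putative, orphan) mix: the membership ratios typical of
#: large actinomycete BGC collections, expressed as exact count ratios.
DEFAULT_MEMBERSHIP_FRACTIONS = (5146 / 8541, 3073 / 8541, 322 / 8541)


def generate_gcf_table(
    region_ids: Sequence[str],
    fractions: tuple[float, float, float] = DEFAULT_MEMBERSHIP_FRACTIONS,
    seed: int = 0,
    n_gcfs: int | None = None,
    dataset_label: str = "synthetic",
) -> pd.DataFrame:
    """BiG-SLiCE-style assignment table with planted membership fractions.

    ``fractions`` are the (core, putative, orphan) probabilities; the
    defaults mirror the membership mix reported for large actinomycete
    BGC collections.  Distances d are drawn uniformly within each
    stratum: [0, 900], (900, 1800], (1800, 3000].  Genome ids are parsed
    from region ids of the form ``<genome>_r<i>c<j>`` when present.
    """
    core, putative, orphan = fractions
    if min(fractions) < 0 or abs(core + putative + orphan - 1.0) > 1e-9:
        raise ValueError("membership fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    n = len(region_ids)
    if n_gcfs is None:
        n_gcfs = max(1, n // 8)
    strata = rng.choice(3, size=n, p=[core, putative, orphan])
    rows = []
    for rid, stratum in zip(region_ids, strata):
        name = ("core", "putative", "orphan")[stratum]
        lo, hi = _STRATA[name]
        d = float(rng.uniform(lo, hi)) if stratum else float(rng.uniform(0.0, hi))
        gcf = f"GCF_{int(rng.integers(0, n_gcfs)):06d}"
        genome_id = rid.split("_r")[0] if "_r" in rid else rid
        rows.append(
            (
                rid,
                gcf,
                d,
                _CHEM_CLASSES[int(rng.integers(0, len(_CHEM_CLASSES)))],
                genome_id,
                dataset_label,
            )
        )
    from .membership import GCF_COLUMNS

    return pd.DataFrame(rows, columns=list(GCF_COLUMNS))


# ---------------------------------------------------------------------------
# FASTA / truth-table I/O


def write_fasta(genomes: Sequence[GenomeRecord], path: str | Path) -> None:
    """Multi-genome FASTA; headers are ``<genome_id> <contig_id>``."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=f"{g.genome_id}|{cid}", description=g.taxon_label)
        for g in genomes
        for cid, seq in g.contigs
    ]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read genomes written by :func:`write_fasta` (``genome|contig`` ids)."""
    from Bio.SeqIO import parse

    grouped: dict[str, list[tuple[str, str]]] = {}
    taxa: dict[str, str] = {}
    for rec in parse(str(path), "fasta"):
        if "|" in rec.id:
            genome_id, contig_id = rec.id.split("|", 1)
        else:
            genome_id, contig_id = rec.id, rec.id
        grouped.setdefault(genome_id, []).append((contig_id, str(rec.seq).upper()))
        taxa.setdefault(genome_id, rec.description.split(" ", 1)[1] if " " in rec.description else "")
    return [
        GenomeRecord(genome_id=gid, contigs=tuple(contigs), taxon_label=taxa[gid])
        for gid, contigs in grouped.items()
    ]


def write_truth(truth: PanelTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tspecies_id\twithin_rate\tbetween_rate\n")
        for gid, sp in truth.species_of.items():
            fh.write(f"{gid}\t{sp}\t{truth.within_rate}\t{truth.between_rate}\n")
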