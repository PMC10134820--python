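"""Fingerprints, Tanimoto edges and molecular-family extraction."""

import numpy as np
import pandas as pd
import pytest

from lichenbgc.molfam import (
    Fingerprint,
    MFReport,
    MolecularFamily,
    ReferenceBGC,
    build_network,
    compare_grouping,
    compound_edges,
    fingerprint,
    from_mibig_entry,
    molecular_families,
    read_reference_library,
    tanimoto,
    write_reference_library,
)


def _links(rows):
    return pd.DataFrame(rows, columns=["region_id", "reference_accession", "score"])


class TestFingerprint:
    def test_deterministic(self):
        assert fingerprint("CCO") == fingerprint("CCO")

    def test_smiles_rewriting_invariant(self):
        assert fingerprint("CCO") == fingerprint("OCC")

    def test_unparsable_rejected(self):
        with pytest.raises(ValueError):
            fingerprint("not_a_smiles")

    def test_bits_within_width(self):
        fp = fingerprint("Cn1cnc2c1c(=O)n(C)c(=O)n2C", n_bits=512)
        assert fp.n_bits == 512
        assert all(0 <= b < 512 for b in fp.bits)


class TestTanimoto:
    def test_identity(self):
        fp = fingerprint("CCO")
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint(self):
        a = Fingerprint(bits=frozenset({1, 2}), n_bits=64)
        b = Fingerprint(bits=frozenset({3, 4}), n_bits=64)
        assert tanimoto(a, b) == 0.0

    def test_arithmetic(self):
        a = Fingerprint(bits=frozenset({1, 2, 3}), n_bits=64)
        b = Fingerprint(bits=frozenset({2, 3, 4}), n_bits=64)
        assert tanimoto(a, b) == 0.5  # |∩|=2, |∪|=4

    def test_both_empty_defined_as_zero(self):
        e = Fingerprint(bits=frozenset(), n_bits=64)
        assert tanimoto(e, e) == 0.0

    def test_symmetry_and_bounds(self):
        a = fingerprint("CC(=O)Oc1ccccc1C(=O)O")
        b = fingerprint("CC(C)Cc1ccc(cc1)C(C)C(=O)O")
        assert tanimoto(a, b) == tanimoto(b, a)
        assert 0.0 <= tanimoto(a, b) <= 1.0

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto(Fingerprint(frozenset(), 64), Fingerprint(frozenset(), 128))


class TestCompoundEdges:
    def test_shared_identical_compound_gives_weight_one(self):
        refs = [
            ReferenceBGC("A1", compounds=("CCO",)),
            ReferenceBGC("A2", compounds=("OCC",)),
        ]
        edges = compound_edges(refs)
        assert edges == [("A1", "A2", 1.0)]

    def test_dissimilar_compounds_give_no_edges(self):
        refs = [
            ReferenceBGC("A1", compounds=("CC(=O)Oc1ccccc1C(=O)O",)),
            ReferenceBGC("A2", compounds=("CN1CCCC1c1cccnc1",)),
        ]
        assert compound_edges(refs, threshold=0.5) == []

    def test_max_over_compound_pairs_decides(self):
        refs = [
            ReferenceBGC("A1", compounds=("CN1CCCC1c1cccnc1", "CCO")),
            ReferenceBGC("A2", compounds=("OCC",)),
        ]
        edges = compound_edges(refs)
        assert len(edges) == 1 and edges[0][2] == 1.0

    def test_unparsable_compound_skipped(self, caplog):
        refs = [
            ReferenceBGC("A1", compounds=("@@bad@@",)),
            ReferenceBGC("A2", compounds=("CCO",)),
        ]
        with caplog.at_level("WARNING"):
            assert compound_edges(refs) == []

    def test_planted_families_exactly_recovered(self, reference_library):
        edges = compound_edges(reference_library)
        fam = {r.accession: r.taxon_label for r in reference_library}
        for a, b, _ in edges:
            assert fam[a] == fam[b], "edge crosses planted families"


class TestBuildNetworkAndMFs:
    def test_no_edges_all_isolated(self):
        net = build_network(_links([]), [], query_ids=["q1", "q2"], reference_ids=["R1"])
        assert net.number_of_edges() == 0
        report = molecular_families(net)
        assert report.n_mfs == 0
        assert report.n_isolated_queries == 2

    def test_transitive_component_through_chemistry(self):
        net = build_network(
            _links([("A", "R1", 0.5), ("B", "R2", 0.5)]),
            [("R1", "R2", 0.8)],
        )
        report = molecular_families(net)
        assert report.n_mfs == 1
        fam = report.families[0]
        assert fam.size == 4
        assert fam.query_members == {"A", "B"}
        assert fam.reference_members == {"R1", "R2"}

    def test_reference_only_component_is_not_an_mf(self):
        net = build_network(_links([]), [("R1", "R2", 0.9)])
        assert molecular_families(net).n_mfs == 0

    def test_min_size_filters_reported_list_only(self):
        links, chem = [], []
        # 12 MFs: 5 of size 2 (1 query + 1 ref), 7 of size 6 (5 queries + 1 ref)
        for i in range(5):
            links.append((f"small{i}", f"SR{i}", 0.5))
        for i in range(7):
            for q in range(5):
                links.append((f"big{i}_q{q}", f"BR{i}", 0.5))
        report_all = molecular_families(build_network(_links(links), chem), min_size=1)
        report_filtered = molecular_families(build_network(_links(links), chem), min_size=6)
        assert report_all.n_mfs == 12
        assert report_filtered.n_mfs == 12  # totals unchanged
        assert report_filtered.n_mfs_reported == 7

    def test_mfs_partition_nodes(self, reference_library):
        links = _links(
            [(f"q{i}", reference_library[i * 3].accession, 0.4) for i in range(3)]
        )
        net = build_network(links, compound_edges(reference_library))
        report = molecular_families(net)
        seen = set()
        for f in report.families:
            assert not (f.members & seen)
            seen |= f.members

    def test_planted_three_family_structure(self, reference_library):
        # one query linked into each planted compound family
        links = _links(
            [(f"q{i}", reference_library[i * 3].accession, 0.5) for i in range(3)]
        )
        net = build_network(links, compound_edges(reference_library),
                            reference_ids=[r.accession for r in reference_library])
        report = molecular_families(net)
        assert report.n_mfs == 3
        assert report.n_query_bgcs == 3
        assert report.n_reference_bgcs == 9

    def test_invalid_min_size(self):
        net = build_network(_links([]), [])
        with pytest.raises(ValueError):
            molecular_families(net, min_size=0)


class TestCompareGrouping:
    @staticmethod
    def _report(queries, refs):
        fam = MolecularFamily(
            members=frozenset(queries) | frozenset(refs),
            query_members=frozenset(queries),
            reference_members=frozenset(refs),
        )
        return MFReport(families=(fam,), reported=(fam,), min_size=1, n_isolated_queries=0)

    @staticmethod
    def _gcf(ids_and_gcfs):
        return pd.DataFrame(
            [(b, g, 100.0) for b, g in ids_and_gcfs], columns=["bgc_id", "gcf_id", "d"]
        )

    def test_identical_grouping_full_intersection(self):
        report = self._report(["q1", "q2"], ["R1"])
        gcf = self._gcf([("q1", "f1"), ("q2", "f1")])
        ref_gcf = self._gcf([("R1", "f1")])
        comp = compare_grouping(report, gcf, ref_gcf)
        assert comp.query_intersection == 2
        assert comp.reference_intersection == 1

    def test_empty_mf_grouping(self):
        report = MFReport(families=(), reported=(), min_size=1, n_isolated_queries=3)
        comp = compare_grouping(report, self._gcf([("q1", "f1")]), self._gcf([("R1", "f1")]))
        assert comp.query_intersection == 0
        assert len(comp.gcf_query_ids) == 1  # GCF still groups q1 with R1

    def test_half_overlapping_schemes(self):
        report = self._report(["q1", "q2"], ["R1"])
        gcf = self._gcf([("q1", "f1"), ("q2", "f2"), ("q3", "f1")])
        ref_gcf = self._gcf([("R1", "f1")])
        comp = compare_grouping(report, gcf, ref_gcf)
        # GCF groups q1 and q3 with R1; MF groups q1 and q2 with R1
        assert comp.gcf_query_ids == {"q1", "q3"}
        assert comp.query_intersection == 1


class TestComponentOracle:
    def test_components_match_union_find_on_random_graphs(self):
        """networkx component counts agree with a union-find oracle."""
        import networkx as nx

        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(5, 200))
            m = int(rng.integers(0, 3 * n))
            edges = [(int(rng.integers(0, n)), int(rng.integers(0, n))) for _ in range(m)]
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            prev_components = n
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for a, b in edges:
                g.add_edge(a, b)
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
                n_comp = len({find(x) for x in range(n)})
                assert nx.number_connected_components(g) == n_comp
                assert n_comp <= prev_components  # edges never split components
                prev_components = n_comp


class TestIOAndConverters:
    def test_reference_round_trip(self, tmp_path, reference_library):
        path = tmp_path / "refs.json"
        write_reference_library(reference_library, path)
        back = read_reference_library(path)
        assert back == list(reference_library)

    def test_mibig_entry_conversion(self):
        entry = {
            "cluster": {
                "mibig_accession": "BGC0000855",
                "organism_name": "Streptomyces anulatus",
                "compounds": [
                    {"chem_struct": "CCO ", "compound": "ethanol-like"},
                    {"compound": "structureless"},
                ],
            }
        }
        ref = from_mibig_entry(entry)
        assert ref.accession == "BGC0000855"
        assert ref.compounds == ("CCO",)
        assert ref.taxon_label == "Streptomyces anulatus"
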