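"""Shared fixtures: small synthetic panels, libraries and regions."""

import pytest

from lichenbgc import synthetic


@pytest.fixture(scope="session")
def strain_panel():
    """3 species x 4 strains, 50 kb genomes; planted within 0.2% / between 8%."""
    return synthetic.generate_strain_panel(
        3, 4, within_rate=0.002, between_rate=0.08, seed=7, genome_length=50_000
    )


@pytest.fixture(scope="session")
def reference_library():
    """3 planted compound families, 3 references each."""
    return synthetic.generate_reference_library(3, 3, seed=5)


@pytest.fixture(scope="session")
def bgc_collection():
    return synthetic.generate_bgc_collection(200, seed=3)


def brute_force_canonical_kmers(sequence: str, k: int) -> set:
    """String-level oracle for the canonical k-mer set of one sequence."""
    comp = str.maketrans("ACGT", "TGCA")
    out = set()
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        if set(kmer) - set("ACGT"):
            continue
        rc = kmer.translate(comp)[::-1]
        out.add(min(kmer, rc))
    return out
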