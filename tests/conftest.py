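import numpy as np
import pytest

import cterminome as ct


@pytest.fixture(scope="session")
def fixture_proteins():
    return ct.load_fixture_proteins()


@pytest.fixture(scope="session")
def fixture_index(fixture_proteins):
    return ct.ProteomeIndex(fixture_proteins)


@pytest.fixture(scope="session")
def truncation_rows():
    """The 14 curated truncation-example peptides (HSP90AB1 + H4)."""
    return ct.load_truncation_examples()


def make_psm(psm_id="p1", replicate="rep1", sequence="ACDK",
             mods=(), intensity=1000.0, score=50.0, charge=2,
             preceding="K", following="A"):
    return ct.PsmRecord(
        psm_id=psm_id, replicate=replicate, sequence=sequence,
        preceding_obs=preceding, following_obs=following,
        modifications=tuple(mods), intensity=intensity, score=score,
        charge=charge)


@pytest.fixture
def psm_factory():
    counter = {"n": 0}

    def _make(**kwargs):
        counter["n"] += 1
        kwargs.setdefault("psm_id", f"auto{counter['n']}")
        return make_psm(**kwargs)

    return _make


@pytest.fixture(scope="session")
def default_sim():
    """One modest default-condition simulation shared across tests."""
    return ct.simulate(ct.SimulationConfig(seed=101, n_proteins=60))


def letter_code(i, width=5, alphabet="ACDEFG"):
    """Deterministic letters-only code for synthetic peptide names."""
    out = []
    for _ in range(width):
        i, r = divmod(i, len(alphabet))
        out.append(alphabet[r])
    return "".join(out)


def random_protein(rng, length, k_rich=True):
    """Random test protein; lysine-enriched so digests are non-trivial."""
    residues = list("ACDEFGHIKLMNPQRSTVWY")
    probs = np.ones(20)
    if k_rich:
        probs[residues.index("K")] = 4.0
        probs[residues.index("P")] = 2.0
    probs /= probs.sum()
    seq = "".join(rng.choice(residues, size=length, p=probs))
    return ct.ProteinRecord(accession=f"T{rng.integers(1e9)}", sequence=seq)
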