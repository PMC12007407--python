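import numpy as np
import pytest

from tetraped.pedigree import Pedigree, PedigreeRecord
from tetraped.simulate import simulate_program, univariate_config


@pytest.fixture
def trio():
    """Two founders and their cross."""
    return Pedigree([PedigreeRecord("A"), PedigreeRecord("B"),
                     PedigreeRecord("C", "A", "B", 2005)])


@pytest.fixture
def family():
    """Founders, full sibs, a selfed line and a half-sib."""
    return Pedigree([
        PedigreeRecord("A"), PedigreeRecord("B"), PedigreeRecord("D"),
        PedigreeRecord("C1", "A", "B", 2004),
        PedigreeRecord("C2", "A", "B", 2004),
        PedigreeRecord("H", "A", "D", 2005),
        PedigreeRecord("S", "A", "A", 2005),
    ])


def random_pedigree(rng: np.random.Generator, n_founders=6, n_extra=20,
                    selfing=0.1, unknown=0.0):
    """Random mating pedigree for property tests (allows selfing and,
    optionally, unknown parents)."""
    recs = [PedigreeRecord(f"F{i}") for i in range(n_founders)]
    ids = [r.id for r in recs]
    for g in range(n_extra):
        if unknown > 0 and rng.random() < unknown:
            p1, p2 = ids[rng.integers(len(ids))], None
        elif rng.random() < selfing:
            p1 = p2 = ids[rng.integers(len(ids))]
        else:
            i1, i2 = rng.choice(len(ids), size=2, replace=False)
            p1, p2 = ids[i1], ids[i2]
        nid = f"X{g}"
        recs.append(PedigreeRecord(nid, p1, p2))
        ids.append(nid)
    return Pedigree(recs)


@pytest.fixture(scope="session")
def small_truth():
    """A small univariate breeding program shared across tests."""
    cfg = univariate_config(n_founders=25, n_cycles=6, crosses_per_cycle=8,
                            progeny_per_cross=5, seed=20)
    return simulate_program(cfg)


@pytest.fixture(scope="session")
def small_truth_bi():
    """A small bivariate breeding program shared across tests."""
    from tetraped.simulate import SimConfig
    cfg = SimConfig(n_founders=20, n_cycles=5, crosses_per_cycle=7,
                    progeny_per_cross=5, seed=21, missing_rate=0.1)
    return simulate_program(cfg)
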