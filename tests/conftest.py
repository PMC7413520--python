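import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import canisnp as cs

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundled():
    return cs.load_bundled_panel()


@pytest.fixture(scope="session")
def panel(bundled):
    return bundled[0]


@pytest.fixture(scope="session")
def freqs(bundled):
    return bundled[1]


@pytest.fixture(scope="session")
def success(bundled):
    return bundled[2]


@pytest.fixture(scope="session")
def reference(freqs):
    """Complete 80-wolf / 90-dog reference simulated from the bundled table."""
    wolf = cs.simulate_population(freqs, cs.SimulationConfig("wolf", 80, seed=11))
    dog = cs.simulate_population(freqs, cs.SimulationConfig("dog", 90, seed=12))
    return cs.GenotypeMatrix.concat([wolf, dog])


def make_matrix(panel, rows, populations):
    """Build a GenotypeMatrix from {individual: [dosages]} and {individual: pop}."""
    ids = list(rows)
    dosage = pd.DataFrame(
        np.array([rows[i] for i in ids], dtype=np.int8), index=ids, columns=panel.locus_ids
    )
    pops = pd.Series([populations[i] for i in ids], index=ids)
    return cs.GenotypeMatrix(panel=panel, dosage=dosage, populations=pops)


def make_freq_table(panel, probs_by_pop, n=100):
    """PopulationFrequencyTable from {pop: [(hom_a, het, hom_b), ...]}."""
    records = []
    for pop, triples in probs_by_pop.items():
        for locus, (ha, he, hb) in zip(panel.locus_ids, triples):
            records.append(
                {
                    "population": pop,
                    "locus_id": locus,
                    "n": n,
                    "hom_a": ha,
                    "het": he,
                    "hom_b": hb,
                    "p_a": ha + he / 2,
                    "p_b": 1 - ha - he / 2,
                }
            )
    table = pd.DataFrame(records).set_index(["population", "locus_id"])
    return cs.PopulationFrequencyTable(panel=panel, table=table)


@pytest.fixture
def toy_panel():
    return cs.PanelDefinition(
        (cs.SnpLocus("L1", "G", "T"), cs.SnpLocus("L2", "C", "A"), cs.SnpLocus("L3", "A", "G"))
    )
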