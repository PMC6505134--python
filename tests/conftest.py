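import numpy as np
import pytest

from regrowqtl.genotypes import (AA, AB, BB, Dataset, GenotypeMatrix,
                                 MarkerLocus, PhenotypeTable)
from regrowqtl.simulate import (CausalModel, Chromosome, GenomeSpec,
                                simulate_f2_population)


@pytest.fixture
def two_by_two():
    """2 plants x 2 markers with the canonical numeric coding example."""
    markers = [MarkerLocus("1", 100, "m1"), MarkerLocus("1", 200, "m2")]
    calls = np.array([[AA, AB], [BB, AA]], dtype=np.int8)
    return GenotypeMatrix(["p1", "p2"], markers, calls)


@pytest.fixture
def informative_sixteen():
    """16 plants at one fully informative marker, phenotype = dominance."""
    plants = [f"p{i:02d}" for i in range(16)]
    markers = [MarkerLocus("1", 1_000_000, "m1")]
    calls = np.array([[AA]] * 4 + [[AB]] * 8 + [[BB]] * 4, dtype=np.int8)
    g = GenotypeMatrix(plants, markers, calls)
    phen = PhenotypeTable({p: ("R" if c[0] != BB else "NR")
                           for p, c in zip(plants, calls)})
    return Dataset(g, phen)


@pytest.fixture(scope="session")
def small_genome():
    """Two 50-Mbp / 50-cM chromosomes, 10 evenly spaced markers each."""
    return GenomeSpec([Chromosome("1", 50_000_000, 50.0),
                       Chromosome("2", 50_000_000, 50.0)],
                      markers_per_chromosome=10)


@pytest.fixture(scope="session")
def small_causal():
    # planted on marker-grid positions so perfectly linked SNPs exist,
    # as they do in dense GBS data
    return CausalModel(loci=(("1", 18_181_818), ("2", 31_818_182)))


@pytest.fixture(scope="session")
def small_f2(small_genome, small_causal):
    """Noise-free 200-plant F2 under the two-locus model (seeded)."""
    return simulate_f2_population(200, small_genome, small_causal,
                                  noise=None, seed=42)
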