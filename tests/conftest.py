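import numpy as np
import pytest

import epiblup as eb


@pytest.fixture(scope="session")
def three_animal_genotypes():
    """Single SNP with calls {2, 1, 0}: observed p = 0.5."""
    return eb.GenotypeMatrix(["a1", "a2", "a3"], ["s1"], np.array([[2], [1], [0]]))


@pytest.fixture(scope="session")
def hwe_dataset():
    """Outbred HWE sample with its additive/dominance/epistatic matrices."""
    g = eb.simulate_genotypes(120, 800, seed=11)
    freqs = eb.allele_frequencies(g)
    ga = eb.additive_grm(g, freqs)
    gd = eb.dominance_grm(g, freqs)
    matrices = {
        "A": ga,
        "D": gd,
        "AA": eb.epistatic_grm(ga, ga, "AA"),
        "AD": eb.epistatic_grm(ga, gd, "AD"),
        "DD": eb.epistatic_grm(gd, gd, "DD"),
    }
    return g, freqs, matrices


@pytest.fixture(scope="session")
def additive_fit(hwe_dataset):
    """MA fit of a trait simulated with additive + residual variance only."""
    g, _, matrices = hwe_dataset
    truth = eb.SimulationTruth({"additive": 0.4, "residual": 0.6}, seed=21)
    pt, effects = eb.simulate_phenotypes(g, truth)
    ds = eb.build_design(pt, eb.model_spec("MA"), matrices)
    fit = eb.fit_reml(ds, eb.model_spec("MA"))
    return pt, effects, fit
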