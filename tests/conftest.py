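import numpy as np
import pandas as pd
import pytest

import halfsib as hs


def make_offspring(sires, bins, outcomes):
    return pd.DataFrame({"sire": sires, "bin": bins, "outcome": outcomes})


@pytest.fixture(scope="session")
def sire_genotypes():
    return hs.load_sire_genotypes()


@pytest.fixture(scope="session")
def study_counts():
    """One fittable count table simulated at the study design with tau2 = 0.5."""
    rng = np.random.default_rng(np.random.SeedSequence(20120807))
    design = hs.study_design(tau2=0.5, seed=0)
    from halfsib.simulation import _draw_counts, _counts_to_frame

    while True:
        s, n = _draw_counts(design, rng)
        if (n.sum(axis=1) > 0).sum() >= 2 and 0 < s.sum() < n.sum():
            return _counts_to_frame(s, n)


@pytest.fixture(scope="session")
def study_offspring(study_counts):
    return hs.expand_counts(study_counts)
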