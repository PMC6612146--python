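import pytest

from fragscore import (FixtureSpec, FragmentAnnotationModel, candidate_from_smiles,
                       make_benchmark)


@pytest.fixture(scope="session")
def ethanol():
    return candidate_from_smiles("CCO", "ethanol")


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark: 30 training molecules (3 replicate
    spectra each), 10 held-out queries with 20 mass-matched decoys, 5 ppm
    jitter, 10% fragment dropout."""
    return make_benchmark(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def fitted(benchmark):
    """Full two-phase training run on the default benchmark."""
    model = FragmentAnnotationModel(benchmark.train_spectra,
                                    benchmark.train_candidates,
                                    mzabs=0.002, mzppm=10.0)
    return model.fit(seed=1)
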