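import pytest

import fermix as fx


@pytest.fixture(scope="session")
def tpc_model():
    """Published special-cubic model for total phenolic content."""
    return fx.load_tpc_model()


@pytest.fixture(scope="session")
def lactic_model():
    """Published special-cubic model for lactic acid concentration."""
    return fx.load_lactic_model()


@pytest.fixture(scope="session")
def sl05_rating():
    """Published rating matrix, weights, grade scores for sample FWJ-SL05."""
    return fx.load_fwj_sl05_rating()


@pytest.fixture(scope="session")
def gcms_table():
    """Transcribed five-sample GC-MS volatile-compound table."""
    return fx.load_gcms_table()


def model_fitness(model):
    """Scalar fitness wrapping a Scheffe model for the optimizers."""
    from fermix.scheffe import predict_many

    def fitness(x):
        return float(predict_many(model, x[None, :])[0])

    return fitness
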