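import numpy as np
import pytest

from eegevent.edf_io import TCP_ELECTRODES, SignalRecord
from eegevent.synthdata import CorpusSpec, generate_record


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def referential_record():
    """A 19-electrode referential record (2 s, 250 Hz) with sinusoids."""
    rng = np.random.default_rng(7)
    n = 500
    t = np.arange(n) / 250.0
    data = np.stack([
        10.0 * np.sin(2 * np.pi * (5 + i) * t) + rng.normal(0, 1, n)
        for i in range(len(TCP_ELECTRODES))
    ])
    return SignalRecord(data, 250.0, list(TCP_ELECTRODES))


@pytest.fixture(scope="session")
def easy_record():
    """One synthetic montaged record with annotations (60 s)."""
    return generate_record(CorpusSpec(seed=11, duration=60.0), 0)


@pytest.fixture(scope="session")
def trained_state(tmp_path_factory):
    """A small trained bundle plus its corpus directory and manifest.

    Session-scoped: several end-to-end tests share this single
    training run to keep the suite fast.
    """
    import json

    from eegevent.pipeline import fast_config, run_train
    from eegevent.synthdata import generate_corpus

    corpus_dir = tmp_path_factory.mktemp("corpus")
    spec = CorpusSpec(n_records=16, duration=60.0, seed=5)
    manifest = generate_corpus(spec, corpus_dir)
    config = fast_config(seed=5)
    bundle = run_train(corpus_dir, config)
    return {"corpus_dir": corpus_dir, "manifest": manifest,
            "bundle": bundle, "config": config, "spec": spec}
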