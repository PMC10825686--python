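import numpy as np
import pytest

from lvqanfis import anfis, synthetic
from lvqanfis.data_io import UCI_DIALECT


@pytest.fixture(scope="session")
def cluster_fixture():
    """Three well-separated feature blobs, each with its own nonlinear
    Sugeno-type map plus output noise — the pipeline's reference conditions."""
    spec = synthetic.SyntheticSpec(seed=1)
    table, truth = synthetic.generate(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def sugeno_1d():
    """A known 1-input, 3-rule Sugeno system and a noiseless sample from it."""
    cfg = anfis.ANFISConfig(seed=11)
    gen = synthetic.make_sugeno_system([(0.0, 10.0)], cfg, seed=11)
    X, y, y_clean = synthetic.sample_sugeno(gen, [(0.0, 10.0)], 300, 0.0, seed=12)
    return gen, X, y, y_clean


@pytest.fixture()
def toy_csv(tmp_path):
    """A 3-row file with all 22 UCI columns."""
    cols = ([UCI_DIALECT["subject_id"], UCI_DIALECT["age"], UCI_DIALECT["sex"],
             UCI_DIALECT["test_time"], UCI_DIALECT["motor"], UCI_DIALECT["total"]]
            + UCI_DIALECT["features"])
    rng = np.random.default_rng(5)
    rows = []
    for i in range(3):
        vals = [i + 1, 65, 0, 10.5 * (i + 1), 20.0 + i, 27.0 + i]
        vals += list(np.round(rng.uniform(0.01, 1.0, 16), 5))
        rows.append(",".join(str(v) for v in vals))
    path = tmp_path / "toy.csv"
    path.write_text(",".join(cols) + "\n" + "\n".join(rows) + "\n")
    return path
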