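import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from qsrr.dataset import QSRRDataset
from qsrr.synthetic import make_planted_instance


def planted_instance(seed: int, n: int = 40, p: int = 20, k: int = 3,
                     noise_sd: float = 0.05, link: str = "rbf_mixture",
                     null: bool = False) -> tuple[QSRRDataset, set[int]]:
    """All-train dataset with k planted informative descriptors."""
    return make_planted_instance(seed, n=n, p=p, k_informative=k,
                                 noise_sd=noise_sd, link=link, null=null)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_csv(tmp_path):
    """3-row descriptor table with 2 descriptors and a k column."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "observation_id,d1,d2,k\n"
        "a,0.1,1.0,0.5\n"
        "b,0.2,2.0,0.7\n"
        "c,0.3,3.0,0.9\n"
    )
    return path
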