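import numpy as np
import pytest

from mpxval.cutoffs import PairedSample
from mpxval.synthetic import default_table4_config, sample_cohort


def pairwise_auc_oracle(pos_scores, neg_scores) -> float:
    """Exhaustive Mann-Whitney U counting: 1 per win, 0.5 per tie."""
    total = 0.0
    for x in pos_scores:
        for y in neg_scores:
            if x > y:
                total += 1.0
            elif x == y:
                total += 0.5
    return total / (len(pos_scores) * len(neg_scores))


def make_pairs(scores, labels):
    return [
        PairedSample(sample_id=f"s{i}", reference_value=float(v), index_result=bool(b))
        for i, (v, b) in enumerate(zip(scores, labels))
    ]


@pytest.fixture
def oracle_auc():
    return pairwise_auc_oracle


@pytest.fixture
def default_cohort():
    """219-patient default-composition cohort, fixed seed."""
    return sample_cohort(default_table4_config(219, seed=2))


@pytest.fixture
def rng():
    return np.random.default_rng(20230522)
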