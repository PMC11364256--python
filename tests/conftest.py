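import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from echoviews.evalmetrics import EvalRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_records(labels, preds, scores):
    return [EvalRecord(clip_id=str(i), true_label=y, predicted_class=p,
                       score=s)
            for i, (y, p, s) in enumerate(zip(labels, preds, scores))]


@pytest.fixture
def five_record_set():
    """Known/unknown toy set: two knowns accepted (one correct), one known
    rejected, one unknown rejected, one unknown accepted at delta = 0.5."""
    labels = [0, 1, 1, "novel_category", "poor_quality"]
    preds = [0, 0, 1, 0, 0]
    scores = [2.0, 1.5, 0.4, 0.3, 1.8]
    return make_records(labels, preds, scores)
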