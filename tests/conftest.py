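import numpy as np
import pytest

from ippm import CandidateTransformList, ExpressionPoint, ExpressionSet


def make_points(
    latencies,
    surprisals=None,
    transform="A",
    hemisphere="left",
    start_hexel=0,
):
    """Build a list of ExpressionPoints from latencies (helper, not a fixture)."""
    if surprisals is None:
        surprisals = [5.0] * len(latencies)
    return [
        ExpressionPoint(
            hexel_id=start_hexel + i,
            transform=transform,
            hemisphere=hemisphere,
            latency_ms=float(l),
            surprisal=float(s),
        )
        for i, (l, s) in enumerate(zip(latencies, surprisals))
    ]


@pytest.fixture
def two_blob_points():
    """50 points ~ N(100, 5^2) + 50 points ~ N(300, 5^2)."""
    rng = np.random.default_rng(42)
    lats = np.concatenate([rng.normal(100, 5, 50), rng.normal(300, 5, 50)])
    surps = 3.0 + rng.exponential(2.0, 100)
    return make_points(lats, surps)


@pytest.fixture
def one_blob_points():
    rng = np.random.default_rng(7)
    lats = rng.normal(100, 5, 50)
    surps = 3.0 + rng.exponential(2.0, 50)
    return make_points(lats, surps)


@pytest.fixture
def simple_ctl():
    return CandidateTransformList(
        parents={"A": ["stream"], "B": ["A"], "C": ["B"]},
        input_streams={"stream"},
    )


def expr_from_points(points, threshold=1.0, n_hexels=10242):
    return ExpressionSet(
        points, n_hexels_per_hemisphere=n_hexels, alpha_threshold_logp=threshold
    )
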