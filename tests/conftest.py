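import math

import numpy as np
import pytest

from homnet import RoiTimeSeries, SlidingWindowSpec, build_lodfcn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_ts(rng, m, r, subject_id="sub"):
    return RoiTimeSeries(subject_id=subject_id, values=rng.standard_normal((m, r)))


@pytest.fixture
def random_dcn(rng):
    """A small random dynamic FC network (R=4, M=40, W=10, s=5 -> K=7)."""
    ts = make_ts(rng, 40, 4)
    return build_lodfcn(ts, SlidingWindowSpec(W=10, s=5))


# ---------------------------------------------------------------------------
# Independent brute-force oracles (plain-Python sums, no shared code paths)


def pearson_brute(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = math.sqrt(sum((x - ma) ** 2 for x in a))
    db = math.sqrt(sum((y - mb) ** 2 for y in b))
    return num / (da * db)


def central_moment_brute(values, d):
    values = list(values)
    k = len(values)
    mean = sum(values) / k
    if d == 1:
        return mean
    s = sum((v - mean) ** d for v in values) / k
    return math.copysign(abs(s) ** (1.0 / d), s)


def lodfcn_brute(ts_values, w, s):
    """Per-window Pearson matrices by direct looping."""
    m, r = ts_values.shape
    k = (m - w) // s + 1
    out = np.empty((k, r, r))
    for win in range(k):
        seg = ts_values[win * s : win * s + w]
        for i in range(r):
            for j in range(r):
                out[win, i, j] = 1.0 if i == j else pearson_brute(seg[:, i], seg[:, j])
    return out
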