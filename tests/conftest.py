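import logging
import warnings

import numpy as np
import pytest

from breathdyn.preprocess import BreathSeries

logging.disable(logging.WARNING)
warnings.filterwarnings("ignore", message="columns left untransformed")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_breath_series(rate, amplitude, start=0.0):
    """BreathSeries from explicit rate/amplitude arrays (times from rates)."""
    rate = np.asarray(rate, dtype=float)
    times = start + np.cumsum(60.0 / rate)
    return BreathSeries(rate=rate, amplitude=np.asarray(amplitude, float),
                        breath_times=times)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)

def sampen_bruteforce(x, m=2, r_factor=0.2):
    """O(n^2) literal template-counting sample entropy."""
    x = list(map(float, x))
    n = len(x)
    sd = float(np.std(x, ddof=1))
    r = r_factor * sd
    T = n - m  # templates whose (m+1)-extension exists
    a = b = 0
    for i in range(T):
        for j in range(T):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def lz76_bruteforce(s: str) -> int:
    """Exhaustive LZ76 parse by naive substring search.

    Phrases are the shortest substrings not seen in the prefix ending one
    character before the phrase's last; a reproducible tail adds nothing.
    """
    n = len(s)
    i = c = 0
    while i < n:
        k = 1
        while i + k <= n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        if i + k > n:
            break
        c += 1
        i += k
    return c


def bh_stepup_bruteforce(p):
    """Literal Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return np.minimum(adj, 1.0)
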