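import numpy as np
import pytest

from asbkit.bad_caller import SnvObservation


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def simulate_observations(bads, n_per_segment, coverage, rng, spacing=1000):
    """Observations from known piecewise BAD, honouring the coverage filter.

    Phasing is drawn per SNV; draws violating 5 <= x <= n - x are redrawn,
    mirroring the upstream per-allele read filter.
    """
    obs, truth = [], []
    pos = 1
    for bad in bads:
        p_major = bad / (bad + 1.0)
        for _ in range(n_per_segment):
            p_ref = p_major if rng.random() < 0.5 else 1.0 - p_major
            while True:
                c = int(rng.binomial(coverage, p_ref))
                if 5 <= min(c, coverage - c):
                    break
            obs.append(SnvObservation(pos, min(c, coverage - c), coverage))
            truth.append(bad)
            pos += spacing
    return obs, truth


@pytest.fixture
def piecewise_observations(rng):
    return simulate_observations([1.0, 2.0], 50, 40, rng)
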