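import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mdint.shell_model import Shell, ShellPair, random_shell

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def rand_shell(l, K, seed, sep=1.0):
    return random_shell(l, K, seed=seed, center_scale=sep)


def rand_pair(l1, l2, K1, K2, seed, sep=1.0):
    a = rand_shell(l1, K1, seed, sep)
    b = rand_shell(l2, K2, seed + 7919, sep)
    return ShellPair.from_shells(a, b)


def rel_dev(got, want, floor=None):
    """Max entrywise relative deviation with a block-scale floor.

    Entries more than four decades below the block maximum are measured
    against that floor: a signed-contraction cancellation can leave a tiny
    net entry whose entrywise ratio reflects reassociation noise rather than
    the algebraic identity under test.
    """
    got, want = np.asarray(got), np.asarray(want)
    if floor is None:
        floor = max(1e-12, 1e-4 * float(np.max(np.abs(want), initial=0.0)))
    denom = np.maximum(np.abs(want), floor)
    return float(np.max(np.abs(got - want) / denom))


def scale_dev(got, want):
    """Max deviation relative to the largest magnitude in the batch.

    The measure for exact-rearrangement identities: both routes sum the same
    primitive contributions in different orders, so their difference is
    bounded by reassociation noise at the scale of the largest contribution,
    not of each (possibly cancellation-suppressed) entry.
    """
    got, want = np.asarray(got), np.asarray(want)
    scale = float(np.max(np.abs(want), initial=0.0)) or 1.0
    return float(np.max(np.abs(got - want))) / scale


@pytest.fixture(scope="session", autouse=True)
def _warm_boys_table():
    # build the shared Chebyshev table once for the whole session
    from mdint.boys import get_table

    get_table(25)


@pytest.fixture
def ss_pair():
    s = Shell(np.zeros(3), 0, np.array([1.0]), np.array([1.0]))
    return ShellPair.from_shells(s, s)
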