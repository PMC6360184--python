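"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pytest

from famvar.simulate import (
    SimulationSpec,
    simulate_annotations,
    simulate_family,
)

#: Desk-scale variant count used by most tests (the full-scale default is
#: exercised by the acceptance script).
SMALL_N = 400


def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Exact integer arithmetic: point probabilities share the denominator
    C(n, c1), so the inclusion rule (point probability at most the observed
    one, with the same 1e-7 relative tie guard as the implementation)
    reduces to an integer comparison on numerators. Independent of the
    implementation's floating-point route.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    obs = nums[a - lo]
    t = 10**7
    kept = sum(v for v in nums if v * t <= obs * (t + 1))
    return Fraction(kept, comb(n, c1))


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    return SimulationSpec(seed=1, n_background_variants=SMALL_N)


@pytest.fixture(scope="session")
def family(small_spec):
    return simulate_family(small_spec)


@pytest.fixture(scope="session")
def annotations(family):
    return simulate_annotations(family.truth)
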