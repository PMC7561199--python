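import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mosaicamp import synthetic_reference

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_and_target():
    return synthetic_reference()


@pytest.fixture(scope="session")
def reference(reference_and_target):
    return reference_and_target[0]


@pytest.fixture(scope="session")
def target(reference_and_target):
    return reference_and_target[1]


@pytest.fixture(scope="session")
def brute_force_score():
    """Exhaustive alignment-score oracle: enumerates every global alignment of
    two short strings recursively and returns the best affine-gap score.  A
    gap run of length g scores gap_open + g * gap_extend; switching between
    gap types re-opens."""

    def oracle(read: str, ref: str, scoring) -> float:
        best = -np.inf

        def rec(i: int, j: int, last: str, score: float) -> None:
            nonlocal best
            if i == len(read) and j == len(ref):
                best = max(best, score)
                return
            if i < len(read) and j < len(ref):
                s = scoring.match if read[i] == ref[j] else scoring.mismatch
                rec(i + 1, j + 1, "M", score + s)
            if j < len(ref):
                extra = scoring.gap_extend + (0 if last == "D" else scoring.gap_open)
                rec(i, j + 1, "D", score + extra)
            if i < len(read):
                extra = scoring.gap_extend + (0 if last == "I" else scoring.gap_open)
                rec(i + 1, j, "I", score + extra)

        rec(0, 0, "", 0.0)
        return best

    return oracle
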