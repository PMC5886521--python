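import pytest
from hypothesis import HealthCheck, settings

from rexscan.pattern import compile_pattern

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: independent base-complement table for oracle checks (not the package's)
ORACLE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def independent_rule_check(window: str) -> bool:
    """Three-clause operator predicate, coded independently of the
    package's matcher: (1) arm 1 is W-T-G-W-W; (2) the 8-bp spacer has
    at most one G/C; (3) arm 2 equals the reverse complement of arm 1
    except for at most one mismatch at its last two positions."""
    w = window.upper()
    arm1, spacer, arm2 = w[:5], w[5:13], w[13:]
    clause1 = (
        arm1[1] == "T"
        and arm1[2] == "G"
        and all(arm1[i] in "AT" for i in (0, 3, 4))
    )
    clause2 = sum(b in "CG" for b in spacer) <= 1
    expected = "".join(ORACLE_COMPLEMENT[b] for b in reversed(arm1))
    mismatches = [i for i in range(5) if arm2[i] != expected[i]]
    clause3 = not mismatches or (len(mismatches) == 1 and mismatches[0] in (3, 4))
    return clause1 and clause2 and clause3


@pytest.fixture(scope="session")
def union_pattern():
    return compile_pattern("paper-union")


@pytest.fixture(scope="session")
def exact_pattern():
    return compile_pattern("WTGWW{WWWWWWWW}-5-4-3-2-1")
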