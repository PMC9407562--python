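import pytest

from mpspheno.panel import Thresholds, default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


def balanced_counts(marker, combined):
    """Combined token counts spread evenly over both strands."""
    from mpspheno.calling import StrandBaseCounts

    plus = {t: n // 2 for t, n in combined.items()}
    minus = {t: n - n // 2 for t, n in combined.items()}
    return StrandBaseCounts(marker, plus, minus)
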