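import random

import pytest

from amplitrim import (
    AmpliconPanel,
    AmpliconPrimer,
    MatchParams,
    TrimParams,
    build_index,
)


def random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)


@pytest.fixture
def small_panel() -> AmpliconPanel:
    """Two well-separated amplicons, hand-picked, insert lengths chosen so
    a 150 bp read shows both the read-through and the normal geometry."""
    return AmpliconPanel(
        [
            AmpliconPrimer(
                "ampA",
                "ACGTACCATGGATCCGATCA",  # 20 bp
                "TGGACCAGTTGAATCCAGGT",  # 20 bp
                110,
            ),
            AmpliconPrimer(
                "ampB",
                "CCTTAGGACAGCAATTCGGAT",  # 21 bp
                "GATTACAGGCGTGAGCCACC",  # 20 bp
                200,
            ),
        ]
    )


@pytest.fixture
def small_index(small_panel):
    return build_index(small_panel, k=8)


@pytest.fixture
def match_params() -> MatchParams:
    return MatchParams(k=8, max_mismatch=3)


@pytest.fixture
def trim_params(match_params) -> TrimParams:
    return TrimParams(match_params=match_params)
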