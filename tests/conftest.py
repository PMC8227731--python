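"""Shared fixtures: small PWM libraries and synthetic corpora.

All fixture data is generated programmatically so tests are self-contained.
"""

from __future__ import annotations

import numpy as np
import pytest

from tfcoop.benchmarks import BENCHMARK_CONSENSI, benchmark_library, benchmark_pwm
from tfcoop.motif_library import PWM

CONSENSI = list(BENCHMARK_CONSENSI)
make_pwm = benchmark_pwm
fixture_library = benchmark_library


@pytest.fixture
def pwm_library() -> list[PWM]:
    return fixture_library()


@pytest.fixture
def simple_pwm() -> PWM:
    """Length-6 PWM with a sharp 5-bp core at positions 1..5."""
    counts = np.array(
        [
            [6, 6, 7, 6],  # near-uniform
            [25, 0, 0, 0],
            [0, 25, 0, 0],
            [0, 0, 25, 0],
            [0, 0, 0, 25],
            [25, 0, 0, 0],
        ]
    )
    return PWM("MSIMPLE", "SIMPLE", counts)
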