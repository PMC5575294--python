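"""Shared fixtures: small synthetic scenarios and corrected stacks."""

from __future__ import annotations

import numpy as np
import pytest

from depotflow import imaging as I
from depotflow import synthetic as S


def correct_stack(scen: S.ScenarioConfig):
    """Generate a scenario and flat-field correct it to transmission."""
    stack, truth, manifest = S.generate_stack(scen)
    _, _, flat = S.render_flat_field(scen)
    trans = np.stack([I.flat_field_correct(f, flat).filled(np.nan) for f in stack.frames])
    corrected = I.ImageStack(
        frames=trans,
        timestamps=stack.timestamps,
        pixel_size_um=stack.pixel_size_um,
        field_of_view_mm=stack.field_of_view_mm,
    )
    return corrected, truth, manifest


@pytest.fixture(scope="session")
def slow100_noiseless():
    scen = S.preset_scenario("slow-100", seed=11, noiseless=True)
    return scen, *correct_stack(scen)


@pytest.fixture(scope="session")
def slow100_noisy():
    scen = S.preset_scenario("slow-100", seed=11)
    return scen, *correct_stack(scen)
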