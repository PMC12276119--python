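import dataclasses

import pytest

from imsquant import AxisSpec, CompoundSpec, ResponseModel, example_compounds


@pytest.fixture
def small_axes() -> AxisSpec:
    """Compact grid around the 2-hexanone retention window, for fast renders."""
    return AxisSpec(rt_start=900.0, rt_stop=1060.0, rt_step=2.0)


@pytest.fixture
def hexanone() -> CompoundSpec:
    return example_compounds()["2-hexanone"]


@pytest.fixture
def hexanone_noise_free(hexanone) -> CompoundSpec:
    model = dataclasses.replace(hexanone.model, noise_sd=0.0)
    return dataclasses.replace(hexanone, model=model)


def make_compound(
    rt: float = 980.0,
    dt_m: float = 1.19,
    dt_d: float = 1.47,
    **model_kwargs,
) -> CompoundSpec:
    return CompoundSpec(
        "test", rt, dt_m, dt_d, model=ResponseModel(**model_kwargs)
    )
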