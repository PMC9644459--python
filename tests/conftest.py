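from __future__ import annotations

import pytest

from devicemcda import load_default_tool, load_first_workshop_tool
from devicemcda.model import CriteriaConfig
from devicemcda.scoring import DeviceProfile


@pytest.fixture(scope="session")
def default_tool() -> CriteriaConfig:
    return load_default_tool()


@pytest.fixture(scope="session")
def interim_tool() -> CriteriaConfig:
    return load_first_workshop_tool()


def top_profile(config: CriteriaConfig, device_id: str = "top") -> DeviceProfile:
    """A device selecting the highest-scoring option on every criterion."""
    return DeviceProfile(
        device_id=device_id,
        supplier_id="s1",
        evidence={c.criterion_id: c.top_option.option_id for c in config.criteria},
        is_local_product=True,
    )


def profile_from_options(
    config: CriteriaConfig, options: dict[str, str], device_id: str = "dev",
    price: float | None = None,
) -> DeviceProfile:
    return DeviceProfile(
        device_id=device_id,
        evidence=dict(options),
        is_local_product=True,
        price=price,
    )
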