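import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from mmcoast import (
    CohortSpec,
    NormBand,
    NormativeTable,
    generate,
    toy_charts,
)


@pytest.fixture(scope="session")
def band():
    """A simple force band: mean 30 lb, SD 5, higher is better."""
    return NormBand("elbow_flexion", "any", 6, 80, "any", 30.0, 5.0, +1, unit="lb")


@pytest.fixture(scope="session")
def timed_band():
    """A timed-test band: mean 20 s, SD 2.5, lower is better."""
    return NormBand("ninehpt", "any", 6, 80, "any", 20.0, 2.5, -1, unit="s")


@pytest.fixture(scope="session")
def small_table():
    """Hand-built table with age structure, an SD-zero band and sexes."""
    return NormativeTable(
        [
            NormBand("elbow_flexion", "any", 6, 16, "any", 20.0, 4.0, +1, unit="lb"),
            NormBand("elbow_flexion", "any", 16, 18, "any", 28.0, 5.0, +1, unit="lb"),
            NormBand("elbow_flexion", "any", 18, 80, "any", 30.0, 5.0, +1, unit="lb"),
            NormBand("wrist_extension", "any", 6, 80, "any", 25.0, 4.0, +1, unit="lb"),
            NormBand("ninehpt", "any", 6, 80, "any", 20.0, 2.5, -1, unit="s"),
            NormBand(
                "ts_eyes_open", "any", 6, 80, "any", 10.0, 0.0, +1,
                ceiling=10.0, unit="s",
            ),
            NormBand("sts30", "male", 6, 80, "any", 15.0, 3.0, +1, unit="count"),
            NormBand("sts30", "female", 6, 80, "any", 14.0, 3.0, +1, unit="count"),
        ]
    )


@pytest.fixture(scope="session")
def charts():
    return toy_charts()


@pytest.fixture(scope="session")
def cohort():
    """One mid-sized synthetic cohort reused across tests."""
    spec = CohortSpec(n_per_group={"mm": 40, "unlikely": 25, "healthy": 20})
    return generate(spec, seed=20240901)
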