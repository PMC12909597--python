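import pytest

from txtime import (
    EnergyLayer,
    LineSegment,
    MachineSpec,
    PlanGenSpec,
    RespiratoryModel,
    generate_plan,
)

# The worked five-segment 189.6 MeV layer used throughout: uniform 0.6 cm
# segments whose MU span (0.0010..0.0198) gives an intrinsic dynamic range
# of 19.8, so DR = 10 elevates exactly two segments.
WORKED_MUS = (0.0013, 0.0198, 0.0178, 0.0056, 0.0010)


@pytest.fixture
def worked_layer() -> EnergyLayer:
    return EnergyLayer(
        energy=189.6,
        segments=tuple(LineSegment(mu=m, length=0.6) for m in WORKED_MUS),
    )


@pytest.fixture
def machine() -> MachineSpec:
    return MachineSpec(speed_max=2000.0, t_ls=2.0)


@pytest.fixture
def resp_model() -> RespiratoryModel:
    return RespiratoryModel(period=4.0)


@pytest.fixture
def small_plan():
    """3-field, ~20-layer synthetic plan, small enough for fast round-trips."""
    return generate_plan(
        PlanGenSpec(
            n_fields=3,
            n_layers=(5, 8),
            segments_per_layer=(10, 30),
            seed=7,
        )
    )
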