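import pytest

from pefreseal import (
    AnchorSet,
    UptakeConstants,
    WallPoreParams,
    calibrate_from_anchors,
)


@pytest.fixture(scope="session")
def constants() -> UptakeConstants:
    """Standard capacity constants: N_m = 0.5 uM, N_s = 1 uM."""
    return UptakeConstants(N_m=0.5, N_s=1.0)


@pytest.fixture(scope="session")
def anchors() -> AnchorSet:
    """Printed anchor ratios: baseline 0.12, zero-delay 0.65, 180 s, tau_d 24 s."""
    return AnchorSet()


@pytest.fixture(scope="session")
def calibration(anchors, constants):
    return calibrate_from_anchors(anchors, constants)


@pytest.fixture(scope="session")
def wall_reference(calibration) -> WallPoreParams:
    """Wall parameters at the reference (highest) field strength."""
    return WallPoreParams(
        k_a0=calibration.k_a0, A=calibration.A_reference, tau_d=24.0
    )
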