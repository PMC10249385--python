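import numpy as np
import pytest

from gcretention import ABCParams, ColumnSpec, FlowConditions, KCentricParams


@pytest.fixture
def cinnamaldehyde_abc() -> ABCParams:
    """Published Clarke–Glew coefficients for cinnamaldehyde on Rxi17SilMS
    (phase ratio 250, film thickness ratio 0.001)."""
    return ABCParams(A=-82.062, B=10505.0, C=10.503, beta0=250.0)


@pytest.fixture
def standard_column() -> ColumnSpec:
    """30 m x 0.25 mm x 0.25 um column (beta = 250)."""
    return ColumnSpec(L=30.0, d=0.25e-3, df=0.25e-6, phase="Rxi17SilMS")


@pytest.fixture
def constant_flow() -> FlowConditions:
    """Helium at a constant 1 mL/min (reference state), ambient outlet."""
    return FlowConditions(gas="helium", mode="flow", flow=1e-6 / 60.0, p_o=101325.0)


@pytest.fixture
def true_kcentric() -> KCentricParams:
    return KCentricParams(Tchar=400.0, thetachar=30.0, dCp=100.0, beta0=250.0)
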