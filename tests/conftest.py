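import numpy as np
import pytest

from stabscan import FitConfig, analyze_curve, load_reference_fits
from stabscan.simulate import CurveSpec, simulate_curve


@pytest.fixture(scope="session")
def reference_fits():
    """Measured AR-LBD fit parameters (WT + four AIS mutants)."""
    return load_reference_fits().set_index("sample_id")


def fit_noiseless(dg0, m_value, sample_id="sim", noise_sd=0.0, seed=0):
    """Simulate a curve from (dg0, m) and run the full LEM chain on it.

    The generator's true baselines are passed to the analysis, so at zero
    noise this composition is an exact round trip.
    """
    spec = CurveSpec(
        dg0=dg0, m_value=m_value, sample_id=sample_id,
        noise_sd=noise_sd, seed=seed,
    )
    curve = simulate_curve(spec)
    config = FitConfig(
        theta_folded=spec.theta_folded, theta_unfolded=spec.theta_unfolded
    )
    fit, audit = analyze_curve(curve, config)
    return fit, audit


def ols_closed_form(x, y):
    """Independent two-parameter least-squares oracle (normal equations)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    return intercept, slope
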