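import numpy as np
import pytest

import phenoplate as pp
from phenoplate import synthetic_plate as sp


@pytest.fixture(scope="session")
def published_model():
    return pp.PUBLISHED_CALIBRATION


@pytest.fixture(scope="session")
def logistic_reference():
    """Noiseless logistic curve (N0=0.05, K=5, r=0.01/min) on a 10-min grid."""
    t = np.arange(0.0, 2500.0, 10.0)
    N0, K, r = 0.05, 5.0, 0.01
    N = K / (1.0 + (K - N0) / N0 * np.exp(-r * t))
    curve = pp.log_transform(N, t, init_cycles=1)
    return {"times": t, "N": N, "N0": N0, "K": K, "r": r, "curve": curve}


def gompertz_curve(spec: sp.WellSimSpec, t_end: float | None = None, dt: float = 10.0):
    """Noiseless observed log-ratio curve for a simulator spec."""
    if t_end is None:
        t_end = spec.lag_lambda + 8.0 * spec.asym_A / spec.mu_max
    t = np.arange(0.0, t_end, dt)
    od = sp.true_od_series(spec, t)
    return pp.log_transform(od, t, init_cycles=1)


@pytest.fixture(scope="session")
def small_screen():
    """A 3-genotype toxic screen at default noise, with its ground truth."""
    design = sp.ScreenDesign(
        genotypes={
            "empty": sp.WellSimSpec(),
            "lineA": sp.WellSimSpec(lag_lambda=350.0, mu_max=0.009, asym_A=3.8),
            "lineB": sp.WellSimSpec(lag_lambda=250.0, mu_max=0.011, asym_A=4.0),
        },
        treatment=sp.TreatmentEffectModel(
            kind="toxic",
            on_lambda=sp.HillEffect(emax=1.0, ec50=1.0),
            on_mu=sp.HillEffect(emax=0.5, ec50=1.0),
            on_kappa=sp.HillEffect(emax=0.3, ec50=1.0),
        ),
        treatment_name="oxidant",
        doses=(0.0, 0.5, 1.0),
        replicates=3,
    )
    noise = sp.NoiseSpec(seed=7)
    series, pm = sp.simulate_screen(design, pp.PUBLISHED_CALIBRATION, noise)
    return {"design": design, "noise": noise, "series": series, "plate_map": pm}
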