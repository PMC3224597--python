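"""Shared fixtures: small grids, clean Lorentzian standards, a synthetic NSSD."""

import numpy as np
import pytest

from nmrmixsim import SimulationParameters, StandardSpectrum
from nmrmixsim.synthetic_standards import (
    LorentzianSpec,
    MultipletShape,
    make_lorentzian_standard,
    make_synthetic_nssd,
)


@pytest.fixture
def small_params():
    """Fast parameter set on a 4096-point grid, noise-free, shifts off."""
    return SimulationParameters(
        n_replicates=5,
        n_points=4096,
        snr=float("inf"),
        shift_enabled=False,
        rng_seed=123,
    )


@pytest.fixture
def grid4k():
    return np.linspace(-0.5, 10.0, 4096)


@pytest.fixture
def singlet_spectrum(grid4k):
    """One clean symmetric Lorentzian singlet at 3.0 ppm."""
    spec = LorentzianSpec(
        multiplets=[MultipletShape(centre=3.0, j_spacing=0.0, half_width=0.004)]
    )
    spectrum, truth = make_lorentzian_standard(spec, grid4k, metabolite_id="singlet")
    return spectrum, truth


@pytest.fixture
def triplet_spectrum(grid4k):
    """A 1:2:1 triplet at 2.5 ppm with 0.02 ppm line spacing."""
    spec = LorentzianSpec(
        multiplets=[
            MultipletShape(centre=2.5, j_spacing=0.02, weights=(1.0, 2.0, 1.0),
                           half_width=0.003)
        ]
    )
    spectrum, truth = make_lorentzian_standard(spec, grid4k, metabolite_id="triplet")
    return spectrum, truth


@pytest.fixture(scope="session")
def synthetic_nssd(tmp_path_factory):
    """A 4-metabolite synthetic database written once per session."""
    out = tmp_path_factory.mktemp("nssd")
    truths = make_synthetic_nssd(
        4, 42, out, grid=np.linspace(-0.5, 10.0, 4096)
    )
    return out, truths


def constant_spectrum(value: float, grid: np.ndarray, name: str = "const") -> StandardSpectrum:
    return StandardSpectrum(name, "expt1", grid, np.full(grid.size, float(value)))
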