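import numpy as np
import pytest

import chromachoice as cc


@pytest.fixture(scope="session")
def grid():
    return cc.WORKING_GRID


@pytest.fixture(scope="session")
def tetra_vs():
    """Synthetic goose-like tetrachromat, fixed seed."""
    return cc.synth_visual_system(n_cones=4, seed=0)


@pytest.fixture(scope="session")
def clear_sky():
    return cc.synth_sky("clear", seed=0)


@pytest.fixture(scope="session")
def cloudy_sky():
    return cc.synth_sky("cloudy", seed=0)


@pytest.fixture(scope="session")
def choice_df():
    """A study-sized synthetic trial table with PCA1 attached."""
    from chromachoice.choice import attach_pca1

    return attach_pca1(cc.synth_choice_dataset(cc.ChoiceSimParams(seed=3)))


def random_spectrum(rng, n=50, unit="photon_flux", lo=300.0, hi=700.0):
    wl = np.sort(rng.uniform(lo, hi, n))
    wl += np.arange(n) * 1e-6  # enforce strict monotonicity
    return cc.Spectrum(wl, rng.uniform(0.1, 10.0, n), unit=unit)


def dichromat(e1=0.1, e2=0.2):
    """A minimal two-cone system with transparent droplets and no ocular filter."""
    from chromachoice.visual import ConeClass, OilDroplet, VisualSystem

    # densities chosen so receptor_noise gives exactly (e1, e2) with omega=e1<=e2
    d1, d2 = 1.0, (e1 / e2) ** 2
    cones = (
        ConeClass("S", 450.0, OilDroplet(), d1),
        ConeClass("L", 600.0, OilDroplet(), d2),
    )
    return VisualSystem(cones=cones, ocular=None, weber_fraction=e1)
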