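"""Shared fixtures: the reference operating points of the channel model."""

import numpy as np
import pytest

import ternaflow as tf

# velocity figure baseline: alpha=0.5, tau=1, phi_hnf=0.02 (equal split),
# Pr=21, Re=1.2, Gr=4, G=2, lambda=3, beta=1.2
BASELINE = dict(alpha=0.5, beta_casson=1.2, lam=3.0, G=2.0, Gr=4.0,
                Pr=21.0, Re=1.2)


def make_params(phi=0.02, materials=tf.DEFAULT_MATERIALS, **over):
    kw = dict(BASELINE)
    kw.update(over)
    mix = tf.assemble_mixture(phi / 3, phi / 3, phi / 3, materials)
    return mix, tf.dimensionless_groups(mix, **kw)


@pytest.fixture(scope="session")
def baseline():
    mix, params = make_params()
    return mix, params


@pytest.fixture(scope="session")
def pure_fluid():
    mix, params = make_params(phi=0.0)
    return mix, params


@pytest.fixture
def xi_grid():
    return np.linspace(0.0, 1.0, 21)
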