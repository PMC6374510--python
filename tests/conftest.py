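import numpy as np
import pytest

from micelle_ensemble import (MicelleSpec, SaxsConfig, analytic_shape,
                              assemble_micelle, build_surfactant,
                              debye_intensity)


@pytest.fixture(scope="session")
def default_spec():
    return MicelleSpec()


@pytest.fixture(scope="session")
def ideal_micelle(default_spec):
    return assemble_micelle(default_spec)


@pytest.fixture(scope="session")
def surfactant(default_spec):
    return build_surfactant(default_spec)


@pytest.fixture(scope="session")
def vacuum_cfg():
    """No solvent, no shell: bead amplitudes reduce to bare form factors."""
    return SaxsConfig(n_q=64, solvent_density=0.0, shell_contrast=0.0)


@pytest.fixture(scope="session")
def sphere_r12():
    """~1200-bead jittered-grid ball of radius 12 Å (analytic oracle)."""
    return analytic_shape("solid_sphere", radius=12.0, spacing=1.8, rng_seed=3)


@pytest.fixture(scope="session")
def sphere_r12_profile(sphere_r12, vacuum_cfg):
    return debye_intensity(sphere_r12, vacuum_cfg)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced bead counts: fast frames for trajectory-level tests."""
    return MicelleSpec(tail_length_beads=1, head_arm_beads=2,
                       perturbation_sigma=0.3)
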