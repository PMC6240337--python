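import numpy as np
import pytest

from molshape import EFACoefficients, Outline, efa_inverse


def make_circle(n: int = 1024, r: float = 1.0, center=(0.0, 0.0),
                label: str = "circle") -> Outline:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Outline(np.column_stack([center[0] + r * np.cos(t),
                                    center[1] + r * np.sin(t)]), label=label)


def make_blob_coeffs(seed: int, n_harmonics: int = 8, amp: float = 0.25,
                     label: str = "blob") -> EFACoefficients:
    """Random smooth closed blob: dominant first harmonic plus decaying
    low-frequency perturbations (always a valid simple curve)."""
    rng = np.random.default_rng(seed)
    decay = amp / np.arange(2, n_harmonics + 1) ** 1.5
    a = np.r_[2.0, decay * rng.standard_normal(n_harmonics - 1)]
    b = np.r_[0.3, decay * rng.standard_normal(n_harmonics - 1)]
    c = np.r_[-0.2, decay * rng.standard_normal(n_harmonics - 1)]
    d = np.r_[1.4, decay * rng.standard_normal(n_harmonics - 1)]
    return EFACoefficients(a, b, c, d, dc=(0.5, -0.3), label=label)


def make_blob(seed: int, n_points: int = 360, n_harmonics: int = 8,
              amp: float = 0.25) -> Outline:
    return efa_inverse(make_blob_coeffs(seed, n_harmonics, amp), n_points)


@pytest.fixture
def circle_outline():
    return make_circle


@pytest.fixture
def blob_outline():
    return make_blob


@pytest.fixture
def blob_coeffs():
    return make_blob_coeffs
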