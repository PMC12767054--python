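import numpy as np
import pytest

from sparseffr.contours import RawCell, align_contour, resample_contour


def make_egg(n=100, scale=1.0, rot=0.0, shift=(0.0, 0.0)):
    """Asymmetric smooth closed curve (unambiguous principal axis and
    third moments), optionally rigidly transformed."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([
        3 * np.cos(th) + 0.5 * np.cos(2 * th),
        np.sin(th) + 0.3 * np.sin(2 * th) + 0.15 * np.cos(2 * th),
    ]) * scale
    R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
    return pts @ R.T + np.asarray(shift, float)


def make_star(n=100, k=5, amp=0.3):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = 1 + amp * np.cos(k * th)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


@pytest.fixture
def egg_contour():
    return align_contour(resample_contour(RawCell("egg", 0.0, make_egg()), K=100))


@pytest.fixture
def unit_square_cell():
    return RawCell("sq", 0.0, np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))


class AnalyticForceField:
    """Test double: analytic force field with the ForceField interface."""

    def __init__(self, f, D, jac=None):
        self.f = f
        self.D = float(D)
        self._jac = jac

    def __call__(self, x):
        return self.f(x)

    def force(self, x):
        return self.f(x)

    def with_D(self, D):
        return AnalyticForceField(self.f, D, self._jac)

    def jacobian(self, x):
        if self._jac is not None:
            return self._jac(np.asarray(x, float))
        from sparseffr.field import _fd_jacobian

        return _fd_jacobian(self.f, np.asarray(x, float))


@pytest.fixture
def linear_ff():
    def make(A, D):
        A = np.asarray(A, float)
        return AnalyticForceField(
            lambda x: np.atleast_2d(x) @ A.T, D, jac=lambda x: A.copy()
        )

    return make
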