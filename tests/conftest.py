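import numpy as np
import pytest

from medspectralnet import autograd as ag


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_grad(fn, x, eps=1e-6):
    """Central finite differences of a scalar-valued fn() w.r.t. array x (in place)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = fn()
        x[i] -= 2 * eps
        fm = fn()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_gradcheck(make_output, tensors, rng, tol=1e-5):
    """Check autograd gradients of make_output() against finite differences.

    ``make_output`` must rebuild the graph from the leaf ``tensors`` (float64)
    on every call.
    """
    out = make_output()
    weights = rng.standard_normal(out.data.shape)

    def scalar():
        return float((make_output().data * weights).sum())

    for t in tensors:
        t.grad = None
    make_output().backward(weights)
    for t in tensors:
        num = numeric_grad(scalar, t.data)
        assert t.grad is not None, "missing gradient"
        scale = max(1.0, np.abs(num).max())
        np.testing.assert_allclose(t.grad, num, atol=tol * scale,
                                   err_msg="analytic vs numeric gradient mismatch")
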