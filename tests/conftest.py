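import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_fixture():
    """12-row (genotype, trichotomous outcome) fixture for oracle checks."""
    g = np.array([0, 0, 0, 1, 1, 1, 2, 2, 0, 1, 2, 0], float)
    y = np.array([0, 0, 1, 0, 1, 2, 2, 2, 2, 0, 1, 1])
    return g, y


def refine_grid_loglik(loglik_fn, n_free, lo=-4.0, hi=4.0, coarse=17, levels=6):
    """Independent grid-search maximizer: iteratively refined lattice.

    Evaluates ``loglik_fn`` (vectorized over a (M, n_free) parameter array)
    on a coarse lattice, then repeatedly re-grids around the incumbent with
    a shrinking span.  Reaches an effective step well below 1e-3 without
    gradient information.
    """
    center = np.zeros(n_free)
    span = (hi - lo) / 2.0
    best_ll = -np.inf
    best = center
    for _ in range(levels):
        axes = [np.linspace(c - span, c + span, coarse) for c in center]
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, n_free)
        ll = loglik_fn(mesh)
        i = int(np.argmax(ll))
        if ll[i] > best_ll:
            best_ll = float(ll[i])
            best = mesh[i]
        center = mesh[i]
        span = span * 2.2 / (coarse - 1)  # keep neighbours of the incumbent
    return best_ll, best


def trinomial_loglik_vec(g, y, model):
    """Vectorized trinomial loglik over a parameter lattice, by direct sums.

    Parameter layout per model: null (a1, a2); basic (a1, a2, b);
    subset (a1, a2, b+); inverse_subset (a1, a2, b-); general
    (a1, a2, b-, b+); modifier (a, c, gamma).
    """
    g = np.asarray(g, float)
    y = np.asarray(y)

    def fn(theta):
        theta = np.atleast_2d(theta)
        a1 = theta[:, 0:1]
        if model == "modifier":
            a, c, gam = theta[:, 0:1], theta[:, 1:2], theta[:, 2:3]
            case = (y > 0).astype(float)
            ll_margin = (case[None, :] * a - np.logaddexp(0.0, a)).sum(1)
            mask = y > 0
            eta = c + gam * g[None, mask]
            s = (y[mask] == 2).astype(float)
            ll_sym = (s[None, :] * eta - np.logaddexp(0.0, eta)).sum(1)
            return ll_margin + ll_sym
        a2 = theta[:, 1:2]
        if model == "null":
            b1 = b2 = np.zeros_like(a1)
        elif model == "basic":
            b1 = b2 = theta[:, 2:3]
        elif model == "subset":
            b1, b2 = np.zeros_like(a1), theta[:, 2:3]
        elif model == "inverse_subset":
            b1, b2 = theta[:, 2:3], np.zeros_like(a1)
        elif model == "general":
            b1, b2 = theta[:, 2:3], theta[:, 3:4]
        else:
            raise ValueError(model)
        eta1 = a1 + b1 * g[None, :]
        eta2 = a2 + b2 * g[None, :]
        denom = np.logaddexp(0.0, np.logaddexp(eta1, eta2))
        pick = np.where(y[None, :] == 0, -denom,
                        np.where(y[None, :] == 1, eta1 - denom, eta2 - denom))
        return pick.sum(1)

    return fn


MODEL_FREE_PARAMS = {"null": 2, "basic": 3, "subset": 3, "inverse_subset": 3,
                     "general": 4, "modifier": 3}
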