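"""EM fitting of a three-state beta mixture to methylation beta values.

Array beta values are well described by a mixture of unmethylated (U),
hemimethylated (H) and methylated (M) states, each a Beta(a, b) density.
The fit drives beta-mixture quantile normalisation: state membership and
state-wise CDFs are what the normalisation maps between probe chemistries.

The M-step maximises the weighted beta log-likelihood per component
(numerically, in log-shape space), so the observed-data log-likelihood is
non-decreasing across iterations up to optimiser tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from ..errors import DegenerateInputError, ValidationError

__all__ = ["BetaMixture", "fit_beta_mixture"]

SHAPE_MIN, SHAPE_MAX = 0.1, 1e4
CLAMP = 1e-6


@dataclass
class BetaMixture:
    """Fitted 3-state beta mixture with per-point responsibilities.

    States are ordered so mean(U) < mean(H) < mean(M).
    """

    weights: np.ndarray  # (K,)
    a: np.ndarray  # (K,)
    b: np.ndarray  # (K,)
    responsibilities: np.ndarray  # (n, K), rows sum to 1
    log_likelihood: float
    converged: bool
    n_iter: int
    ll_path: np.ndarray = field(repr=False, default=None)

    @property
    def means(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    def state_cdf(self, k: int, x):
        return stats.beta.cdf(x, self.a[k], self.b[k])

    def state_ppf(self, k: int, q):
        return stats.beta.ppf(q, self.a[k], self.b[k])

    def classify(self, x: np.ndarray) -> np.ndarray:
        """Most probable state for each value under the fitted mixture."""
        logp = self._log_component_densities(np.asarray(x, dtype=float))
        return np.argmax(logp, axis=1)

    def _log_component_densities(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(x, CLAMP, 1 - CLAMP)
        return np.log(self.weights)[None, :] + np.column_stack(
            [stats.beta.logpdf(x, self.a[k], self.b[k]) for k in range(len(self.weights))]
        )


def _weighted_beta_mle(x: np.ndarray, r: np.ndarray, a0: float, b0: float):
    """Maximise sum_i r_i log Beta(x_i; a, b) over bounded shapes."""
    R = r.sum()
    slx = float(r @ np.log(x))
    sl1x = float(r @ np.log1p(-x))

    def negll_grad(theta):
        a, b = np.exp(theta)
        ll = (
            (a - 1) * slx
            + (b - 1) * sl1x
            - R * float(special.betaln(a, b))
        )
        dig = special.digamma
        da = slx - R * (dig(a) - dig(a + b))
        db = sl1x - R * (dig(b) - dig(a + b))
        # chain rule for log-parametrisation
        return -ll, -np.array([da * a, db * b])

    lo, hi = np.log(SHAPE_MIN), np.log(SHAPE_MAX)
    res = optimize.minimize(
        negll_grad,
        x0=np.log([np.clip(a0, SHAPE_MIN, SHAPE_MAX), np.clip(b0, SHAPE_MIN, SHAPE_MAX)]),
        jac=True,
        method="L-BFGS-B",
        bounds=[(lo, hi), (lo, hi)],
    )
    a, b = np.exp(res.x)
    return a, b


def _moment_shapes(x: np.ndarray, w: np.ndarray | None = None):
    if w is None:
        w = np.ones_like(x)
    mu = float(w @ x / w.sum())
    var = float(w @ (x - mu) ** 2 / w.sum())
    var = max(var, 1e-6)
    common = max(mu * (1 - mu) / var - 1.0, 0.2)
    return np.clip(mu * common, SHAPE_MIN, SHAPE_MAX), np.clip(
        (1 - mu) * common, SHAPE_MIN, SHAPE_MAX
    )


def fit_beta_mixture(
    values,
    n_states: int = 3,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed=None,
) -> BetaMixture:
    """Fit an ``n_states`` beta mixture by EM.

    Values are clamped to [1e-6, 1 - 1e-6]. Initialisation is deterministic
    (quantile slices + method of moments); ``seed`` is accepted for interface
    symmetry but unused. ``tol`` is on the relative log-likelihood change.
    Non-convergence after ``max_iter`` warns and returns the best-so-far fit.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 30:
        raise ValidationError(f"need >= 30 values to fit a mixture, got {x.size}")
    if not np.isfinite(x).all():
        raise ValidationError("values must be finite")
    x = np.clip(x, CLAMP, 1 - CLAMP)
    if np.unique(x).size < n_states:
        raise DegenerateInputError(
            f"fewer than {n_states} distinct values; mixture fit is degenerate"
        )

    n = x.size
    order = np.argsort(x)
    K = n_states
    a = np.empty(K)
    b = np.empty(K)
    for k, chunk in enumerate(np.array_split(order, K)):
        a[k], b[k] = _moment_shapes(x[chunk])
    w = np.full(K, 1.0 / K)

    ll_prev = -np.inf
    ll_path = []
    converged = False
    resp = np.full((n, K), 1.0 / K)
    for it in range(1, max_iter + 1):
        # E-step
        logp = np.log(w)[None, :] + np.column_stack(
            [stats.beta.logpdf(x, a[k], b[k]) for k in range(K)]
        )
        norm = special.logsumexp(logp, axis=1)
        ll = float(norm.sum())
        ll_path.append(ll)
        resp = np.exp(logp - norm[:, None])
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-12):
            converged = True
            break
        ll_prev = ll
        # M-step
        w = resp.mean(axis=0)
        w = np.maximum(w, 1e-12)
        w /= w.sum()
        for k in range(K):
            a0, b0 = _moment_shapes(x, resp[:, k])
            a[k], b[k] = _weighted_beta_mle(x, resp[:, k], a0, b0)
    else:
        it = max_iter
    if not converged:
        warnings.warn(
            f"beta-mixture EM did not converge in {max_iter} iterations; "
            "returning best-so-far fit"
        )

    means = a / (a + b)
    ordk = np.argsort(means)
    return BetaMixture(
        weights=w[ordk],
        a=a[ordk],
        b=b[ordk],
        responsibilities=resp[:, ordk],
        log_likelihood=ll_path[-1],
        converged=converged,
        n_iter=it,
        ll_path=np.asarray(ll_path),
    )
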