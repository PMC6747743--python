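"""Beta-mixture quantile (BMIQ) normalisation of type-II probes.

The two Infinium probe chemistries yield systematically different beta
distributions: type-II betas are compressed toward 0.5 relative to type-I.
BMIQ corrects this per sample by (1) fitting a three-state (U/H/M) beta
mixture separately to type-I and type-II probes, (2) assigning each type-II
probe to its most probable state, (3) mapping U- and M-state type-II probes
onto the corresponding type-I state distribution by quantile transformation
(for M, on the reflected scale so the transformation is anchored at 1), and
(4) rescaling H-state probes by a monotone affine (dilation) map onto the
gap between the transformed U and M regions. Type-I probes pass through
untouched, and the within-state rank order of type-II probes is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..errors import SomnoclockError, ValidationError
from .mixture import BetaMixture, fit_beta_mixture
from .model import BetaMatrix, ProbeAnnotation

__all__ = ["BmiqParams", "bmiq_normalize", "bmiq_normalize_sample"]


@dataclass(frozen=True)
class BmiqParams:
    n_states: int = 3
    max_iter: int = 500
    tol: float = 1e-6
    # with no type-II probes there is nothing to normalise; pass through
    # instead of erroring when True
    allow_passthrough: bool = False


def _transform_U(x, mix2: BetaMixture, mix1: BetaMixture):
    q = mix2.state_cdf(0, x)
    return mix1.state_ppf(0, q)


def _transform_M(x, mix2: BetaMixture, mix1: BetaMixture):
    # reflected quantile map: anchored at beta = 1
    K = len(mix2.weights) - 1
    q = stats.beta.sf(x, mix2.a[K], mix2.b[K])
    return stats.beta.isf(q, mix1.a[K], mix1.b[K])


def bmiq_normalize_sample(
    t1_values: np.ndarray, t2_values: np.ndarray, params: BmiqParams = BmiqParams()
) -> np.ndarray:
    """Normalise one sample's type-II betas onto its type-I distribution."""
    mix1 = fit_beta_mixture(
        t1_values, n_states=params.n_states, max_iter=params.max_iter, tol=params.tol
    )
    mix2 = fit_beta_mixture(
        t2_values, n_states=params.n_states, max_iter=params.max_iter, tol=params.tol
    )
    state = mix2.classify(t2_values)
    out = np.array(t2_values, dtype=float)
    H = params.n_states // 2  # middle state index after mean-ordering

    isU, isH, isM = state == 0, state == H, state == params.n_states - 1
    if isU.any():
        out[isU] = _transform_U(t2_values[isU], mix2, mix1)
    if isM.any():
        out[isM] = _transform_M(t2_values[isM], mix2, mix1)
    if isH.any():
        h = t2_values[isH]
        left = out[isU].max() if isU.any() else 0.0
        right = out[isM].min() if isM.any() else 1.0
        lo, hi = h.min(), h.max()
        if hi > lo and right > left:
            out[isH] = left + (h - lo) * (right - left) / (hi - lo)
        # degenerate gap or a single H value: leave unchanged
    return np.clip(out, 0.0, 1.0)


def bmiq_normalize(
    betas: BetaMatrix, ann: ProbeAnnotation, params: BmiqParams = BmiqParams()
) -> BetaMatrix:
    """BMIQ-normalise every sample of a beta matrix.

    Returns a new matrix; type-I probe rows are bitwise-unchanged.
    """
    types = ann.types_for(betas.probe_ids)
    is2 = types == "II"
    out = betas.copy()
    if not is2.any():
        if params.allow_passthrough:
            return out
        raise ValidationError(
            "no type-II probes to normalise (set allow_passthrough to skip BMIQ)"
        )
    if not (~is2).any():
        raise ValidationError("BMIQ needs type-I probes as the reference distribution")
    for j, sample in enumerate(betas.sample_ids):
        try:
            out.values[is2, j] = bmiq_normalize_sample(
                betas.values[~is2, j], betas.values[is2, j], params
            )
        except SomnoclockError as e:
            raise SomnoclockError(f"BMIQ failed for sample {sample!r}: {e}") from e
    return out
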