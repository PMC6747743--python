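"""Cell-composition correction of beta values.

Per probe, beta is regressed (OLS, intercept included) on the estimated
cell-type proportions across samples; the corrected value is the residual
plus the fitted value at the cohort-mean proportions. This removes
between-sample variation attributable to composition while keeping betas on
their original scale, then clamps to [0, 1].
"""

from __future__ import annotations

import numpy as np

from ..errors import ValidationError
from .deconvolution import CellProportions
from .model import BetaMatrix

__all__ = ["celltype_correct"]


def celltype_correct(betas: BetaMatrix, props: CellProportions) -> BetaMatrix:
    P = props.table.loc[betas.sample_ids].to_numpy(float)
    S, K = P.shape
    if S < K + 2:
        raise ValidationError(
            f"{S} samples cannot support a {K}-proportion regression "
            "(need n_samples >= n_cell_types + 2); use a pass-through flag upstream"
        )
    X = np.column_stack([np.ones(S), P])
    Y = betas.values.T  # samples x probes
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ coef
    at_mean = np.concatenate([[1.0], P.mean(axis=0)]) @ coef  # 1 x probes
    corrected = (Y - fitted) + at_mean[None, :]
    out = betas.copy()
    out.values = np.clip(corrected.T, 0.0, 1.0)
    return out
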