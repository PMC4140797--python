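"""Model-based (NormFinder-style) stability estimation.

Expression values are modelled additively on the log2 scale:

    x_gi = mu + alpha_g + beta_i + eps_gi,   eps_gi ~ N(0, sigma_g^2)

where ``alpha_g`` is the gene's overall level, ``beta_i`` a sample-wide
effect (e.g. input amount) shared by every gene in sample *i*, and the
residual variance ``sigma_g^2`` is the gene's own instability.  The model
is fit by row/column centering; the naive per-gene residual mean square
is biased because all G genes share the centering, so a moment correction
is applied before taking the square root:

    z_g       = sum_i r_gi^2 / (S - 1)
    sigma^2_g = G/(G-2) * ( z_g - sum_h z_h / (G (G-1)) )
    rho_g     = sqrt( max(0, sigma^2_g) )

``rho`` (the stability value) is in log2 units: lower = more stable.
This is the ungrouped estimator; grouped (inter/intra-group) designs are
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .genorm import RelativeQuantityMatrix


@dataclass
class NormFinderResult:
    """Per-gene stability value, variance component and ascending ranking."""

    stability: pd.Series        # rho, log2 units, >= 0
    variance: pd.Series         # bias-corrected sigma^2 estimate (may be < 0)
    ranking: list[str]          # genes sorted ascending by rho (stable sort)


def normfinder_stability(rq: RelativeQuantityMatrix | pd.DataFrame) -> NormFinderResult:
    """Estimate each gene's stability value from relative quantities.

    Requires at least 3 genes and 3 samples and a complete matrix.  Ties
    in rho keep input order (stable sort), so an all-constant input ranks
    genes in input order with rho = 0 everywhere.
    """
    mat = rq.rq if isinstance(rq, RelativeQuantityMatrix) else rq
    n_genes, n_samples = mat.shape
    if n_genes < 3:
        raise InputError("NormFinder needs at least 3 genes (centering leaves no df)")
    if n_samples < 3:
        raise InputError("NormFinder needs at least 3 samples")
    arr = mat.to_numpy(dtype=float)
    if not np.isfinite(arr).all() or (arr <= 0).any():
        raise InputError("NormFinder needs a complete, strictly positive matrix")
    x = np.log2(arr)
    resid = (
        x
        - x.mean(axis=1, keepdims=True)
        - x.mean(axis=0, keepdims=True)
        + x.mean()
    )
    z = (resid ** 2).sum(axis=1) / (n_samples - 1)
    g = n_genes
    sigma2 = g / (g - 2) * (z - z.sum() / (g * (g - 1)))
    rho = np.sqrt(np.clip(sigma2, 0.0, None))
    stability = pd.Series(rho, index=mat.index, name="rho")
    order = stability.sort_values(kind="stable").index
    return NormFinderResult(
        stability=stability,
        variance=pd.Series(sigma2, index=mat.index, name="sigma2"),
        ranking=list(order),
    )
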