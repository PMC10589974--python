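"""Global and local Moran autocorrelation statistics on district values.

Global Moran's I for values :math:`x` with weights :math:`W`:

.. math:: I = \\frac{n}{S_0} \\frac{\\sum_i \\sum_j w_{ij} z_i z_j}{\\sum_i z_i^2},
          \\qquad z_i = x_i - \\bar x,\\ S_0 = \\sum_{ij} w_{ij}

with analytic null expectation :math:`E[I] = -1/(n-1)`. Inference is by
random permutation of the values over the districts; the two-sided p-value
``(1 + #{|I*| >= |I|}) / (n_perm + 1)`` is the default, with both one-sided
variants always reported alongside.

Local Moran (LISA) statistics :math:`I_i = z_i \\sum_j w_{ij} z_j / m_2`
(:math:`m_2 = \\sum_k z_k^2 / n`) use conditional permutation — unit *i* is
held fixed and the remaining values are permuted over its neighbours — and
are labelled by Moran-scatter quadrant (HH, LL, HL, LH) when significant at
``alpha``, else NS. The useful identity ``sum_i I_i = S0 * I`` holds for any
weight style. No multiple-testing correction is applied to the local tests
by default; a Benjamini-Hochberg option is available and logged when used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import DistrictGraph, moran_weights

__all__ = ["MoranResult", "global_moran", "local_moran"]

logger = logging.getLogger(__name__)


@dataclass
class MoranResult:
    statistic: float
    expectation_null: float
    p_value: float  # the p-value under `alternative`
    p_greater: float
    p_less: float
    p_two_sided: float
    n_perm: int
    alternative: str
    per_unit: pd.DataFrame = None

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("permutation p-values lie in (0, 1]")


def _prepare(values, graph: DistrictGraph, style: str, n_perm: int):
    x = np.asarray(values, dtype=float).ravel()
    if graph.n < 3:
        raise ValueError("Moran statistics need at least 3 districts")
    if x.size != graph.n:
        raise ValueError(f"got {x.size} values for {graph.n} districts")
    if np.ptp(x) == 0:
        raise ValueError("Moran's I is undefined for constant values")
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse permutation p-value")
    w = moran_weights(graph, style)
    return x, w


def global_moran(values, graph: DistrictGraph, style: str = "row_standardized",
                 n_perm: int = 999, seed: int = 0,
                 alternative: str = "two-sided") -> MoranResult:
    """Global Moran's I with permutation inference."""
    x, w = _prepare(values, graph, style, n_perm)
    n = x.size
    z = x - x.mean()
    s0 = w.sum()
    denom = z @ z
    i_obs = n / s0 * (z @ (w @ z)) / denom

    rng = np.random.default_rng(seed)
    zp = rng.permuted(np.tile(z, (n_perm, 1)), axis=1)
    i_star = n / s0 * ((zp @ w.T) * zp).sum(axis=1) / denom
    p_gr = (1 + int((i_star >= i_obs).sum())) / (n_perm + 1)
    p_ls = (1 + int((i_star <= i_obs).sum())) / (n_perm + 1)
    p_two = (1 + int((np.abs(i_star) >= abs(i_obs)).sum())) / (n_perm + 1)
    chosen = {"two-sided": p_two, "greater": p_gr, "less": p_ls}
    if alternative not in chosen:
        raise ValueError(f"unknown alternative {alternative!r}")
    logger.info("global Moran I=%.4f (style=%s, %s permutation p=%.4g)",
                i_obs, style, alternative, chosen[alternative])
    return MoranResult(float(i_obs), -1.0 / (n - 1), chosen[alternative],
                       p_gr, p_ls, p_two, n_perm, alternative)


def local_moran(values, graph: DistrictGraph, style: str = "row_standardized",
                n_perm: int = 999, seed: int = 0, alpha: float = 0.05,
                fdr: bool = False) -> pd.DataFrame:
    """Local Moran statistics with conditional-permutation p-values.

    Returns one row per district: value, deviation ``z``, spatial lag,
    ``local_i``, permutation ``p_value`` (two-sided), and ``cluster`` label
    (HH/LL/HL/LH when ``p <= alpha``, isolated or insignificant units NS).
    """
    x, w = _prepare(values, graph, style, n_perm)
    n = x.size
    z = x - x.mean()
    m2 = z @ z / n
    lag = w @ z
    local_i = z * lag / m2

    rng = np.random.default_rng(seed)
    p = np.ones(n)
    for i in range(n):
        wi = w[i]
        nbr = np.flatnonzero(wi)
        if nbr.size == 0:
            continue  # isolated: I_i = 0 by the zero-lag convention
        others = np.delete(z, i)
        keys = rng.random((n_perm, others.size))
        order = np.argsort(keys, axis=1)[:, : nbr.size]
        lag_star = others[order] @ wi[nbr]
        i_star = z[i] * lag_star / m2
        p[i] = (1 + int((np.abs(i_star) >= abs(local_i[i])).sum())) / (n_perm + 1)

    p_eff = p.copy()
    if fdr:
        from statsmodels.stats.multitest import multipletests

        p_eff = multipletests(p, method="fdr_bh")[1]
        logger.info("local Moran p-values BH-adjusted across %d districts", n)

    labels = []
    for i in range(n):
        if w[i].sum() == 0 or p_eff[i] > alpha:
            labels.append("NS")
        elif z[i] > 0:
            labels.append("HH" if lag[i] > 0 else "HL")
        else:
            labels.append("LL" if lag[i] <= 0 else "LH")
    return pd.DataFrame(
        {
            "district": list(graph.labels),
            "value": x,
            "z": z,
            "lag": lag,
            "local_i": local_i,
            "p_value": p,
            "cluster": labels,
        }
    )
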