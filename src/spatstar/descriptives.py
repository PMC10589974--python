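"""Design-based descriptives and conventional logistic screening.

Implements the survey-analysis stage that precedes the Bayesian spatial
model: weighted prevalence with Taylor-linearised, logit-transformed 95%
confidence intervals; Rao-Scott (first-order) corrected chi-square tests on
weighted contingency tables; conventional maximum-likelihood logistic
regression; and the p <= 0.2 screening rule that selects covariates for the
spatial model.

Conventions (flagged, since design-based software differs):

* CIs are logit-Wald (design SE mapped through the logit), which keeps them
  inside [0, 1].
* The Rao-Scott correction is first-order (mean design effect of cell and
  marginal proportions); design effects are taken relative to the
  with-replacement SRS variance ``p(1-p)/(n-1)`` so that under the trivial
  design — equal weights, one PSU per record, one stratum — the statistic
  reduces *exactly* to classical Pearson.
* A stratum containing a single PSU has no design-based variance; it is an
  error naming the stratum unless ``single_psu="certainty"`` is passed, in
  which case the stratum contributes zero variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from scipy.stats import chi2, norm

__all__ = [
    "DesignError",
    "PrevalenceEstimate",
    "ChisqResult",
    "weighted_prevalence",
    "design_chisq",
    "fit_logistic_ml",
    "screen_covariates",
]

logger = logging.getLogger(__name__)

SEPARATION_THRESHOLD = 15.0  # |logit coefficient| beyond which we flag separation


class DesignError(ValueError):
    """Raised for invalid survey-design or design-matrix configurations."""


@dataclass
class PrevalenceEstimate:
    proportion: float
    ci_low: float
    ci_high: float
    n: int
    se: float
    method: str = "taylor-logit-wald"

    def __post_init__(self):
        if not self.ci_low <= self.proportion <= self.ci_high:
            raise ValueError("confidence bounds must bracket the estimate")


@dataclass
class ChisqResult:
    statistic: float  # Rao-Scott corrected
    df: int
    p_value: float
    pearson: float  # uncorrected (weighted-table) Pearson
    design_correction: float  # mean generalised design effect divisor


def _records(data) -> pd.DataFrame:
    return data.records if hasattr(data, "records") else data


def _linearized_variance(u, stratum, psu, single_psu="error"):
    """Design variance of a weighted total via Taylor linearisation.

    ``u`` are the per-record linearised contributions; clusters (PSUs) are
    summed within strata and the with-replacement between-cluster variance
    ``n_h/(n_h-1) * sum_c (U_hc - mean_h)^2`` is accumulated over strata.
    """
    df = pd.DataFrame({"u": u, "stratum": stratum, "psu": psu})
    var = 0.0
    for s, grp in df.groupby("stratum", observed=True, sort=True):
        totals = grp.groupby("psu", observed=True)["u"].sum().to_numpy()
        nh = totals.size
        if nh < 2:
            if single_psu == "certainty":
                continue  # certainty unit: zero variance contribution
            raise DesignError(
                f"stratum {s!r} has a single PSU; design variance undefined "
                "(pass single_psu='certainty' to treat it as a certainty unit)"
            )
        var += nh / (nh - 1.0) * ((totals - totals.mean()) ** 2).sum()
    return var


def weighted_prevalence(data, outcome_col: str = "outcome", weight_col: str = "weight",
                        stratum_col: str = "stratum", psu_col: str = "psu",
                        single_psu: str = "error", level: float = 0.95) -> PrevalenceEstimate:
    """Survey-weighted prevalence with a design-based logit-Wald CI.

    Point estimate is the Hajek ratio ``sum(w*y)/sum(w)``; its variance uses
    Taylor linearisation over strata and PSUs; the CI is computed on the
    logit scale and back-transformed, so it always respects [0, 1].
    """
    df = _records(data).dropna(subset=[outcome_col])
    y = df[outcome_col].to_numpy(dtype=float)
    w = df[weight_col].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    wsum = w.sum()
    p = float(w @ y / wsum)
    u = w * (y - p) / wsum
    var = _linearized_variance(u, df[stratum_col], df[psu_col], single_psu=single_psu)
    se = float(np.sqrt(var))
    n = int(y.size)
    if p <= 0.0 or p >= 1.0 or se == 0.0:
        return PrevalenceEstimate(p, p, p, n, se, method="taylor-logit-wald/degenerate")
    z = norm.ppf(0.5 + level / 2.0)
    l = np.log(p / (1 - p))
    se_l = se / (p * (1 - p))
    lo, hi = 1 / (1 + np.exp(-(l - z * se_l))), 1 / (1 + np.exp(-(l + z * se_l)))
    return PrevalenceEstimate(p, float(lo), float(hi), n, se)


def design_chisq(data, outcome_col: str, factor_col: str, weight_col: str = "weight",
                 stratum_col: str = "stratum", psu_col: str = "psu",
                 single_psu: str = "error") -> ChisqResult:
    """Rao-Scott first-order corrected Pearson chi-square of a weighted table.

    The Pearson statistic is computed on the weighted proportions scaled to
    the unweighted sample size; the first-order correction divides it by the
    mean generalised design effect built from cell and marginal design
    effects. Under a trivial design the divisor is exactly 1.
    """
    df = _records(data).dropna(subset=[outcome_col, factor_col])
    y = df[outcome_col]
    f = df[factor_col]
    w = df[weight_col].to_numpy(dtype=float)
    n = len(df)
    r_levels = [lv for lv in pd.unique(y) if pd.notna(lv)]
    c_levels = [lv for lv in pd.unique(f) if pd.notna(lv)]
    r_levels, c_levels = sorted(r_levels, key=str), sorted(c_levels, key=str)
    nr, nc = len(r_levels), len(c_levels)
    if nr < 2 or nc < 2:
        raise DesignError(
            f"degenerate table: {outcome_col!r} has {nr} level(s), {factor_col!r} has {nc}"
        )
    wsum = w.sum()
    prop = np.zeros((nr, nc))
    ind = {}
    for a, rl in enumerate(r_levels):
        for b, cl in enumerate(c_levels):
            m = ((y == rl) & (f == cl)).to_numpy()
            ind[(a, b)] = m
            prop[a, b] = w[m].sum() / wsum
    if (prop.sum(axis=1) == 0).any() or (prop.sum(axis=0) == 0).any():
        raise DesignError("degenerate table: empty row or column after weighting")
    pr, pc = prop.sum(axis=1), prop.sum(axis=0)
    expected = np.outer(pr, pc)
    pearson = float(n * ((prop - expected) ** 2 / expected).sum())

    def deff(mask, p):
        if p <= 0 or p >= 1 or n < 2:
            return 1.0
        u = w * (mask.astype(float) - p) / wsum
        v = _linearized_variance(u, df[stratum_col], df[psu_col], single_psu=single_psu)
        v_srs = p * (1 - p) / (n - 1)
        return v / v_srs if v_srs > 0 else 1.0

    cell_term = sum((1 - prop[a, b]) * deff(ind[(a, b)], prop[a, b])
                    for a in range(nr) for b in range(nc))
    row_term = sum((1 - pr[a]) * deff((y == r_levels[a]).to_numpy(), pr[a]) for a in range(nr))
    col_term = sum((1 - pc[b]) * deff((f == c_levels[b]).to_numpy(), pc[b]) for b in range(nc))
    dof = (nr - 1) * (nc - 1)
    delta = (cell_term - row_term - col_term) / dof
    delta = max(delta, 1e-12)
    stat = pearson / delta
    return ChisqResult(stat, dof, float(chi2.sf(stat, dof)), pearson, float(delta))


def _design_matrix(df: pd.DataFrame, covariates):
    """Intercept + first-level-reference dummy coding; numeric columns pass through."""
    cols = [np.ones(len(df))]
    names = [("intercept", "")]
    for c in covariates:
        s = df[c]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            if isinstance(s.dtype, pd.CategoricalDtype):
                levels = list(s.cat.categories)
                codes = s.cat.codes.to_numpy()
            else:
                cat = pd.Categorical(s)
                levels = list(cat.categories)
                codes = np.asarray(cat.codes)
            if len(levels) < 2:
                raise DesignError(f"covariate {c!r} has a single observed level")
            for k, lv in enumerate(levels[1:], start=1):
                cols.append((codes == k).astype(float))
                names.append((c, str(lv)))
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append((c, ""))
    return np.column_stack(cols), names


def _check_rank(x: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, _, piv = qr(x, mode="economic", pivoting=True)
        bad = sorted(f"{t}[{l}]" if l else t for t, l in (names[j] for j in piv[rank:]))
        raise DesignError(f"design matrix rank deficient; collinear columns: {bad}")


def fit_logistic_ml(data, outcome_col: str, covariates) -> pd.DataFrame:
    """Maximum-likelihood logistic regression (IRLS) with Wald inference.

    Returns one row per design column: term, level, estimate (log-odds),
    std_error, p_value, odds_ratio, and a ``separation_flag`` set when the
    coefficient magnitude exceeds 15 on the logit scale.
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("no covariates supplied")
    df = _records(data).dropna(subset=[outcome_col, *covariates])
    y = df[outcome_col].to_numpy(dtype=float)
    x, names = _design_matrix(df, covariates)
    _check_rank(x, names)
    res = sm.GLM(y, x, family=sm.families.Binomial()).fit(maxiter=100)
    est = res.params
    se = res.bse
    pvals = res.pvalues
    out = pd.DataFrame(
        {
            "term": [t for t, _ in names],
            "level": [l for _, l in names],
            "estimate": est,
            "std_error": se,
            "p_value": pvals,
            "odds_ratio": np.exp(est),
            "separation_flag": np.abs(est) > SEPARATION_THRESHOLD,
        }
    )
    if out["separation_flag"].any():
        flagged = out.loc[out["separation_flag"], "term"].tolist()
        logger.warning("possible separation on term(s): %s", flagged)
    return out


def screen_covariates(data, outcome_col: str, candidates, alpha: float = 0.2,
                      always_keep=()) -> list:
    """Select covariates for the spatial model at the nominal p <= alpha level.

    Fits the multivariable model on all candidates and keeps each term whose
    smallest Wald p-value across its dummy levels is <= ``alpha``. Terms in
    ``always_keep`` (literature-informed forcing) bypass the threshold.
    Univariate p-values are also computed and logged for transparency.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be nonempty")
    table = fit_logistic_ml(data, outcome_col, candidates)
    for c in candidates:
        try:
            uni = fit_logistic_ml(data, outcome_col, [c])
            pu = uni.loc[uni["term"] == c, "p_value"].min()
            logger.info("univariate screen %s: min Wald p = %.4g", c, pu)
        except DesignError:
            logger.info("univariate screen %s: not estimable", c)
    keep = set(always_keep)
    selected = []
    for c in candidates:
        pmin = table.loc[table["term"] == c, "p_value"].min()
        if c in keep or (np.isfinite(pmin) and pmin <= alpha):
            selected.append(c)
        logger.info("multivariable screen %s: min Wald p = %.4g -> %s",
                    c, pmin, "keep" if c in selected else "drop")
    return selected
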