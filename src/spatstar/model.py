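"""Bayesian structured additive logistic regression with spatial effects.

The model for a binary outcome :math:`y_{ij}` of individual *i* in district
*j* is

.. math::

    \\mathrm{logit}\\, p_{ij} = \\beta_0 + Z_{ij}'\\theta + f(x_{ij})
        + f_{str}(s_j) + f_{unstr}(s_j)

with categorical fixed effects :math:`\\theta`, a P-spline smooth *f* for
continuous covariates, an intrinsic-CAR (Besag) structured district effect
:math:`f_{str}` and an iid Gaussian unstructured effect :math:`f_{unstr}`
(the convolution / BYM decomposition of the spatial field). Every variance
component carries an inverse-gamma(a, b) hyperprior; fixed effects get a
diffuse Gaussian prior.

Inference is a rejection-free Gibbs sampler built on Polya-Gamma data
augmentation: latent :math:`\\omega_i \\sim PG(1, \\eta_i)` renders the
likelihood conditionally Gaussian, so each sweep draws (i) all latent
omegas, (ii) the full location block (fixed + spline + both spatial fields)
jointly from one sparse-structured Gaussian system, and (iii) the variance
components from their inverse-gamma conditionals. Identifiability of the
improper CAR prior and of the spline level is restored by sum-to-zero
centring after every sweep, with the offsets absorbed into the intercept
(the clamped B-spline basis sums to one row-wise, so subtracting a constant
from the spline coefficients shifts the curve by exactly that constant).

The estimator follows scikit-learn conventions (``get_params`` /
``set_params``, fitted attributes with trailing underscores); the
specification-style entry point :func:`fit_star` is a thin wrapper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cholesky, solve_triangular, LinAlgError
from scipy.special import expit
from sklearn.base import BaseEstimator

from .graph import DistrictGraph, car_precision
from .pg import seed_pg, pg_draw, pg_draw_general
from .pspline import SplineBasis, build_pspline_basis

__all__ = [
    "ModelSpec",
    "McmcConfig",
    "FitResult",
    "StructuredAdditiveLogit",
    "fit_star",
    "variance_decomposition",
    "VarianceDecomposition",
    "compute_dic",
    "DicResult",
    "posterior_odds_table",
    "predicted_district_prevalence",
]

logger = logging.getLogger(__name__)

ETA_WARN = 40.0  # |linear predictor| beyond which a divergence warning is logged


@dataclass
class ModelSpec:
    """Declarative model description (see :class:`StructuredAdditiveLogit`)."""

    fixed_terms: list = field(default_factory=list)
    smooth_terms: list = field(default_factory=list)  # name or (name, n_knots, degree, order)
    district_col: str = "district"
    graph: DistrictGraph = None
    include_structured: bool = True
    include_unstructured: bool = True
    hyper_a: float = 0.001
    hyper_b: float = 0.001
    fixed_prior_var: float = 100.0

    def __post_init__(self):
        if self.hyper_a <= 0 or self.hyper_b <= 0:
            raise ValueError("inverse-gamma hyperparameters must be positive")


@dataclass
class McmcConfig:
    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 10
    n_chains: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")


@dataclass
class FitResult:
    """Posterior draws, summaries and the design needed to post-process them."""

    coef_names: list  # [(term, level)] for the dense block, intercept first
    beta: np.ndarray  # (S, p_dense)
    f_str: np.ndarray  # (S, J) or None
    f_unstr: np.ndarray  # (S, J) or None
    tau2: dict  # name -> (S,) draws
    chain: np.ndarray  # (S,) chain index of each draw
    district_labels: tuple
    dist_idx: np.ndarray  # (n,) or None
    design: np.ndarray  # (n, p_dense) dense design matrix
    y: np.ndarray  # (n,)
    smooths: dict  # name -> (slice into dense block, SplineBasis)
    term_levels: dict  # fixed term -> list of levels (first = reference)
    summaries: pd.DataFrame = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def eta_draws(self) -> np.ndarray:
        """(S, n) posterior draws of the linear predictor on the fit data."""
        eta = self.beta @ self.design.T
        if self.f_str is not None:
            eta = eta + self.f_str[:, self.dist_idx]
        if self.f_unstr is not None:
            eta = eta + self.f_unstr[:, self.dist_idx]
        return eta

    def smooth_curve(self, name: str, x=None) -> pd.DataFrame:
        """Posterior mean and 95% band of a fitted smooth on a grid."""
        sl, basis = self.smooths[name]
        if x is None:
            x = np.linspace(basis.x_min, basis.x_max, 101)
        b = basis.evaluate(x)
        draws = self.beta[:, sl] @ b.T
        draws = draws - draws.mean(axis=1, keepdims=True)
        return pd.DataFrame(
            {
                name: x,
                "mean": draws.mean(axis=0),
                "q025": np.quantile(draws, 0.025, axis=0),
                "q975": np.quantile(draws, 0.975, axis=0),
            }
        )


def _normalize_smooth(term):
    if isinstance(term, str):
        return (term, 22, 3, 2)
    name, n_knots, degree, order = term
    return (str(name), int(n_knots), int(degree), int(order))


def _split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of a (n_chains, S) draw array."""
    half = x.shape[1] // 2
    if half < 2:
        return float("nan")
    parts = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, s = parts.shape
    means = parts.mean(axis=1)
    w = parts.var(axis=1, ddof=1).mean()
    b = s * means.var(ddof=1)
    if w <= 0:
        return 1.0
    return float(np.sqrt(((s - 1) / s * w + b / s) / w))


class StructuredAdditiveLogit(BaseEstimator):
    """Scikit-learn style estimator for the spatial structured additive model.

    Parameters
    ----------
    fixed : sequence of str
        Categorical covariate columns (first observed level is the reference).
    smooth : sequence
        Continuous covariates given P-spline smooths; each entry is either a
        column name (default basis: 22 knots, cubic, 2nd-order penalty) or a
        tuple ``(name, n_knots, degree, penalty_order)``.
    graph : DistrictGraph
        District adjacency; required when a spatial term is included.
    district_col : str
        Column holding district labels (must all appear in ``graph``).
    structured, unstructured : bool
        Include the CAR and/or the iid district effect.
    hyper_a, hyper_b : float
        Inverse-gamma hyperprior (shape, scale) shared by all variance
        components (historical default 0.001, 0.001).
    fixed_prior_var : float
        Gaussian prior variance of intercept and fixed effects.
    n_iter, burn_in, thin, n_chains, seed : MCMC settings.
    weighted : bool
        Fit a survey-weighted pseudo-likelihood (weights normalised to mean
        one; approximate PG(w, eta) augmentation). Default False: the survey
        weights are *not* used by the Bayesian model.

    Attributes
    ----------
    result_ : FitResult
    summaries_ : DataFrame of posterior mean / sd / 2.5% / 97.5% per quantity
    dic_ : DicResult
    phi_ : VarianceDecomposition (when both spatial terms are present)
    """

    def __init__(self, fixed=(), smooth=(), graph=None, district_col="district",
                 structured=True, unstructured=True, hyper_a=0.001, hyper_b=0.001,
                 fixed_prior_var=100.0, n_iter=12000, burn_in=2000, thin=10,
                 n_chains=2, seed=0, weighted=False, weight_col="weight"):
        self.fixed = fixed
        self.smooth = smooth
        self.graph = graph
        self.district_col = district_col
        self.structured = structured
        self.unstructured = unstructured
        self.hyper_a = hyper_a
        self.hyper_b = hyper_b
        self.fixed_prior_var = fixed_prior_var
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.n_chains = n_chains
        self.seed = seed
        self.weighted = weighted
        self.weight_col = weight_col

    # ------------------------------------------------------------------ build
    def _build_design(self, df: pd.DataFrame):
        n = len(df)
        cols = [np.ones(n)]
        names = [("intercept", "")]
        term_levels = {}
        for c in self.fixed:
            s = df[c]
            if isinstance(s.dtype, pd.CategoricalDtype):
                levels = [lv for lv in s.cat.categories if lv in set(s.dropna().unique())]
                codes = pd.Categorical(s, categories=levels).codes
            else:
                cat = pd.Categorical(s)
                levels = list(cat.categories)
                codes = cat.codes
            if len(levels) < 2:
                raise ValueError(f"fixed term {c!r} has fewer than 2 observed levels")
            term_levels[c] = [str(lv) for lv in levels]
            for k, lv in enumerate(levels[1:], start=1):
                cols.append((codes == k).astype(float))
                names.append((c, str(lv)))
        smooths = {}
        ncol = len(cols)  # intercept + dummies, all 1-d columns so far
        for term in self.smooth:
            name, n_knots, degree, order = _normalize_smooth(term)
            basis = build_pspline_basis(df[name].to_numpy(dtype=float), n_knots, degree, order)
            smooths[name] = (slice(ncol, ncol + basis.n_basis), basis)
            cols.append(basis.basis)
            ncol += basis.n_basis
        d = np.column_stack(cols)
        return d, names, term_levels, smooths

    # ------------------------------------------------------------------- fit
    def fit(self, data, outcome: str = "outcome"):
        df = data.records if hasattr(data, "records") else data
        used = list(dict.fromkeys(
            [outcome, *self.fixed, *[_normalize_smooth(t)[0] for t in self.smooth]]
            + ([self.district_col] if (self.structured or self.unstructured) else [])
            + ([self.weight_col] if self.weighted else [])
        ))
        before = len(df)
        df = df.dropna(subset=[c for c in used if c in df.columns]).copy()
        if len(df) < before:
            logger.info("listwise deletion dropped %d of %d records", before - len(df), before)
        y = df[outcome].to_numpy()
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")

        spatial = self.structured or self.unstructured
        if spatial:
            if self.graph is None:
                raise ValueError("spatial term requested but no graph supplied")
            unknown = sorted(set(map(str, df[self.district_col].unique())) - set(self.graph.labels))
            if unknown:
                raise ValueError(f"district labels not in graph: {unknown}")

        # canonical sort: results are invariant to input record order
        df = df.sort_values(by=[c for c in used if c in df.columns],
                            kind="mergesort").reset_index(drop=True)
        y = df[outcome].to_numpy(dtype=float)
        d, names, term_levels, smooths = self._build_design(df)
        n, p_d = d.shape

        j = self.graph.n if spatial else 0
        if spatial:
            lab_to_idx = {lab: i for i, lab in enumerate(self.graph.labels)}
            dist_idx = np.array([lab_to_idx[str(v)] for v in df[self.district_col]])
            zs = sparse.csr_matrix(
                (np.ones(n), (np.arange(n), dist_idx)), shape=(n, j)
            )
        else:
            dist_idx = None
            zs = None
        k_mat = rank_k = None
        if self.structured:
            k_mat = car_precision(self.graph)
            rank_k = j - self.graph.n_components()

        w = None
        if self.weighted:
            w = df[self.weight_col].to_numpy(dtype=float)
            w = w / w.mean()

        mcmc = McmcConfig(self.n_iter, self.burn_in, self.thin, self.n_chains, self.seed)
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(self.n_chains)
        draws = []
        for c, child in enumerate(children):
            draws.append(
                self._run_chain(
                    d, y, dist_idx, zs, k_mat, rank_k, smooths, mcmc, child, w
                )
            )
        res = self._collect(draws, names, term_levels, smooths, d, y, dist_idx)
        self.result_ = res
        self.summaries_ = res.summaries
        self.n_features_in_ = p_d
        self.dic_ = compute_dic(res)
        if self.structured and self.unstructured:
            self.phi_ = variance_decomposition(res)
        return self

    def _run_chain(self, d, y, dist_idx, zs, k_mat, rank_k, smooths, mcmc, seedseq, w):
        rng = np.random.default_rng(seedseq)
        seed_pg(int(seedseq.generate_state(1, np.uint32)[0]))
        n, p_d = d.shape
        j = zs.shape[1] if zs is not None else 0
        has_str = self.structured
        has_unstr = self.unstructured
        p = p_d + j * (int(has_str) + int(has_unstr))
        sl_str = slice(p_d, p_d + j) if has_str else None
        sl_unstr = slice(p_d + j * int(has_str), p) if has_unstr else None

        wvec = w if w is not None else 1.0
        kappa = (y - 0.5) * wvec
        b_full = np.empty(p)
        b_full[:p_d] = d.T @ kappa
        if zs is not None:
            bz = zs.T @ kappa
            if has_str:
                b_full[sl_str] = bz
            if has_unstr:
                b_full[sl_unstr] = bz

        prior_fixed = np.zeros(p_d)
        smooth_cols = np.zeros(p_d, dtype=bool)
        for sl, basis in smooths.values():
            smooth_cols[sl] = True
        prior_fixed[~smooth_cols] = 1.0 / self.fixed_prior_var

        # Soft sum-to-zero constraints: the difference penalty and the CAR
        # Laplacian both annihilate constants, so block-level constants are
        # flat directions of the conditional. A small precision on each
        # block mean keeps the joint draw numerically proper; the exact
        # recentring below then removes the block means, so the posterior
        # of the identified (centred) quantities is unchanged.
        soft = {nm: np.full((sl.stop - sl.start,) * 2, 1.0 / (sl.stop - sl.start))
                for nm, (sl, _b) in smooths.items()}
        soft_j = np.full((j, j), 1.0 / j) if (has_str and j) else None

        theta = np.zeros(p_d)
        f_str = np.zeros(j)
        f_unstr = np.zeros(j)
        tau2 = {name: 0.5 for name in
                ([f"tau2_spline_{nm}" for nm in smooths]
                 + (["tau2_str"] if has_str else [])
                 + (["tau2_unstr"] if has_unstr else []))}

        a0, b0 = self.hyper_a, self.hyper_b
        keep = {"beta": [], "f_str": [], "f_unstr": [],
                **{t: [] for t in tau2}}
        warned = False
        for it in range(mcmc.n_iter):
            eta = d @ theta
            if has_str:
                eta += f_str[dist_idx]
            if has_unstr:
                eta += f_unstr[dist_idx]
            if not warned and np.abs(eta).max() > ETA_WARN:
                logger.warning("linear predictor exceeded |%g|; draws retained", ETA_WARN)
                warned = True
            if w is None:
                omega = pg_draw(eta)
            else:
                omega = pg_draw_general(w, eta, rng)

            q = np.zeros((p, p))
            m = d * omega[:, None]
            q[:p_d, :p_d] = d.T @ m
            q[np.arange(p_d), np.arange(p_d)] += prior_fixed
            for nm, (sl, basis) in smooths.items():
                q[sl, sl] += basis.penalty / tau2[f"tau2_spline_{nm}"] + soft[nm]
            if zs is not None:
                s_w = np.asarray(zs.T @ omega).ravel()
                a_zd = zs.T @ m  # (J, p_d)
                if has_str:
                    q[sl_str, :p_d] = a_zd
                    q[:p_d, sl_str] = a_zd.T
                    q[sl_str, sl_str] = np.diag(s_w) + k_mat / tau2["tau2_str"] + soft_j
                if has_unstr:
                    q[sl_unstr, :p_d] = a_zd
                    q[:p_d, sl_unstr] = a_zd.T
                    q[sl_unstr, sl_unstr] = np.diag(s_w) + np.eye(j) / tau2["tau2_unstr"]
                if has_str and has_unstr:
                    q[sl_str, sl_unstr] = np.diag(s_w)
                    q[sl_unstr, sl_str] = np.diag(s_w)

            try:
                u = cholesky(q, lower=False)
            except LinAlgError:
                q[np.arange(p), np.arange(p)] += 1e-8
                u = cholesky(q, lower=False)
            mean = solve_triangular(
                u, solve_triangular(u, b_full, trans="T", lower=False), lower=False
            )
            draw = mean + solve_triangular(u, rng.standard_normal(p), lower=False)
            theta = draw[:p_d].copy()
            if has_str:
                f_str = draw[sl_str].copy()
            if has_unstr:
                f_unstr = draw[sl_unstr].copy()

            # sum-to-zero centring; offsets absorbed into the intercept
            for nm, (sl, basis) in smooths.items():
                shift = float((d[:, sl] @ theta[sl]).mean())
                theta[sl] -= shift  # partition of unity: curve drops by shift
                theta[0] += shift
            if has_str:
                shift = float(f_str.mean())
                f_str -= shift
                theta[0] += shift

            for nm, (sl, basis) in smooths.items():
                g = theta[sl]
                quad = float(g @ basis.penalty @ g)
                tau2[f"tau2_spline_{nm}"] = 1.0 / rng.gamma(
                    a0 + basis.penalty_rank / 2.0, 1.0 / (b0 + quad / 2.0)
                )
            if has_str:
                quad = float(f_str @ k_mat @ f_str)
                tau2["tau2_str"] = 1.0 / rng.gamma(a0 + rank_k / 2.0, 1.0 / (b0 + quad / 2.0))
            if has_unstr:
                quad = float(f_unstr @ f_unstr)
                tau2["tau2_unstr"] = 1.0 / rng.gamma(a0 + j / 2.0, 1.0 / (b0 + quad / 2.0))

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                keep["beta"].append(theta.copy())
                if has_str:
                    keep["f_str"].append(f_str.copy())
                if has_unstr:
                    keep["f_unstr"].append(f_unstr.copy())
                for t in tau2:
                    keep[t].append(tau2[t])
        out = {"beta": np.array(keep["beta"])}
        out["f_str"] = np.array(keep["f_str"]) if has_str else None
        out["f_unstr"] = np.array(keep["f_unstr"]) if has_unstr else None
        out["tau2"] = {t: np.array(keep[t]) for t in tau2}
        return out

    def _collect(self, chains, names, term_levels, smooths, d, y, dist_idx):
        beta = np.concatenate([c["beta"] for c in chains], axis=0)
        chain_id = np.concatenate(
            [np.full(c["beta"].shape[0], i) for i, c in enumerate(chains)]
        )
        f_str = (np.concatenate([c["f_str"] for c in chains], axis=0)
                 if chains[0]["f_str"] is not None else None)
        f_unstr = (np.concatenate([c["f_unstr"] for c in chains], axis=0)
                   if chains[0]["f_unstr"] is not None else None)
        tau2 = {t: np.concatenate([c["tau2"][t] for c in chains])
                for t in chains[0]["tau2"]}

        labels = tuple(self.graph.labels) if self.graph is not None else ()
        rows = []

        def add(name, arr):
            rows.append(
                dict(parameter=name, mean=float(arr.mean()), sd=float(arr.std(ddof=1)),
                     q025=float(np.quantile(arr, 0.025)), q975=float(np.quantile(arr, 0.975)))
            )

        for k, (t, lv) in enumerate(names):
            add(f"{t}[{lv}]" if lv else t, beta[:, k])
        if f_str is not None:
            for jdx, lab in enumerate(labels):
                add(f"f_str[{lab}]", f_str[:, jdx])
        if f_unstr is not None:
            for jdx, lab in enumerate(labels):
                add(f"f_unstr[{lab}]", f_unstr[:, jdx])
        for t, arr in tau2.items():
            add(t, arr)
        summaries = pd.DataFrame(rows).set_index("parameter")

        diag = {}
        per_chain = len(chains[0]["beta"])
        if per_chain >= 4:
            stack = lambda arrs: np.stack(arrs, axis=0)
            diag["rhat_intercept"] = _split_rhat(stack([c["beta"][:, 0] for c in chains]))
            for t in tau2:
                diag[f"rhat_{t}"] = _split_rhat(stack([c["tau2"][t] for c in chains]))
        diag["n_draws"] = beta.shape[0]

        return FitResult(
            coef_names=names, beta=beta, f_str=f_str, f_unstr=f_unstr, tau2=tau2,
            chain=chain_id, district_labels=labels, dist_idx=dist_idx, design=d,
            y=y, smooths=smooths, term_levels=term_levels, summaries=summaries,
            diagnostics=diag,
        )

    # --------------------------------------------------------------- predict
    def predict_proba(self, data, outcome: str = None) -> np.ndarray:
        """Posterior-mean event probability for new records (two-column array)."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        df = data.records if hasattr(data, "records") else data
        res = self.result_
        n = len(df)
        cols = [np.ones(n)]
        for t, lv in res.coef_names[1:]:
            cols.append((df[t].astype(str) == lv).to_numpy(dtype=float))
        for nm, (sl, basis) in res.smooths.items():
            cols.append(basis.evaluate(df[nm].to_numpy(dtype=float)))
        d = np.column_stack(cols)
        eta = d @ res.beta.mean(axis=0)
        if res.f_str is not None or res.f_unstr is not None:
            lab_to_idx = {lab: i for i, lab in enumerate(res.district_labels)}
            idx = np.array([lab_to_idx[str(v)] for v in df[self.district_col]])
            if res.f_str is not None:
                eta += res.f_str.mean(axis=0)[idx]
            if res.f_unstr is not None:
                eta += res.f_unstr.mean(axis=0)[idx]
        p = expit(eta)
        return np.column_stack([1 - p, p])


def fit_star(data, spec: ModelSpec, mcmc: McmcConfig = None) -> FitResult:
    """Fit the structured additive logistic model described by ``spec``."""
    mcmc = mcmc or McmcConfig()
    est = StructuredAdditiveLogit(
        fixed=list(spec.fixed_terms), smooth=list(spec.smooth_terms),
        graph=spec.graph, district_col=spec.district_col,
        structured=spec.include_structured, unstructured=spec.include_unstructured,
        hyper_a=spec.hyper_a, hyper_b=spec.hyper_b,
        fixed_prior_var=spec.fixed_prior_var,
        n_iter=mcmc.n_iter, burn_in=mcmc.burn_in, thin=mcmc.thin,
        n_chains=mcmc.n_chains, seed=mcmc.seed,
    )
    est.fit(data)
    return est.result_


# ------------------------------------------------------------------ phi / DIC

@dataclass
class VarianceDecomposition:
    structured_pct: float  # phi, % of spatial variance that is structured
    unstructured_pct: float
    ci_structured_pct: tuple = None  # equal-tailed 95% interval of per-draw phi
    undefined: bool = False


def variance_decomposition(fit_or_vstr, v_unstr: float = None) -> VarianceDecomposition:
    """Structured share phi = v_str / (v_str + v_unstr) of the spatial field.

    Accepts either a :class:`FitResult` (posterior-mean variance components,
    plus a per-draw credible interval) or two scalar variance components.
    Percentages are rounded to one decimal.
    """
    if v_unstr is not None:
        v_str = float(fit_or_vstr)
        tot = v_str + float(v_unstr)
        if tot <= 0:
            return VarianceDecomposition(float("nan"), float("nan"), undefined=True)
        phi = 100.0 * v_str / tot
        return VarianceDecomposition(round(phi, 1), round(100.0 - phi, 1))
    fit = fit_or_vstr
    if "tau2_str" not in fit.tau2 or "tau2_unstr" not in fit.tau2:
        raise ValueError("both spatial terms must be present in the fit")
    vs, vu = fit.tau2["tau2_str"], fit.tau2["tau2_unstr"]
    tot = vs.mean() + vu.mean()
    if tot <= 0:
        return VarianceDecomposition(float("nan"), float("nan"), undefined=True)
    phi = 100.0 * vs.mean() / tot
    per_draw = 100.0 * vs / (vs + vu)
    ci = (round(float(np.quantile(per_draw, 0.025)), 1),
          round(float(np.quantile(per_draw, 0.975)), 1))
    return VarianceDecomposition(round(float(phi), 1), round(100.0 - float(phi), 1), ci)


@dataclass
class DicResult:
    dic: float
    p_d: float
    mean_deviance: float


def _bernoulli_deviance(y, eta):
    # -2 log L, numerically stable through logaddexp
    return 2.0 * (np.logaddexp(0.0, eta) - y * eta).sum(axis=-1)


def compute_dic(fit: FitResult) -> DicResult:
    """Deviance information criterion from the stored posterior draws.

    ``pD = mean(D) - D(posterior mean)`` with the posterior mean taken on
    the linear-predictor scale; ``DIC = mean(D) + pD``.
    """
    eta = fit.eta_draws()
    dev = _bernoulli_deviance(fit.y[None, :], eta)
    d_bar = float(dev.mean())
    d_hat = float(_bernoulli_deviance(fit.y, eta.mean(axis=0)))
    p_d = d_bar - d_hat
    return DicResult(d_bar + p_d, p_d, d_bar)


def posterior_odds_table(fit: FitResult, round_to: int = 2) -> pd.DataFrame:
    """Adjusted odds ratio table: exp(posterior mean) with equal-tailed 95% CrI.

    Reference levels are shown with aOR exactly 1 and no interval.
    """
    rows = []
    ref_done = set()
    for k, (t, lv) in enumerate(fit.coef_names):
        if t == "intercept" or t in fit.smooths:
            continue
        if t not in ref_done and t in fit.term_levels:
            rows.append(dict(term=t, level=fit.term_levels[t][0], aOR=1.0,
                             ci_low=np.nan, ci_high=np.nan, reference=True))
            ref_done.add(t)
        arr = fit.beta[:, k]
        rows.append(dict(
            term=t, level=lv,
            aOR=round(float(np.exp(arr.mean())), round_to),
            ci_low=round(float(np.exp(np.quantile(arr, 0.025))), round_to),
            ci_high=round(float(np.exp(np.quantile(arr, 0.975))), round_to),
            reference=False,
        ))
    return pd.DataFrame(rows)


def predicted_district_prevalence(fit: FitResult) -> pd.DataFrame:
    """Per-district adjusted prevalence and district-associated odds.

    Prevalence is the mean over a district's individuals of the posterior
    mean of expit(eta); districts with no individuals get NaN and are
    flagged. District odds are exp of the posterior-mean total spatial
    effect, centred so their geometric mean is exactly one.
    """
    if fit.dist_idx is None:
        raise ValueError("fit has no spatial term")
    j = len(fit.district_labels)
    p_post = expit(fit.eta_draws()).mean(axis=0)  # (n,)
    prev = np.full(j, np.nan)
    counts = np.bincount(fit.dist_idx, minlength=j)
    sums = np.bincount(fit.dist_idx, weights=p_post, minlength=j)
    nz = counts > 0
    prev[nz] = sums[nz] / counts[nz]

    total = np.zeros(j)
    if fit.f_str is not None:
        total = total + fit.f_str.mean(axis=0)
    if fit.f_unstr is not None:
        total = total + fit.f_unstr.mean(axis=0)
    centred = total - total.mean()
    odds = np.exp(centred)
    out = pd.DataFrame(
        {
            "district": list(fit.district_labels),
            "n": counts,
            "predicted_prevalence": prev,
            "district_odds": odds,
            "spatial_effect": centred,
            "no_individuals": ~nz,
        }
    )
    if (~nz).any():
        logger.warning("districts with no individuals: %s",
                       [fit.district_labels[i] for i in np.where(~nz)[0]])
    return out
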