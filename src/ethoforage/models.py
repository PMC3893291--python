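"""Attack-frequency and capture-success models with AIC selection.

Attack counts per recording interval are modeled with a Poisson GLM, log link
and an exposure offset ``log(exposure_h)`` so coefficients describe rates per
hour.  Attack outcomes are modeled with a Bernoulli GLM and logit link.
Candidate fixed-effect sets are compared by AIC (``2k - 2 lnL``); a random
individual intercept can be added to either family, fitted by maximizing a
Gauss-Hermite approximation to the marginal likelihood.  Cell predictions on
the response scale carry Wald 95% confidence intervals formed on the link
scale and back-transformed.

Fixed-effect fits are delegated to :mod:`statsmodels`; the exposure-offset
bookkeeping, AIC table, outlier rule and the random-intercept marginal
likelihood are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy.special import expit, gammaln, logsumexp

from ethoforage.ethogram import AttackRecord, SamplingInterval

#: z-quantile for 95% confidence; the significance threshold is alpha = 0.05.
Z_95 = 1.96

#: Canonical ordering of fixed-effect terms (unordered sets are displayed and
#: encoded in this order so formulas and labels are deterministic).
TERM_ORDER = ("diel_bin", "site_year", "water_position", "hunting_mode", "habitat")

_RESPONSES = ("attack_count", "outcome")


class ConvergenceError(RuntimeError):
    """Raised when a model fit fails to converge and no fallback exists."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one candidate model.

    ``fixed_terms`` is an unordered, duplicate-free subset of
    :data:`TERM_ORDER`; ``attack_count`` responses always carry the
    ``log(exposure_h)`` offset.
    """

    response: str
    fixed_terms: frozenset[str] = frozenset()
    random_individual: bool = False

    def __init__(
        self,
        response: str,
        fixed_terms: Iterable[str] = (),
        random_individual: bool = False,
    ) -> None:
        if response not in _RESPONSES:
            raise ValueError(f"response must be one of {_RESPONSES}, got {response!r}")
        terms = frozenset(fixed_terms)
        unknown = terms - set(TERM_ORDER)
        if unknown:
            raise ValueError(f"unknown fixed terms: {sorted(unknown)}")
        object.__setattr__(self, "response", response)
        object.__setattr__(self, "fixed_terms", terms)
        object.__setattr__(self, "random_individual", bool(random_individual))

    @property
    def ordered_terms(self) -> tuple[str, ...]:
        return tuple(t for t in TERM_ORDER if t in self.fixed_terms)

    @property
    def label(self) -> str:
        parts = [t for t in self.ordered_terms] or ["intercept"]
        if self.random_individual:
            parts.append("individual(random)")
        return " + ".join(parts)

    def formula(self) -> str:
        lhs = "attack_count" if self.response == "attack_count" else "success"
        rhs = " + ".join(f"C({t})" for t in self.ordered_terms) or "1"
        return f"{lhs} ~ {rhs}"


@dataclass
class GLMFit:
    """A fitted model: coefficients, likelihood, AIC and cell predictions."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # index: term; columns: estimate, se
    log_likelihood: float
    k: int
    aic: float
    cell_predictions: pd.DataFrame  # factor columns + mean, lo, hi
    n_units: int
    converged: bool = True
    messages: list[str] = field(default_factory=list)


@dataclass
class AICTable:
    """Model-selection table sorted by ascending AIC with deltas.

    ``table`` has columns ``model, k, aic, delta, converged, message``; the
    best (lowest-AIC) row has ``delta = 0``.  ``fits`` maps model labels to
    the successful :class:`GLMFit` objects.
    """

    table: pd.DataFrame
    fits: dict[str, GLMFit]

    @property
    def best(self) -> GLMFit:
        ok = self.table[self.table["converged"]]
        if ok.empty:
            raise ConvergenceError("no candidate model converged")
        return self.fits[ok.iloc[0]["model"]]


# ---------------------------------------------------------------------------
# data marshalling


def intervals_to_frame(intervals: Union[pd.DataFrame, Iterable[SamplingInterval]]) -> pd.DataFrame:
    if isinstance(intervals, pd.DataFrame):
        df = intervals.copy()
    else:
        rows = []
        for iv in intervals:
            rows.append(
                {
                    "individual_id": iv.individual_id,
                    "site_year": iv.site_year,
                    "start": iv.start,
                    "diel_bin": iv.diel_bin.value,
                    "exposure_h": iv.exposure_h,
                    "attack_count": iv.attack_count,
                    "viable": iv.viable,
                }
            )
        df = pd.DataFrame(rows)
    if "viable" in df.columns:
        df = df[df["viable"].astype(bool)].copy()
    return df.reset_index(drop=True)


def attacks_to_frame(attacks: Union[pd.DataFrame, Iterable[AttackRecord]]) -> pd.DataFrame:
    if isinstance(attacks, pd.DataFrame):
        df = attacks.copy()
        if "success" not in df.columns:
            df["success"] = (df["outcome"] == "success").astype(int)
        return df.reset_index(drop=True)
    rows = []
    for a in attacks:
        rows.append(
            {
                "individual_id": a.individual_id,
                "site_year": a.site_year,
                "time": a.time,
                "diel_bin": a.diel_bin.value,
                "water_position": a.water_position,
                "hunting_mode": a.hunting_mode,
                "habitat": a.habitat,
                "outcome": a.outcome,
                "success": a.success,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# outlier rule


def flag_outlier_intervals(
    intervals: Sequence[SamplingInterval], threshold: int = 10
) -> tuple[list[SamplingInterval], list[SamplingInterval]]:
    """Split intervals into (kept, flagged) by an attack-count threshold.

    Intervals with ``attack_count > threshold`` are excluded from rate
    fitting as outliers (e.g. a single feeding-frenzy interval), but their
    attack records remain valid units for the capture-success model.  Flagged
    intervals are returned, never silently dropped.
    """
    if threshold < 0:
        raise ValueError(f"outlier threshold must be >= 0, got {threshold}")
    kept, flagged = [], []
    for iv in intervals:
        (flagged if iv.attack_count > threshold else kept).append(iv)
    return kept, flagged


# ---------------------------------------------------------------------------
# Wald intervals

_INVERSE_LINKS = {
    "identity": lambda x: x,
    "log": np.exp,
    "logit": expit,
}


def wald_interval(
    estimate: float, se: float, link: str = "identity", z: float = Z_95
) -> tuple[float, float]:
    """95% Wald interval: ``estimate +/- z*se`` on the link scale, inverted.

    The inverse link is monotone increasing for all supported links, so the
    returned pair always satisfies ``lo <= point <= hi``.
    """
    if se < 0:
        raise ValueError(f"standard error must be >= 0, got {se}")
    try:
        inv = _INVERSE_LINKS[link]
    except KeyError:
        raise ValueError(f"unknown link {link!r} (use identity, log or logit)") from None
    return float(inv(estimate - z * se)), float(inv(estimate + z * se))


# ---------------------------------------------------------------------------
# fixed-effect GLMs


def _cell_grid(df: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    if not terms:
        return pd.DataFrame({"cell": ["(all)"]})
    cells = df[list(terms)].drop_duplicates().sort_values(list(terms))
    return cells.reset_index(drop=True)

def _predict_cells(res, spec: ModelSpec, df: pd.DataFrame, link: str) -> pd.DataFrame:
    terms = spec.ordered_terms
    cells = _cell_grid(df, terms)
    if terms:
        exog = build_design_matrices([res.model.data.design_info], cells)[0]
        X = np.asarray(exog)
    else:
        X = np.ones((1, 1))
    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    eta = X @ params
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
    inv = _INVERSE_LINKS[link]
    out = cells.copy()
    out["mean"] = inv(eta)
    bounds = [wald_interval(e, s, link=link) for e, s in zip(eta, se)]
    out["lo"] = [b[0] for b in bounds]
    out["hi"] = [b[1] for b in bounds]
    return out


def _finalize_fit(res, spec, df, link, n_units, messages) -> GLMFit:
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    coef = pd.DataFrame({"estimate": params, "se": bse}, index=list(res.params.index))
    llf = float(res.llf)
    k = len(params)
    cells = _predict_cells(res, spec, df, link)
    if link == "logit":
        boundary = (cells["mean"] < 1e-8) | (cells["mean"] > 1 - 1e-8)
        if boundary.any():
            messages.append(
                "boundary cell estimate(s) at 0 or 1; Wald intervals are degenerate"
            )
        if np.any(np.abs(params) > 15):
            messages.append("very large coefficient(s); possible complete separation")
    for m in messages:
        warnings.warn(m, stacklevel=3)
    return GLMFit(
        spec=spec,
        coefficients=coef,
        log_likelihood=llf,
        k=k,
        aic=2.0 * k - 2.0 * llf,
        cell_predictions=cells,
        n_units=n_units,
        converged=True,
        messages=messages,
    )


def fit_attack_rate_model(
    intervals: Union[pd.DataFrame, Iterable[SamplingInterval]], spec: ModelSpec
) -> GLMFit:
    """Fit a Poisson attack-rate GLM with ``log(exposure_h)`` offset.

    The intercept-only fit reproduces the closed form
    ``exp(intercept) = total attacks / total exposure``.  Cell predictions are
    rates per hour (offset of one hour).  With ``random_individual`` a normal
    random intercept per individual is integrated out by Gauss-Hermite
    quadrature.
    """
    if spec.response != "attack_count":
        raise ValueError("attack-rate model requires response='attack_count'")
    df = intervals_to_frame(intervals)
    if df.empty:
        raise ValueError("no viable intervals to fit")
    if (df["exposure_h"] <= 0).any():
        raise ValueError("all exposures must be positive")
    offset = np.log(df["exposure_h"].to_numpy(dtype=float))
    if spec.random_individual:
        return _fit_random_intercept(df, spec, offset=offset, family="poisson")
    model = smf.glm(spec.formula(), data=df, family=sm.families.Poisson(), offset=offset)
    res = model.fit(tol=1e-12, maxiter=300)
    if not getattr(res, "converged", True):
        raise ConvergenceError(f"Poisson GLM did not converge: {spec.label}")
    return _finalize_fit(res, spec, df, "log", n_units=len(df), messages=[])


def fit_capture_success_model(
    attacks: Union[pd.DataFrame, Iterable[AttackRecord]], spec: ModelSpec
) -> GLMFit:
    """Fit a Bernoulli capture-success GLM with logit link.

    For purely categorical saturated specifications the cell predictions equal
    the observed per-cell success proportions.  Boundary cells (all successes
    or all failures) and suspected separation are reported as warnings on the
    fit rather than silently regularized.
    """
    if spec.response != "outcome":
        raise ValueError("capture-success model requires response='outcome'")
    df = attacks_to_frame(attacks)
    if df.empty:
        raise ValueError("no attack records to fit")
    needed = list(spec.ordered_terms)
    if df[needed + ["success"]].isna().any().any() if needed else df["success"].isna().any():
        raise ValueError("missing covariate or outcome values in attack records")
    if spec.random_individual:
        return _fit_random_intercept(df, spec, offset=np.zeros(len(df)), family="binomial")
    model = smf.glm(spec.formula(), data=df, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on perfect separation
        res = model.fit(tol=1e-12, maxiter=300)
    if not getattr(res, "converged", True):
        raise ConvergenceError(f"binomial GLM did not converge: {spec.label}")
    return _finalize_fit(res, spec, df, "logit", n_units=len(df), messages=[])


# ---------------------------------------------------------------------------
# random-intercept marginal likelihood (Gauss-Hermite)

_GH_NODES = 25


def _obs_loglik(y, eta, family):
    if family == "poisson":
        return y * eta - np.exp(eta) - gammaln(y + 1.0)
    # bernoulli
    return y * eta - np.logaddexp(0.0, eta)


def marginal_loglik(
    params: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    family: str,
    n_nodes: int = _GH_NODES,
) -> float:
    """Gauss-Hermite marginal log-likelihood of a random-intercept GLM.

    ``params`` is ``(beta..., log_sigma)``; the per-individual intercept
    ``u_j ~ Normal(0, sigma^2)`` is integrated out with ``n_nodes`` Hermite
    nodes (substituting ``u = sqrt(2) * sigma * z``).
    """
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    eta0 = X @ beta + offset
    # (nodes, observations) grid of per-observation log-likelihoods
    eta = eta0[None, :] + np.sqrt(2.0) * sigma * nodes[:, None]
    ll_obs = _obs_loglik(y[None, :], eta, family)
    # sum within group for each node
    ll_group = np.zeros((n_nodes, n_groups))
    for q in range(n_nodes):
        ll_group[q] = np.bincount(group_idx, weights=ll_obs[q], minlength=n_groups)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)
    return float(np.sum(logsumexp(ll_group + log_w[:, None], axis=0)))


def _fit_random_intercept(df: pd.DataFrame, spec: ModelSpec, offset, family: str) -> GLMFit:
    from scipy.optimize import minimize

    fixed_spec = ModelSpec(spec.response, spec.fixed_terms, random_individual=False)
    if family == "poisson":
        base_model = smf.glm(
            fixed_spec.formula(), data=df, family=sm.families.Poisson(), offset=offset
        )
        y_col, link = "attack_count", "log"
    else:
        base_model = smf.glm(fixed_spec.formula(), data=df, family=sm.families.Binomial())
        y_col, link = "success", "logit"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = base_model.fit()

    X = np.asarray(base.model.exog, dtype=float)
    y = df[y_col].to_numpy(dtype=float)
    groups, group_idx = np.unique(df["individual_id"].to_numpy(), return_inverse=True)
    n_groups = len(groups)
    offset = np.asarray(offset, dtype=float)

    def neg(params):
        return -marginal_loglik(params, y, X, offset, group_idx, n_groups, family)

    x0 = np.concatenate([np.asarray(base.params, dtype=float), [np.log(0.5)]])
    opt = minimize(neg, x0, method="BFGS", options={"maxiter": 500, "gtol": 1e-6})
    if not opt.success and opt.status != 2:  # status 2: precision loss at optimum
        raise ConvergenceError(
            f"random-intercept fit did not converge: {spec.label} ({opt.message})"
        )

    llf = -float(opt.fun)
    k = len(opt.x)  # fixed effects + random-intercept sd
    se = np.sqrt(np.clip(np.diag(opt.hess_inv), 0.0, np.inf))
    names = list(base.params.index) + ["log_sigma_individual"]
    coef = pd.DataFrame({"estimate": opt.x, "se": se}, index=names)

    # population-level (u = 0) cell predictions from the fixed part
    class _Shim:
        params = pd.Series(opt.x[:-1], index=list(base.params.index))
        model = base.model

        @staticmethod
        def cov_params():
            return opt.hess_inv[:-1, :-1]

    cells = _predict_cells(_Shim, fixed_spec, df, link)
    messages = [] if opt.success else [f"optimizer stopped with: {opt.message}"]
    return GLMFit(
        spec=spec,
        coefficients=coef,
        log_likelihood=llf,
        k=k,
        aic=2.0 * k - 2.0 * llf,
        cell_predictions=cells,
        n_units=len(df),
        converged=True,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# AIC model selection


def aic_model_selection(
    data: Union[pd.DataFrame, Iterable],
    specs: Sequence[ModelSpec],
) -> AICTable:
    """Fit every candidate and tabulate AICs ascending with deltas.

    All candidates must share one response (hence the same analysis units).
    Ties are broken toward fewer parameters.  A candidate whose fit fails is
    recorded in its row with the error message rather than aborting the
    selection.
    """
    if not specs:
        raise ValueError("no candidate specifications")
    responses = {s.response for s in specs}
    if len(responses) > 1:
        raise ValueError(f"candidates mix responses: {sorted(responses)}")
    response = next(iter(responses))
    fitter = fit_attack_rate_model if response == "attack_count" else fit_capture_success_model

    rows = []
    fits: dict[str, GLMFit] = {}
    for spec in specs:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fitter(data, spec)
        except Exception as exc:  # recorded in-row, not fatal
            rows.append(
                {
                    "model": spec.label,
                    "k": np.nan,
                    "aic": np.nan,
                    "converged": False,
                    "message": f"{type(exc).__name__}: {exc}",
                }
            )
            continue
        fits[spec.label] = fit
        rows.append(
            {
                "model": spec.label,
                "k": fit.k,
                "aic": fit.aic,
                "converged": True,
                "message": "; ".join(fit.messages),
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["aic", "k"], ascending=[True, True], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    best = table["aic"].min(skipna=True)
    table["delta"] = table["aic"] - best
    table = table[["model", "k", "aic", "delta", "converged", "message"]]
    return AICTable(table=table, fits=fits)
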