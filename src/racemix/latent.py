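"""Linear models of log race time with a latent binary natal-sex covariate.

Natal sex is unobserved for part of the sample; each record carries a known
probability ``prob_male`` of being natal male.  The response is log(time) and
some design columns (the natal-sex indicator itself, ``nb_predictor``,
``is_nbm``, ``is_nbf``) take different values under the two completions of the
latent variable.  The marginal likelihood

    prod_i [ p_i N(y_i; x_i(M) beta, s^2) + (1 - p_i) N(y_i; x_i(F) beta, s^2) ]

is maximized by EM over fractionally weighted duplicated rows; records with a
degenerate probability contribute a single component, so the fit reduces
exactly to ordinary least squares when every probability is 0 or 1.
Significance is assessed by a parametric bootstrap: responses are resimulated
from the fitted model with the tested coefficient set to zero and the model is
refit on each draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConvergenceError, SingularDesignError

__all__ = [
    "FitResult",
    "ModelSpec",
    "effect_size_pct",
    "fit_latent_model",
    "fit_result_to_frame",
    "latent_covariates",
    "model_spec",
    "monte_carlo_pvalues",
    "residual_qq",
    "significance_stars",
]

_VALID_GENDER = {"male", "female", "non-binary"}
_VALID_NATAL = {"male", "female"}

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 500


def latent_covariates(gender_id: str, natal_sex: str) -> tuple[int, int, int, int]:
    """(nb_predictor, is_nbm, is_nbf, is_nb) for one athlete.

    nb_predictor is +1 for natal-male non-binary athletes, -1 for natal-female
    non-binary athletes and 0 otherwise; is_nbm/is_nbf indicate natal-male and
    natal-female non-binary athletes; is_nb = is_nbm + is_nbf.
    """
    if gender_id not in _VALID_GENDER:
        raise ValueError(f"unknown gender_id {gender_id!r}")
    if natal_sex not in _VALID_NATAL:
        raise ValueError(f"unknown natal_sex {natal_sex!r}")
    if gender_id != "non-binary":
        return (0, 0, 0, 0)
    if natal_sex == "male":
        return (1, 1, 0, 1)
    return (-1, 0, 1, 1)


@dataclass(frozen=True)
class ModelSpec:
    """One of the four model formulas.

    All models share event fixed effects and the centred-age terms; they
    differ in the sex term (latent natal sex vs declared gender identity) and
    in the non-binary terms.
    """

    model_id: int
    sex_term: str  # "natal_sex" | "gender_id"
    nb_terms: tuple[str, ...]

    @property
    def reported_terms(self) -> tuple[str, ...]:
        sex = ("natal_female",) if self.sex_term == "natal_sex" else (
            "gender_female", "gender_nonbinary")
        return sex + ("age_c", "age_c2") + self.nb_terms


_SPECS = {
    1: ModelSpec(1, "natal_sex", ("nb_predictor",)),
    2: ModelSpec(2, "gender_id", ("nb_predictor",)),
    3: ModelSpec(3, "natal_sex", ("is_nbm", "is_nbf")),
    4: ModelSpec(4, "natal_sex", ("is_nb",)),
}


def model_spec(model_id: int) -> ModelSpec:
    if model_id not in _SPECS:
        raise ValueError("model_id must be 1, 2, 3 or 4")
    return _SPECS[model_id]


@dataclass
class FitResult:
    """Fitted coefficients and inference for one model."""

    model_id: int
    coefficients: dict[str, float]
    residual_sd: float
    loglik: float
    n_obs: int
    n_iter: int
    converged: bool
    dropped_terms: tuple[str, ...] = ()
    spec: ModelSpec | None = None
    p_one_tailed: dict[str, float] = field(default_factory=dict)
    p_two_tailed: dict[str, float] = field(default_factory=dict)
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def effect_pct(self) -> dict[str, float]:
        return {k: effect_size_pct(v) for k, v in self.coefficients.items()}


def _design(df: pd.DataFrame, spec: ModelSpec):
    """Design matrices under the two latent completions.

    Returns (xm, xf, columns, y, p) where xm/xf are the design rows with
    natal sex set to male/female.  Event effects are dummy-coded with the
    first (sorted) event absorbed into the intercept.
    """
    gender = df["gender_id"].to_numpy()
    bad = set(gender) - _VALID_GENDER
    if bad:
        raise ValueError(f"unknown gender_id values {sorted(bad)}")
    y = np.log(df["time_seconds"].to_numpy(dtype=float))
    p = df["prob_male"].to_numpy(dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("every record needs prob_male in [0, 1]")

    n = len(df)
    events = sorted(pd.unique(df["event"]))
    age_c = df["age"].to_numpy(dtype=float) - 40.0
    nb = (gender == "non-binary").astype(float)

    cols: list[str] = ["intercept"]
    shared: list[np.ndarray] = [np.ones(n)]
    for e in events[1:]:
        cols.append(f"event[{e}]")
        shared.append((df["event"] == e).to_numpy(dtype=float))

    latent_m: list[np.ndarray] = []
    latent_f: list[np.ndarray] = []
    latent_cols: list[str] = []
    if spec.sex_term == "natal_sex":
        latent_cols.append("natal_female")
        latent_m.append(np.zeros(n))
        latent_f.append(np.ones(n))
    else:
        cols.append("gender_female")
        shared.append((gender == "female").astype(float))
        cols.append("gender_nonbinary")
        shared.append(nb)

    cols_shared_tail = [("age_c", age_c), ("age_c2", age_c**2)]
    for name, col in cols_shared_tail:
        cols.append(name)
        shared.append(col)

    for term in spec.nb_terms:
        if term == "nb_predictor":
            latent_cols.append(term)
            latent_m.append(nb)
            latent_f.append(-nb)
        elif term == "is_nbm":
            latent_cols.append(term)
            latent_m.append(nb)
            latent_f.append(np.zeros(n))
        elif term == "is_nbf":
            latent_cols.append(term)
            latent_m.append(np.zeros(n))
            latent_f.append(nb)
        elif term == "is_nb":
            cols.append(term)
            shared.append(nb)
        else:  # pragma: no cover - specs are fixed
            raise ValueError(f"unknown term {term!r}")

    base = np.column_stack(shared)
    if latent_cols:
        xm = np.column_stack([base] + [c[:, None] for c in latent_m])
        xf = np.column_stack([base] + [c[:, None] for c in latent_f])
        cols = cols + latent_cols
    else:
        xm = xf = base
    # keep a canonical term order: intercept, events, sex, age, nb terms
    order = _canonical_order(cols, spec)
    xm = xm[:, order]
    xf = xf[:, order]
    cols = [cols[i] for i in order]
    return xm, xf, cols, y, p


def _canonical_order(cols: list[str], spec: ModelSpec) -> list[int]:
    def key(name: str):
        if name == "intercept":
            return (0, name)
        if name.startswith("event["):
            return (1, name)
        if name in ("natal_female", "gender_female", "gender_nonbinary"):
            return (2, name)
        if name in ("age_c", "age_c2"):
            return (3, name)
        return (4, spec.nb_terms.index(name) if name in spec.nb_terms else 99)

    return sorted(range(len(cols)), key=lambda i: key(cols[i]))


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    xw = x * w[:, None]
    return np.linalg.solve(xw.T @ x, xw.T @ y)


def _em(
    xm: np.ndarray,
    xf: np.ndarray,
    y: np.ndarray,
    p: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    beta0: np.ndarray | None = None,
    sigma0: float | None = None,
):
    """EM on the stacked two-completion design; returns (beta, sigma, ll, trace, converged)."""
    n = len(y)
    x2 = np.vstack([xm, xf])
    y2 = np.concatenate([y, y])
    prior = np.concatenate([p, 1.0 - p])
    with np.errstate(divide="ignore"):
        log_prior = np.log(prior)

    if beta0 is None:
        beta = _wls(x2, y2, prior)
    else:
        beta = np.asarray(beta0, dtype=float).copy()
    if sigma0 is None:
        r = y2 - x2 @ beta
        sigma2 = max(float(prior @ (r * r)) / n, 1e-12)
    else:
        sigma2 = max(float(sigma0) ** 2, 1e-12)

    trace: list[float] = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = y2 - x2 @ beta
        log_phi = -0.5 * np.log(2.0 * np.pi * sigma2) - (r * r) / (2.0 * sigma2)
        a = log_prior + log_phi
        ll_rec = np.logaddexp(a[:n], a[n:])
        ll = float(ll_rec.sum())
        trace.append(ll)
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        w = np.where(np.isneginf(a), 0.0, np.exp(a - np.concatenate([ll_rec, ll_rec])))
        beta = _wls(x2, y2, w)
        r_new = y2 - x2 @ beta
        sigma2 = max(float(w @ (r_new * r_new)) / n, 1e-12)
    return beta, float(np.sqrt(sigma2)), trace[-1], trace, converged, it


def fit_latent_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    on_nonconvergence: str = "raise",
) -> FitResult:
    """Maximize the marginal likelihood of one model over ``data``.

    ``data`` needs columns event, age, gender_id, time_seconds and prob_male.
    Design columns that are identically zero under both latent completions
    (e.g. non-binary terms when no athlete is non-binary) cannot be estimated;
    they are dropped with a warning and reported as NaN coefficients.
    """
    xm, xf, cols, y, p = _design(data, spec)
    zero = [
        i for i in range(xm.shape[1])
        if not xm[:, i].any() and not xf[:, i].any()
    ]
    dropped = tuple(cols[i] for i in zero)
    if zero:
        warnings.warn(
            f"structurally zero term(s) dropped from model {spec.model_id}: "
            f"{', '.join(dropped)}",
            stacklevel=2,
        )
        keep = [i for i in range(xm.shape[1]) if i not in zero]
        xm, xf = xm[:, keep], xf[:, keep]
        cols = [cols[i] for i in keep]

    prior = np.concatenate([p, 1.0 - p])
    x2 = np.vstack([xm, xf])
    active = x2[prior > 0]
    if np.linalg.matrix_rank(active) < len(cols):
        raise SingularDesignError("design matrix is rank deficient")

    beta, sigma, ll, trace, converged, n_iter = _em(
        xm, xf, y, p, tol=tol, max_iter=max_iter
    )
    if not converged and on_nonconvergence == "raise":
        raise ConvergenceError(
            f"EM did not converge within {max_iter} iterations (model {spec.model_id})"
        )
    coeffs = dict(zip(cols, (float(b) for b in beta)))
    for term in dropped:
        coeffs[term] = float("nan")
    return FitResult(
        model_id=spec.model_id,
        coefficients=coeffs,
        residual_sd=sigma,
        loglik=ll,
        n_obs=len(y),
        n_iter=n_iter,
        converged=converged,
        dropped_terms=dropped,
        spec=spec,
        loglik_trace=trace,
    )


def monte_carlo_pvalues(
    fit: FitResult,
    data: pd.DataFrame,
    spec: ModelSpec,
    term: str,
    n_sims: int,
    seed: int,
    direction: int | None = None,
    refit_tol: float = 1e-8,
    refit_max_iter: int = 200,
) -> tuple[float, float]:
    """Parametric-bootstrap p-values for one coefficient.

    The null model keeps every fitted coefficient except ``term``, which is
    set to zero.  Each simulation draws the latent natal sex from the observed
    per-record probabilities (names are not resimulated), generates responses
    from the null model with the fitted residual SD, refits, and records the
    coefficient.  P-values use the add-one estimator (r + 1) / (n_sims + 1).
    The one-tailed direction defaults to the sign of the observed estimate.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    xm, xf, cols, y, p = _design(data, spec)
    if term in fit.dropped_terms:
        raise ValueError(f"term {term!r} was dropped as structurally zero")
    if term not in cols or term not in fit.coefficients:
        raise ValueError(f"term {term!r} not in model {spec.model_id}")
    if fit.dropped_terms:
        keep = [i for i, c in enumerate(cols) if c not in fit.dropped_terms]
        xm, xf = xm[:, keep], xf[:, keep]
        cols = [cols[i] for i in keep]
    beta_hat_full = np.array([fit.coefficients[c] for c in cols])
    j = cols.index(term)
    b_obs = float(beta_hat_full[j])
    beta_null = beta_hat_full.copy()
    beta_null[j] = 0.0
    sigma = fit.residual_sd

    mean_m = xm @ beta_null
    mean_f = xf @ beta_null
    n = len(y)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_sims)
    for s in range(n_sims):
        male = rng.random(n) < p
        mu = np.where(male, mean_m, mean_f)
        y_star = mu + sigma * rng.standard_normal(n)
        beta_s, _, _, _, _, _ = _em(
            xm, xf, y_star, p,
            tol=refit_tol, max_iter=refit_max_iter,
            beta0=beta_null, sigma0=sigma,
        )
        draws[s] = beta_s[j]

    if direction is None:
        direction = 1 if b_obs >= 0 else -1
    p_two = (int(np.sum(np.abs(draws) >= abs(b_obs))) + 1) / (n_sims + 1)
    p_one = (int(np.sum(direction * draws >= direction * b_obs)) + 1) / (n_sims + 1)
    return p_one, p_two


def effect_size_pct(coefficient: float) -> float:
    """Percentage change in race time implied by a log-time coefficient."""
    return 100.0 * (np.exp(coefficient) - 1.0)


def significance_stars(p_two_tailed: float) -> str:
    if p_two_tailed < 0.001:
        return "***"
    if p_two_tailed < 0.01:
        return "**"
    if p_two_tailed < 0.05:
        return "*"
    if p_two_tailed < 0.10:
        return "(.)"
    return ""


def residual_qq(
    fit: FitResult,
    data: pd.DataFrame,
    known_sex_only: bool = True,
) -> np.ndarray:
    """Normal Q-Q pairs (theoretical quantile, ordered residual).

    Residuals are computed with natal sex at its known value; when
    ``known_sex_only`` is set, the sample is restricted to records with a
    degenerate probability (the athletes whose sex is known).  Otherwise the
    higher-probability completion is used for uncertain records.  Theoretical
    quantiles are standard-normal at (i - 0.5) / n.
    """
    if fit.spec is None:
        raise ValueError("fit carries no model spec")
    xm, xf, cols, y, p = _design(data, fit.spec)
    keep = [i for i, c in enumerate(cols) if c not in fit.dropped_terms]
    beta = np.array([fit.coefficients[cols[i]] for i in keep])
    xm, xf = xm[:, keep], xf[:, keep]
    male = p >= 0.5
    resid = y - np.where(male, xm @ beta, xf @ beta)
    if known_sex_only:
        mask = (p == 0.0) | (p == 1.0)
        resid = resid[mask]
    resid = np.sort(resid)
    n = len(resid)
    if n == 0:
        return np.empty((0, 2))
    q = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return np.column_stack([q, resid])


def fit_result_to_frame(fit: FitResult, include_events: bool = False) -> pd.DataFrame:
    """Tabulate a fit: Parameter, Coefficient, Effect size, p-values, Stars."""
    rows = []
    for term, coef in fit.coefficients.items():
        if not include_events and (term == "intercept" or term.startswith("event[")):
            continue
        p1 = fit.p_one_tailed.get(term)
        p2 = fit.p_two_tailed.get(term)
        rows.append(
            {
                "Parameter": term,
                "Coefficient": coef,
                "Effect size": effect_size_pct(coef),
                "P(one-tailed)": p1,
                "P(two-tailed)": p2,
                "Stars": significance_stars(p2) if p2 is not None else "",
            }
        )
    return pd.DataFrame(rows)
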