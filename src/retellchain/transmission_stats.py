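"""Count and proportion trend models across retellings 1-3 by producer.

Word counts follow a log-link negative-binomial regression with a separate
intercept, slope over retelling index, and dispersion parameter for each
producer. Part-of-speech counts follow a beta-binomial regression that
falls back to plain binomial when the overdispersion estimate sits at the
zero boundary. All fits are deterministic maximum likelihood with
observed-information standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess3


def _hessian(nll, theta: np.ndarray) -> np.ndarray:
    """Centered-difference Hessian with a magnitude-scaled step.

    Forward differences with the default step are noise-dominated here:
    the log likelihoods sum many large gammaln terms, so cancellation error
    gets amplified by 1/h^2."""
    eps = 1e-4 * np.maximum(1.0, np.abs(theta))
    return approx_hess3(theta, nll, epsilon=eps)

__all__ = [
    "CountModelFit",
    "fit_wordcount_trend",
    "fit_pos_trend",
    "negation_condition_contrast",
    "collapse_condition",
]

_LOG_ALPHA_BOUNDS = (-12.0, 5.0)
_LOG_M_BOUNDS = (-5.0, 15.0)


@dataclass
class CountModelFit:
    coefficients: dict[str, dict[str, float]]
    dispersions: dict[str, float]
    contrasts: dict[str, dict[str, float]]
    n_stories: int
    loglik: float = float("nan")
    family: str = "negative_binomial"
    extras: dict = field(default_factory=dict)

    def coef(self, name: str) -> float:
        return self.coefficients[name]["estimate"]


def _wald(estimate: float, se: float) -> dict[str, float]:
    z = estimate / se if se > 0 else np.inf * np.sign(estimate)
    return {
        "estimate": float(estimate),
        "se": float(se),
        "z": float(z),
        "p": float(2 * stats.norm.sf(abs(z))),
    }


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log likelihood; Var = mu + alpha * mu^2."""
    if alpha < 1e-10:
        return float(np.sum(stats.poisson.logpmf(y, mu)))
    inv = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + inv)
            - special.gammaln(inv)
            - special.gammaln(y + 1)
            + inv * np.log(inv / (inv + mu))
            + y * np.log(mu / (inv + mu))
        )
    )


def _check_trend_frame(stories: pd.DataFrame, count_col: str) -> pd.DataFrame:
    required = {"producer", "retelling_index", count_col}
    missing = required - set(stories.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    data = stories[stories["retelling_index"].isin([1, 2, 3])].copy()
    producers = set(data["producer"])
    if not producers >= {"human", "llm"}:
        raise ValueError("both producers must be present")
    return data


def fit_wordcount_trend(stories: pd.DataFrame) -> CountModelFit:
    """Negative-binomial trend in word count over retellings 1-3.

    ``stories`` needs columns producer, retelling_index (1-3), word_count.
    Reports per-producer slopes, the slope-difference contrast, and a Wald
    test of the log dispersion ratio.
    """
    data = _check_trend_frame(stories, "word_count")
    y = data["word_count"].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("word_count must hold non-negative integers")
    r = data["retelling_index"].to_numpy(dtype=float)
    is_h = (data["producer"] == "human").to_numpy()

    # start values: per-producer Poisson GLM + method-of-moments dispersion
    theta0 = []
    for mask in (is_h, ~is_h):
        yy, rr = y[mask], r[mask]
        slope, intercept = np.polyfit(rr, np.log(yy + 0.5), 1)
        mu = np.exp(intercept + slope * rr)
        mom = max(np.mean(((yy - mu) ** 2 - mu) / mu**2), 1e-4)
        if np.allclose(yy, yy[0]):
            warnings.warn(
                "constant counts within a producer: dispersion at boundary",
                RuntimeWarning,
            )
        theta0.extend([intercept, slope, np.log(mom)])
    theta0 = np.asarray(theta0)

    def nll(theta: np.ndarray) -> float:
        b0h, b1h, lah, b0l, b1l, lal = theta
        total = 0.0
        for mask, b0, b1, la in ((is_h, b0h, b1h, lah), (~is_h, b0l, b1l, lal)):
            mu = np.exp(np.clip(b0 + b1 * r[mask], -30, 30))
            total += _nb_loglik(y[mask], mu, np.exp(la))
        return -total

    bounds = [(None, None), (None, None), _LOG_ALPHA_BOUNDS] * 2
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
    theta = res.x
    hess = _hessian(nll, theta)
    cov = _safe_inv(hess)
    diag = np.diag(cov)
    if np.any(diag < 0):  # boundary dispersion: observed information not PD
        warnings.warn(
            "non-positive-definite information matrix (dispersion at boundary); "
            "standard errors clipped",
            RuntimeWarning,
        )
    se = np.sqrt(np.clip(diag, 0, None))

    names = [
        "intercept_human", "slope_human", "log_dispersion_human",
        "intercept_llm", "slope_llm", "log_dispersion_llm",
    ]
    coefficients = {n: _wald(theta[i], se[i]) for i, n in enumerate(names)}
    slope_diff = theta[1] - theta[4]
    slope_var = cov[1, 1] + cov[4, 4] - 2 * cov[1, 4]
    la_diff = theta[2] - theta[5]
    la_var = cov[2, 2] + cov[5, 5] - 2 * cov[2, 5]
    contrasts = {
        "slope_human_minus_llm": _wald(slope_diff, np.sqrt(max(slope_var, 0))),
        "log_dispersion_ratio": _wald(la_diff, np.sqrt(max(la_var, 0))),
    }
    return CountModelFit(
        coefficients=coefficients,
        dispersions={"human": float(np.exp(theta[2])), "llm": float(np.exp(theta[5]))},
        contrasts=contrasts,
        n_stories=int(len(data)),
        loglik=float(-res.fun),
    )


def _bb_loglik(k: np.ndarray, n: np.ndarray, mu: np.ndarray, m: float) -> float:
    a = mu * m
    b = (1 - mu) * m
    return float(
        np.sum(
            special.gammaln(n + 1)
            - special.gammaln(k + 1)
            - special.gammaln(n - k + 1)
            + special.betaln(k + a, n - k + b)
            - special.betaln(a, b)
        )
    )


def _binom_loglik(k: np.ndarray, n: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(stats.binom.logpmf(k, n, mu)))


def _safe_inv(hess: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(hess)


def _fit_proportion_glm(
    k: np.ndarray, n: np.ndarray, X: np.ndarray, names: list[str]
) -> CountModelFit:
    """Beta-binomial regression with binomial fallback at the boundary.

    Returns coefficients on the logit scale plus the model family chosen by
    a boundary-corrected likelihood-ratio check at alpha = 0.05.
    """
    if np.any(k > n):
        raise ValueError("category count k exceeds word count n")
    if np.all(k == 0) or np.all(k == n):
        warnings.warn(
            "all counts at the boundary: contrasts are undefined-at-boundary",
            RuntimeWarning,
        )

    p_pooled = np.clip(k.sum() / n.sum(), 1e-6, 1 - 1e-6)
    beta0 = np.zeros(X.shape[1])
    beta0[0] = special.logit(p_pooled)

    def nll_binom(beta: np.ndarray) -> float:
        mu = special.expit(np.clip(X @ beta, -30, 30))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return -_binom_loglik(k, n, mu)

    res_b = optimize.minimize(nll_binom, beta0, method="BFGS")

    def nll_bb(theta: np.ndarray) -> float:
        beta, log_m = theta[:-1], theta[-1]
        mu = special.expit(np.clip(X @ beta, -30, 30))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return -_bb_loglik(k, n, mu, np.exp(log_m))

    theta0 = np.append(res_b.x, 4.0)
    bounds = [(None, None)] * X.shape[1] + [_LOG_M_BOUNDS]
    res_bb = optimize.minimize(nll_bb, theta0, method="L-BFGS-B", bounds=bounds)

    # boundary-corrected LR test for overdispersion (rho -> 0 <=> m -> inf)
    lr = 2 * (res_b.fun - res_bb.fun)
    p_overdisp = 0.5 * stats.chi2.sf(max(lr, 0.0), df=1)
    at_boundary = res_bb.x[-1] >= _LOG_M_BOUNDS[1] - 1e-6
    use_binomial = at_boundary or p_overdisp >= 0.05

    if use_binomial:
        theta, fun, nll = res_b.x, res_b.fun, nll_binom
        family = "binomial"
        rho = 0.0
    else:
        theta, fun, nll = res_bb.x, res_bb.fun, nll_bb
        family = "beta_binomial"
        m = np.exp(theta[-1])
        rho = 1.0 / (1.0 + m)
    hess = _hessian(nll, theta)
    cov = _safe_inv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    coefficients = {nm: _wald(theta[i], se[i]) for i, nm in enumerate(names)}
    fit = CountModelFit(
        coefficients=coefficients,
        dispersions={"rho": float(rho)},
        contrasts={},
        n_stories=int(len(k)),
        loglik=float(-fun),
        family=family,
        extras={"overdispersion_lr_p": float(p_overdisp)},
    )
    fit.extras["cov"] = cov
    return fit


def fit_pos_trend(stories: pd.DataFrame, category: str | None = None) -> CountModelFit:
    """Beta-binomial trend of a category share over retellings 1-3.

    ``stories`` needs columns producer, retelling_index, count, word_count
    (``count`` may instead be named after the category). Model: logit share
    ~ producer (effect-coded) + retelling index; producer contrast reported.
    """
    count_col = "count"
    if count_col not in stories.columns and category and category in stories.columns:
        stories = stories.rename(columns={category: "count"})
    data = _check_trend_frame(stories, count_col)
    k = data["count"].to_numpy(dtype=float)
    n = data["word_count"].to_numpy(dtype=float)
    code = np.where(data["producer"] == "human", 0.5, -0.5)
    r = data["retelling_index"].to_numpy(dtype=float) - 2.0  # centered at 2
    X = np.column_stack([np.ones_like(k), code, r])
    fit = _fit_proportion_glm(k, n, X, ["intercept", "producer", "retelling_index"])
    fit.contrasts["producer_human_minus_llm"] = fit.coefficients["producer"]
    fit.extras["category"] = category
    fit.extras.pop("cov", None)
    return fit


def collapse_condition(condition: str) -> str:
    """Four-level condition -> {happy_side, sad_side}."""
    if condition in ("happy", "mildly_happy"):
        return "happy_side"
    if condition in ("sad", "mildly_sad"):
        return "sad_side"
    raise ValueError(f"unknown condition {condition!r}")


def negation_condition_contrast(stories: pd.DataFrame) -> CountModelFit:
    """Negation share by producer x (sad-side vs happy-side) condition.

    ``stories`` needs columns producer, condition (4-level or collapsed),
    retelling_index, count, word_count. Returns the four pooled cell
    proportions and a beta-binomial producer x condition interaction test.
    """
    data = _check_trend_frame(stories, "count")
    side = data["condition"].map(
        lambda c: c if c in ("happy_side", "sad_side") else collapse_condition(c)
    )
    data = data.assign(side=side)
    pooled: dict[str, float] = {}
    for producer in ("human", "llm"):
        for s in ("sad_side", "happy_side"):
            cell = data[(data["producer"] == producer) & (data["side"] == s)]
            if cell.empty:
                raise ValueError(f"empty cell: producer={producer}, condition={s}")
            pooled[f"{producer}_{s}"] = float(
                cell["count"].sum() / cell["word_count"].sum()
            )

    k = data["count"].to_numpy(dtype=float)
    n = data["word_count"].to_numpy(dtype=float)
    prod_code = np.where(data["producer"] == "human", 0.5, -0.5)
    cond_code = np.where(data["side"] == "sad_side", 0.5, -0.5)
    X = np.column_stack([np.ones_like(k), prod_code, cond_code, prod_code * cond_code])
    fit = _fit_proportion_glm(
        k, n, X, ["intercept", "producer", "condition", "interaction"]
    )
    fit.contrasts["interaction"] = fit.coefficients["interaction"]
    fit.contrasts["condition_sad_minus_happy"] = fit.coefficients["condition"]
    fit.extras["pooled_proportions"] = pooled
    fit.extras.pop("cov", None)
    return fit
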