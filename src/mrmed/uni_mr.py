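"""Univariable two-sample Mendelian randomization estimators.

Four estimators over a harmonized single-exposure variant set:

* inverse-variance weighted (IVW) with a multiplicative random-effects
  standard error — the main analysis;
* MR-Egger regression, whose intercept estimates average directional
  pleiotropy (slope consistent under the InSIDE assumption);
* the weighted median, consistent when under half the weight comes from
  invalid instruments, with a parametric-bootstrap standard error;
* the contamination-mixture model, which profiles a two-component normal
  mixture likelihood (valid instruments centred on the causal effect,
  invalid ones centred on zero) over a grid of candidate effects.

All estimates are on the log-OR per exposure-SD scale and are exponentiated
into odds ratios for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, ValidationError
from .summary_stats import HarmonizedSet

Z95 = float(stats.norm.ppf(0.975))

#: Profile log-likelihood drop defining the 95% CI (chi2_1 quantile / 2).
CONMIX_LL_DROP = 1.92


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-OR-per-SD scale.

    ``se`` is ``None`` for the contamination mixture, whose interval comes
    from the profile likelihood rather than a normal approximation.
    ``ci_status`` is ``"ok"`` for a contiguous interval, ``"non_contiguous"``
    when the profile-likelihood acceptance set splits into disjoint pieces,
    and ``"failed"`` when it touches the search-grid boundary.
    """

    method: str
    beta: float
    se: float | None
    ci_low: float
    ci_high: float
    n_variants: int
    exposure: str = "exposure"
    q_statistic: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    ci_status: str = "ok"

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    @property
    def pvalue(self) -> float | None:
        if self.se is None or self.se == 0:
            return None
        return float(2 * stats.norm.sf(abs(self.beta) / self.se))


def _single_exposure(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray,
                                                   np.ndarray, np.ndarray]:
    if hset.n_exposures != 1:
        raise ValidationError(
            f"univariable MR requires exactly one exposure, got "
            f"{hset.n_exposures}")
    return (hset.exposure_betas[:, 0], hset.exposure_ses[:, 0],
            hset.outcome_betas, hset.outcome_ses)


def cochran_q(hset: HarmonizedSet) -> float:
    """Cochran's Q heterogeneity statistic of the per-variant ratio estimates.

    Q = sum_j w_j (theta_j - theta_ivw)^2 with theta_j = bY_j / bX_j and
    w_j = bX_j^2 / seY_j^2; zero iff all ratio estimates agree.
    """
    bx, _, by, sy = _single_exposure(hset)
    if hset.n_variants < 2:
        raise ValidationError("Cochran's Q requires at least two variants")
    w = bx**2 / sy**2
    theta_hat = np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = by - theta_hat * bx
    # regression form: w_j (theta_j - theta)^2 == resid_j^2 / seY_j^2,
    # well defined even when some bX_j == 0
    return float(np.sum(resid**2 / sy**2))


def ivw(hset: HarmonizedSet, re_model: str = "multiplicative") -> MREstimate:
    """Inverse-variance weighted estimate (zero-intercept WLS form).

    ``re_model="multiplicative"`` (the default main analysis) inflates the
    fixed-effect SE by max(1, sqrt(Q / (J - 1))); ``"fixed"`` reports the
    unscaled SE.
    """
    if re_model not in ("fixed", "multiplicative"):
        raise ValidationError(f"unknown re_model {re_model!r}")
    bx, _, by, sy = _single_exposure(hset)
    j = hset.n_variants
    if j < 1:
        raise ValidationError("IVW requires at least one variant")
    denom = np.sum(bx**2 / sy**2)
    if denom == 0:
        raise DegenerateDesignError("all exposure betas are zero")
    theta = float(np.sum(bx * by / sy**2) / denom)
    se_fixed = float(1.0 / np.sqrt(denom))
    q = float(np.sum((by - theta * bx) ** 2 / sy**2)) if j >= 2 else None
    se = se_fixed
    if re_model == "multiplicative" and j >= 2:
        se = se_fixed * max(1.0, np.sqrt(q / (j - 1)))
    return MREstimate(
        method="ivw", beta=theta, se=se,
        ci_low=theta - Z95 * se, ci_high=theta + Z95 * se,
        n_variants=j, exposure=hset.trait_names[0], q_statistic=q)


def egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger regression with directional-pleiotropy intercept test.

    Variant rows are oriented so all exposure betas are non-negative (the
    intercept is orientation dependent), then outcome betas are regressed on
    exposure betas with an intercept, weighted by 1/seY^2.  Both SEs carry
    the multiplicative random-effects factor max(1, sqrt(Q / (J - 2)));
    the intercept p-value uses a t distribution on J - 2 df.
    """
    bx, _, by, sy = _single_exposure(hset)
    j = hset.n_variants
    if j < 3:
        raise ValidationError("MR-Egger requires at least three variants")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0:
        raise DegenerateDesignError(
            "exposure betas have zero variance after orientation")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(j), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q / (j - 2)))
    cov = np.linalg.inv(xtwx)
    se_int, se_slope = np.sqrt(np.diag(cov)) * scale
    intercept, slope = coef
    p_int = float(2 * stats.t.sf(abs(intercept) / se_int, df=j - 2))
    return MREstimate(
        method="egger", beta=float(slope), se=float(se_slope),
        ci_low=float(slope - Z95 * se_slope),
        ci_high=float(slope + Z95 * se_slope),
        n_variants=j, exposure=hset.trait_names[0], q_statistic=q,
        egger_intercept=float(intercept),
        egger_intercept_se=float(se_int), egger_intercept_p=p_int)


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    theta, w = theta[order], w[order]
    wn = w / w.sum()
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, theta))


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted median of the per-variant ratio estimates.

    The ratio estimates theta_j = bY_j / bX_j carry inverse-variance weights
    (seY_j / bX_j)^-2; the estimate interpolates the weighted empirical
    distribution at probability one half.  The SE is the standard deviation
    of the estimate over ``n_boot`` parametric-bootstrap draws of the summary
    statistics (``n_boot=0`` skips the bootstrap and reports no SE/CI).
    """
    bx, sx, by, sy = _single_exposure(hset)
    j = hset.n_variants
    if j < 3:
        raise ValidationError("weighted median requires at least three variants")
    if np.any(bx == 0):
        raise DegenerateDesignError("zero exposure beta gives an undefined ratio")
    theta = by / bx
    w = (bx / sy) ** 2
    est = _weighted_median(theta, w)
    if n_boot <= 0:
        return MREstimate(method="weighted_median", beta=est, se=None,
                          ci_low=np.nan, ci_high=np.nan, n_variants=j,
                          exposure=hset.trait_names[0], ci_status="ok")
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        ok = bxb != 0
        boot[b] = _weighted_median(byb[ok] / bxb[ok], (bxb[ok] / sy[ok]) ** 2)
    se = float(np.std(boot, ddof=1))
    return MREstimate(
        method="weighted_median", beta=est, se=se,
        ci_low=est - Z95 * se, ci_high=est + Z95 * se,
        n_variants=j, exposure=hset.trait_names[0])


def conmix_profile(theta_j: np.ndarray, se_j: np.ndarray, psi: float,
                   grid: np.ndarray) -> np.ndarray:
    """Profile log-likelihood of the contamination mixture over ``grid``.

    For each candidate causal effect, each variant contributes the larger of
    its valid-component log-density N(theta, se_j^2) and its
    invalid-component log-density N(0, se_j^2 + psi^2); the profile is the
    sum over variants (variants allocated to their best component).
    """
    g = grid[:, None]
    ll_valid = stats.norm.logpdf(theta_j[None, :], loc=g, scale=se_j[None, :])
    s_inv = np.sqrt(se_j**2 + psi**2)
    ll_invalid = stats.norm.logpdf(theta_j, loc=0.0, scale=s_inv)[None, :]
    return np.maximum(ll_valid, ll_invalid).sum(axis=1)


def contamination_mixture(hset: HarmonizedSet, psi: float | str = "auto",
                          grid: np.ndarray | None = None,
                          n_grid: int = 2001) -> MREstimate:
    """Contamination-mixture robust estimate with profile-likelihood CI.

    ``psi`` is the SD of invalid instruments' effects about zero; ``"auto"``
    uses 1.5 times the SD of the ratio estimates.  The default grid spans the
    IVW estimate +/- 5 multiplicative-random-effects SEs at ``n_grid``
    points.  The 95% interval is the set of grid effects within 1.92
    log-likelihood units of the maximum; if that set is a union of disjoint
    intervals the status is ``non_contiguous``, and if it touches the grid
    boundary the status is ``failed`` (no exception either way — weak or
    conflicting instruments genuinely produce such intervals).
    """
    bx, _, by, sy = _single_exposure(hset)
    j = hset.n_variants
    if j < 3:
        raise ValidationError(
            "contamination mixture requires at least three variants")
    if np.any(bx == 0):
        raise DegenerateDesignError("zero exposure beta gives an undefined ratio")
    theta_j = by / bx
    se_j = sy / np.abs(bx)
    if psi == "auto":
        psi_val = 1.5 * float(np.std(theta_j, ddof=1))
        if psi_val == 0:
            psi_val = float(np.mean(se_j))
    else:
        psi_val = float(psi)
        if psi_val <= 0:
            raise ValidationError("psi must be positive")
    if grid is None:
        anchor = ivw(hset)
        grid = np.linspace(anchor.beta - 5 * anchor.se,
                           anchor.beta + 5 * anchor.se, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
    ll = conmix_profile(theta_j, se_j, psi_val, grid)
    best = int(np.argmax(ll))
    mask = ll >= ll[best] - CONMIX_LL_DROP
    idx = np.flatnonzero(mask)
    status = "ok"
    if mask[0] or mask[-1]:
        status = "failed"
    elif np.any(np.diff(idx) > 1):
        status = "non_contiguous"
    return MREstimate(
        method="conmix", beta=float(grid[best]), se=None,
        ci_low=float(grid[idx[0]]), ci_high=float(grid[idx[-1]]),
        n_variants=j, exposure=hset.trait_names[0], ci_status=status)


def all_estimators(hset: HarmonizedSet, n_boot: int = 1000,
                   seed: int = 0, psi: float | str = "auto",
                   re_model: str = "multiplicative") -> list[MREstimate]:
    """Run the main IVW analysis plus the three pleiotropy-robust estimators."""
    return [
        ivw(hset, re_model=re_model),
        contamination_mixture(hset, psi=psi),
        egger(hset),
        weighted_median(hset, n_boot=n_boot, seed=seed),
    ]
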