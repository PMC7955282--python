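"""Multivariable MR direct effects and mediated-proportion estimation.

Multivariable MR (MVMR) regresses the variant-outcome associations (log-OR
scale) jointly on the variant-exposure associations for K exposures, with
the intercept fixed at zero and weights equal to the inverse variance of the
outcome associations.  Each coefficient is the direct effect of that
exposure conditional on the others.  The proportion of the primary
exposure's total effect mediated through the adjusted-for traits is
PM = 1 - direct/total, with a propagation-of-error (delta-method) standard
error treating the two estimates as uncorrelated.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, ValidationError
from .summary_stats import (GENOME_WIDE_P, DEFAULT_R2, HarmonizedSet, LDInfo,
                            VariantAssociation, clump, harmonize,
                            select_instruments)
from .uni_mr import Z95, MREstimate, ivw

log = logging.getLogger("mrmed")


@dataclass(frozen=True)
class MediationResult:
    """Total effect, mediator-adjusted direct effect and proportion mediated.

    ``proportion_mediated`` satisfies 1 - direct_beta/total_beta exactly; its
    interval is symmetric and deliberately unclipped (sampling noise can push
    the bounds below 0 or above 1).
    """

    exposure: str
    adjusted_for: tuple[str, ...]
    total_beta: float
    total_se: float
    direct_beta: float
    direct_se: float
    proportion_mediated: float
    pm_se: float
    n_variants: int

    @property
    def pm_ci(self) -> tuple[float, float]:
        return (self.proportion_mediated - Z95 * self.pm_se,
                self.proportion_mediated + Z95 * self.pm_se)

    @property
    def direct_or(self) -> float:
        return float(np.exp(self.direct_beta))

    @property
    def direct_or_ci(self) -> tuple[float, float]:
        half = Z95 * self.direct_se
        return (float(np.exp(self.direct_beta - half)),
                float(np.exp(self.direct_beta + half)))


def mvmr(hset: HarmonizedSet) -> list[MREstimate]:
    """Zero-intercept weighted multivariable regression, one estimate per exposure.

    Weights are 1/seY^2; standard errors carry the multiplicative
    random-effects factor max(1, sqrt(Q / (J - K))).
    """
    j, k = hset.n_variants, hset.n_exposures
    if k < 2:
        raise ValidationError("MVMR requires at least two exposures")
    if j < k + 1:
        raise ValidationError(
            f"MVMR with {k} exposures needs at least {k + 1} variants, got {j}")
    X = hset.exposure_betas
    y = hset.outcome_betas
    w = 1.0 / hset.outcome_ses**2
    xtwx = X.T @ (w[:, None] * X)
    cond = np.linalg.cond(xtwx)
    if cond > 1e10:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        a, b = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise DegenerateDesignError(
            f"collinear exposure columns "
            f"{hset.trait_names[a]!r} and {hset.trait_names[b]!r}")
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q / (j - k)))
    ses = np.sqrt(np.diag(np.linalg.inv(xtwx))) * scale
    return [
        MREstimate(method="mvmr", beta=float(coef[i]), se=float(ses[i]),
                   ci_low=float(coef[i] - Z95 * ses[i]),
                   ci_high=float(coef[i] + Z95 * ses[i]),
                   n_variants=j, exposure=hset.trait_names[i], q_statistic=q)
        for i in range(k)
    ]


def proportion_mediated(total: MREstimate, direct: MREstimate,
                        adjusted_for: Sequence[str] = (),
                        covariance: float = 0.0) -> MediationResult:
    """Proportion mediated with a propagation-of-error interval.

    PM = 1 - direct/total on the log-OR scale.  The delta-method variance of
    the ratio R = direct/total is
    R^2 (se_d^2/d^2 + se_t^2/t^2 - 2 cov(d, t)/(d t)).  ``covariance``
    defaults to 0 — appropriate when the two estimates come from independent
    data, or when (as in published tables) only the marginal intervals are
    known.  When both estimates come from the same summary statistics,
    :func:`mediation_covariance` supplies the shared-noise term; ignoring it
    overstates the SE (see the methods note).
    """
    if total.beta == 0:
        raise ValidationError(
            "total effect is exactly zero; proportion mediated undefined")
    if total.se is None or direct.se is None:
        raise ValidationError("both estimates must carry standard errors")
    r = direct.beta / total.beta
    pm = 1.0 - r
    # algebraically r^2 (se_d^2/d^2 + se_t^2/t^2 - 2 cov/(d t)), written to
    # stay finite as d -> 0
    var = (direct.se**2 + r**2 * total.se**2
           - 2.0 * r * covariance) / total.beta**2
    se_pm = np.sqrt(max(var, 0.0))
    return MediationResult(
        exposure=total.exposure,
        adjusted_for=tuple(adjusted_for),
        total_beta=total.beta, total_se=total.se,
        direct_beta=direct.beta, direct_se=direct.se,
        proportion_mediated=float(pm), pm_se=float(se_pm),
        n_variants=direct.n_variants)


def mediation_covariance(pooled: HarmonizedSet,
                         total_ids: Sequence[str],
                         exposure_index: int = 0) -> float:
    """Sampling covariance between the MVMR direct effect and the IVW total.

    Both estimates are linear in the same outcome betas.  Conditional on the
    exposure matrices, cov(direct, total) = [ (X'WX)^{-1} c ]_e / S_A with
    c = X_A' W_A x_A and S_A = x_A' W_A x_A, where A is the total-effect
    instrument subset of the pooled set and e the primary-exposure column.
    No random-effects scaling enters: overdispersion of the total effect
    (mediated heterogeneity) is absorbed by the mediator columns in MVMR
    and contributes no shared noise.
    """
    X = pooled.exposure_betas
    w = 1.0 / pooled.outcome_ses**2
    in_a = np.array([v in set(total_ids) for v in pooled.variant_ids])
    if not in_a.any():
        return 0.0
    x_a = X[in_a, exposure_index]
    w_a = w[in_a]
    s_a = float(np.sum(w_a * x_a**2))
    if s_a == 0:
        return 0.0
    c = (X[in_a].T * (w_a * x_a)).sum(axis=1)
    xtwx = X.T @ (w[:, None] * X)
    return float(np.linalg.solve(xtwx, c)[exposure_index] / s_a)


def pooled_instruments(exposures: Mapping[str, Sequence[VariantAssociation]],
                       ld: LDInfo,
                       p_threshold: float = GENOME_WIDE_P,
                       r2_threshold: float = DEFAULT_R2) -> list[str]:
    """MVMR instrument selection: pool, then clump on the minimum p per variant.

    Variants genome-wide significant for any trait are pooled and clumped to
    pairwise r2 below threshold, ranked by the lowest p-value for their
    association with any trait.
    """
    min_p: dict[str, float] = {}
    pool: dict[str, VariantAssociation] = {}
    for assocs in exposures.values():
        for a in select_instruments(assocs, p_threshold):
            if a.variant_id not in min_p or a.pvalue < min_p[a.variant_id]:
                min_p[a.variant_id] = a.pvalue
                pool[a.variant_id] = a
    if not pool:
        raise ValidationError("no variant reaches the selection threshold "
                              "for any trait")
    kept = clump(list(pool.values()), ld, r2_threshold, rank_p=min_p)
    return [a.variant_id for a in kept]


def _restrict(assocs: Sequence[VariantAssociation],
              ids: set[str]) -> list[VariantAssociation]:
    return [a for a in assocs if a.variant_id in ids]


def _total_hset(exposure: Sequence[VariantAssociation],
                outcome: Sequence[VariantAssociation], ld: LDInfo,
                p_threshold: float, r2_threshold: float,
                drop_palindromic: bool,
                exposure_name: str = "exposure") -> HarmonizedSet:
    sel = select_instruments(exposure, p_threshold)
    if not sel:
        raise ValidationError("no instruments reach the selection threshold")
    sel = clump(sel, ld, r2_threshold)
    return harmonize({exposure_name: sel},
                     _restrict(outcome, {a.variant_id for a in sel}),
                     drop_palindromic=drop_palindromic)


def total_effect(exposure: Sequence[VariantAssociation],
                 outcome: Sequence[VariantAssociation], ld: LDInfo,
                 p_threshold: float = GENOME_WIDE_P,
                 r2_threshold: float = DEFAULT_R2,
                 drop_palindromic: bool = True,
                 re_model: str = "multiplicative") -> MREstimate:
    """Univariable IVW total effect on the exposure's own instrument set."""
    return ivw(_total_hset(exposure, outcome, ld, p_threshold, r2_threshold,
                           drop_palindromic), re_model=re_model)


def mediation_pipeline(exposure: Sequence[VariantAssociation],
                       mediators: Mapping[str, Sequence[VariantAssociation]],
                       outcome: Sequence[VariantAssociation],
                       ld: LDInfo,
                       exposure_name: str = "exposure",
                       p_threshold: float = GENOME_WIDE_P,
                       r2_threshold: float = DEFAULT_R2,
                       drop_palindromic: bool = True,
                       subsets: Sequence[Sequence[str]] | None = None,
                       ) -> list[MediationResult]:
    """Full mediation analysis: total effect, then MVMR per mediator subset.

    The total effect is the univariable IVW estimate on the exposure's own
    clumped instruments.  Each mediator subset (by default every single
    mediator, then all together) gets its own pooled-and-clumped instrument
    set, a joint harmonization, an MVMR fit, and a proportion-mediated
    estimate for the primary exposure.
    """
    if not mediators:
        raise ValidationError("mediation requires at least one mediator")
    thset = _total_hset(exposure, outcome, ld, p_threshold, r2_threshold,
                        drop_palindromic, exposure_name=exposure_name)
    total = ivw(thset)
    if subsets is None:
        names = list(mediators)
        subsets = [[n] for n in names]
        if len(names) > 1:
            subsets.append(names)

    results: list[MediationResult] = []
    for subset in subsets:
        traits = {exposure_name: exposure}
        traits.update({n: mediators[n] for n in subset})
        ids = set(pooled_instruments(traits, ld, p_threshold, r2_threshold))
        hset = harmonize({n: _restrict(a, ids) for n, a in traits.items()},
                         _restrict(outcome, ids),
                         drop_palindromic=drop_palindromic)
        estimates = mvmr(hset)
        direct = next(e for e in estimates if e.exposure == exposure_name)
        cov = mediation_covariance(
            hset, thset.variant_ids,
            exposure_index=hset.trait_names.index(exposure_name))
        res = proportion_mediated(total, direct, adjusted_for=tuple(subset),
                                  covariance=cov)
        log.info("mediation (%s | %s): PM = %.3f (SE %.3f) on %d variants",
                 exposure_name, "+".join(subset), res.proportion_mediated,
                 res.pm_se, res.n_variants)
        results.append(res)
    return results


def mediation_table(results: Sequence[MediationResult]) -> pd.DataFrame:
    """Tabulate mediation results the way MR mediation figures report them."""
    rows = []
    for r in results:
        lo, hi = r.direct_or_ci
        pm_lo, pm_hi = r.pm_ci
        rows.append({
            "exposure": r.exposure,
            "adjusted_for": "+".join(r.adjusted_for),
            "n_snps": r.n_variants,
            "adjusted_or": r.direct_or,
            "adjusted_or_lci": lo,
            "adjusted_or_uci": hi,
            "pm_percent": 100.0 * r.proportion_mediated,
            "pm_lci_percent": 100.0 * pm_lo,
            "pm_uci_percent": 100.0 * pm_hi,
        })
    return pd.DataFrame(rows)
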