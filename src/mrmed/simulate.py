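"""Synthetic two-sample GWAS summary statistics with known ground truth.

Two generation paths:

* :func:`simulate_summary_stats` draws the summary statistics directly from
  their sampling distributions (fast; independent exposure and outcome
  samples).  Per-variant effects of the exposure are drawn from a normal
  distribution truncated away from zero, standard errors follow the usual
  GWAS approximations (1/sqrt(N * 2*maf*(1-maf)) for a continuous trait, an
  extra case-fraction factor for a binary outcome on the log-OR scale), and
  the outcome betas encode a causal effect, optional horizontal pleiotropy
  and an optional mediation structure.

* :func:`simulate_individual_level` simulates genotypes, a shared
  confounder, a continuous exposure and a binary outcome, then runs the
  per-variant linear/logistic regressions.  Only this path can represent
  participant overlap between the exposure and outcome samples, which biases
  weak-instrument MR toward the confounded observational association.

All randomness flows from the scenario seed through per-variant substreams,
so enlarging ``n_variants`` never perturbs earlier variants' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .errors import ConfigurationError, ValidationError
from .summary_stats import (HarmonizedSet, LDInfo, VariantAssociation,
                            harmonize, two_sided_p)

#: Non-palindromic allele pairs a simulated SNP may take.
_NON_PALINDROMIC = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))
_PALINDROMIC = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass(frozen=True)
class MediatorSpec:
    """One mediator trait in a mediation scenario.

    ``rho_em``: effect of the exposure on the mediator (per exposure SD);
    ``theta_med``: mediator -> outcome log-OR per mediator unit;
    ``delta_sd``: SD of per-variant mediator effects independent of the
    exposure (these make the MVMR design full rank).
    """

    name: str
    rho_em: float
    theta_med: float
    delta_sd: float = 0.02


@dataclass(frozen=True)
class SimulationScenario:
    """Full data-generating configuration for a synthetic two-sample study.

    Defaults emulate a well-powered consortium setting: a few dozen common
    (MAF 0.05-0.5) genome-wide-significant instruments with per-variant
    effects ~ Normal(0, 0.05^2) truncated away from zero, a continuous
    exposure GWAS of 200,000, and a binary-outcome GWAS of 400,000 with a
    15% case fraction (log-OR scale).
    """

    n_variants: int = 50
    gamma: tuple[float, ...] | None = None
    gamma_sd: float = 0.05
    gamma_min: float = 0.01
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure: int = 200_000
    n_outcome: int = 400_000
    case_fraction: float = 0.15
    theta: float = 0.0
    pleiotropy_model: str = "none"  # none|balanced|directional|inside_violating
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_corr: float = 0.5
    invalid_fraction: float = 0.0
    invalid_offset: float = 0.0
    mediators: tuple[MediatorSpec, ...] = ()
    theta_dir: float = 0.0
    overlap_fraction: float = 0.0
    confounder_effect: float = 0.0
    palindrome_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 3:
            raise ValidationError("scenarios need at least 3 variants")
        if self.n_exposure < 100 or self.n_outcome < 100:
            raise ValidationError("sample sizes must be at least 100")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValidationError("case_fraction must lie in (0, 1)")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValidationError("overlap_fraction must lie in [0, 1]")
        if self.pleiotropy_model not in ("none", "balanced", "directional",
                                         "inside_violating"):
            raise ValidationError(
                f"unknown pleiotropy model {self.pleiotropy_model!r}")
        for v in (self.gamma_sd, self.pleiotropy_sd):
            if v < 0:
                raise ValidationError("variance parameters must be >= 0")
        if self.gamma is not None and len(self.gamma) != self.n_variants:
            raise ValidationError("fixed gamma vector length != n_variants")
        if not (0.0 <= self.invalid_fraction <= 1.0):
            raise ValidationError("invalid_fraction must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("maf_range must satisfy 0 < lo <= hi < 1")

    @property
    def theta_total(self) -> float:
        """True total exposure -> outcome effect (direct plus mediated)."""
        if not self.mediators:
            return self.theta
        return self.theta_dir + sum(m.rho_em * m.theta_med
                                    for m in self.mediators)

    def true_direct(self, adjusted_for: Sequence[str]) -> float:
        """Direct effect left after adjusting for the named mediators."""
        names = set(adjusted_for)
        unknown = names - {m.name for m in self.mediators}
        if unknown:
            raise ValidationError(f"unknown mediators {sorted(unknown)}")
        return self.theta_dir + sum(m.rho_em * m.theta_med
                                    for m in self.mediators
                                    if m.name not in names)

    def true_pm(self, adjusted_for: Sequence[str] | None = None) -> float:
        """True proportion mediated, 1 - direct/total."""
        if not self.mediators:
            raise ValidationError("no mediation structure in this scenario")
        names = adjusted_for if adjusted_for is not None else [
            m.name for m in self.mediators]
        return 1.0 - self.true_direct(names) / self.theta_total


@dataclass(frozen=True)
class SyntheticStudy:
    """Generated summary statistics plus the ground truth that produced them."""

    exposures: dict[str, list[VariantAssociation]]
    outcome: list[VariantAssociation]
    ld: LDInfo
    truth: dict
    scenario: SimulationScenario

    def harmonized(self, traits: Sequence[str] | None = None,
                   drop_palindromic: bool = True) -> HarmonizedSet:
        """Harmonize selected exposure traits (default: all) with the outcome."""
        names = list(traits) if traits is not None else list(self.exposures)
        return harmonize({t: self.exposures[t] for t in names}, self.outcome,
                         drop_palindromic=drop_palindromic)


def _variant_rng(seed: int, j: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(j,)))


def _alleles(rng: np.random.Generator, palindrome_fraction: float
             ) -> tuple[str, str]:
    if palindrome_fraction > 0 and rng.random() < palindrome_fraction:
        return _PALINDROMIC[rng.integers(len(_PALINDROMIC))]
    return _NON_PALINDROMIC[rng.integers(len(_NON_PALINDROMIC))]


def _draw_gamma(rng: np.random.Generator, sd: float, minimum: float) -> float:
    """Normal(0, sd^2) truncated away from zero (rejection below |minimum|)."""
    while True:
        g = rng.normal(0.0, sd)
        if abs(g) >= minimum:
            return float(g)


def simulate_summary_stats(scenario: SimulationScenario) -> SyntheticStudy:
    """Draw summary statistics directly from their sampling distributions."""
    sc = scenario
    j_total = sc.n_variants
    exposures: dict[str, list[VariantAssociation]] = {"exposure": []}
    for m in sc.mediators:
        exposures[m.name] = []
    outcome: list[VariantAssociation] = []
    ids = [f"rs{j + 1}" for j in range(j_total)]

    theta_direct = sc.theta_dir if sc.mediators else sc.theta
    for j in range(j_total):
        rng = _variant_rng(sc.seed, j)
        maf = float(rng.uniform(*sc.maf_range))
        var_g = 2.0 * maf * (1.0 - maf)
        ea, oa = _alleles(rng, sc.palindrome_fraction)
        gamma = (sc.gamma[j] if sc.gamma is not None
                 else _draw_gamma(rng, sc.gamma_sd, sc.gamma_min))

        # horizontal pleiotropy on the outcome
        alpha = 0.0
        if sc.pleiotropy_model == "balanced":
            alpha = rng.normal(0.0, sc.pleiotropy_sd)
        elif sc.pleiotropy_model == "directional":
            alpha = rng.normal(sc.pleiotropy_mean, sc.pleiotropy_sd)
        elif sc.pleiotropy_model == "inside_violating":
            z = rng.normal()
            rho = sc.pleiotropy_corr
            alpha = sc.pleiotropy_sd * (rho * gamma / sc.gamma_sd
                                        + np.sqrt(1 - rho**2) * z)
        if sc.invalid_fraction > 0 and rng.random() < sc.invalid_fraction:
            alpha += sc.invalid_offset * gamma

        se_x = 1.0 / np.sqrt(sc.n_exposure * var_g)
        bx = float(rng.normal(gamma, se_x))
        exposures["exposure"].append(VariantAssociation(
            ids[j], ea, oa, beta=bx, se=se_x, eaf=maf, n=sc.n_exposure))

        mediated = 0.0
        for m in sc.mediators:
            delta = rng.normal(0.0, m.delta_sd) if m.delta_sd > 0 else 0.0
            mean_m = m.rho_em * gamma + delta
            se_m = 1.0 / np.sqrt(sc.n_exposure * var_g)
            bm = float(rng.normal(mean_m, se_m))
            exposures[m.name].append(VariantAssociation(
                ids[j], ea, oa, beta=bm, se=se_m, eaf=maf, n=sc.n_exposure))
            mediated += m.theta_med * mean_m

        se_y = 1.0 / np.sqrt(sc.n_outcome * sc.case_fraction
                             * (1.0 - sc.case_fraction) * var_g)
        mean_y = theta_direct * gamma + alpha + mediated
        by = float(rng.normal(mean_y, se_y))
        outcome.append(VariantAssociation(
            ids[j], ea, oa, beta=by, se=se_y, eaf=maf, n=sc.n_outcome))

    truth = {"theta_total": sc.theta_total, "theta_direct": theta_direct}
    if sc.mediators:
        truth["pm_true"] = sc.true_pm()
        truth["pm_by_subset"] = {
            m.name: sc.true_pm([m.name]) for m in sc.mediators}
    return SyntheticStudy(exposures=exposures, outcome=outcome,
                          ld=LDInfo.identity(ids), truth=truth, scenario=sc)


# ---------------------------------------------------------------------------
# individual-level path (participant overlap)
# ---------------------------------------------------------------------------

_MAX_J = 500
_MAX_N = 200_000


def _vectorized_logistic(y: np.ndarray, g: np.ndarray,
                         max_iter: int = 30, tol: float = 1e-10
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-column logistic regressions y ~ 1 + g[:, j], Newton-Raphson.

    Returns (slopes, slope SEs), one per column of ``g``.
    """
    n, j = g.shape
    b0 = np.full(j, float(logit(max(min(y.mean(), 1 - 1e-9), 1e-9))))
    b1 = np.zeros(j)
    for _ in range(max_iter):
        eta = b0[None, :] + g * b1[None, :]
        p = expit(eta)
        w = p * (1.0 - p)
        r = y[:, None] - p
        g0 = r.sum(axis=0)
        g1 = (g * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * g).sum(axis=0)
        h11 = (w * g * g).sum(axis=0)
        det = h00 * h11 - h01 * h01
        db0 = (h11 * g0 - h01 * g1) / det
        db1 = (h00 * g1 - h01 * g0) / det
        b0 += db0
        b1 += db1
        if max(np.abs(db0).max(), np.abs(db1).max()) < tol:
            break
    eta = b0[None, :] + g * b1[None, :]
    p = expit(eta)
    w = p * (1.0 - p)
    h00 = w.sum(axis=0)
    h01 = (w * g).sum(axis=0)
    h11 = (w * g * g).sum(axis=0)
    det = h00 * h11 - h01 * h01
    se1 = np.sqrt(h00 / det)
    return b1, se1


def simulate_individual_level(scenario: SimulationScenario) -> SyntheticStudy:
    """Simulate genotypes and phenotypes, then run the per-variant GWAS.

    Exposure: X = sum_j gamma_j g_j + b_ux U + eps with U ~ N(0,1) a shared
    confounder and eps scaled so Var(X) ~ 1.  Outcome: logistic in theta*X
    and U, with the confounder loadings chosen so that under the null the
    observational log-OR of outcome on exposure is approximately
    ``confounder_effect``.  The exposure and outcome samples share
    ``overlap_fraction`` of the smaller sample's individuals.
    """
    sc = scenario
    if sc.n_variants > _MAX_J or max(sc.n_exposure, sc.n_outcome) > _MAX_N:
        raise ConfigurationError(
            f"individual-level path limited to J <= {_MAX_J} and "
            f"N <= {_MAX_N}")
    rng = np.random.default_rng(np.random.SeedSequence(sc.seed,
                                                       spawn_key=(2**20,)))
    j = sc.n_variants
    ids = [f"rs{i + 1}" for i in range(j)]
    maf = rng.uniform(*sc.maf_range, size=j)
    if sc.gamma is not None:
        gamma = np.asarray(sc.gamma, dtype=float)
    else:
        gamma = np.array([_draw_gamma(rng, sc.gamma_sd, sc.gamma_min)
                          for _ in range(j)])
    alleles = [_alleles(rng, sc.palindrome_fraction) for _ in range(j)]

    n_shared = int(round(sc.overlap_fraction * min(sc.n_exposure, sc.n_outcome)))
    n_total = sc.n_exposure + sc.n_outcome - n_shared

    b_ux = 0.7
    var_g = float(np.sum(gamma**2 * 2 * maf * (1 - maf)))
    eps_sd = np.sqrt(max(1.0 - b_ux**2 - var_g, 0.05))
    b_uy = sc.confounder_effect / b_ux

    g = rng.binomial(2, maf[None, :], size=(n_total, j)).astype(np.float64)
    u = rng.standard_normal(n_total)
    x = g @ gamma + b_ux * u + eps_sd * rng.standard_normal(n_total)
    eta = logit(sc.case_fraction) + sc.theta * x + b_uy * u
    y = (rng.random(n_total) < expit(eta)).astype(np.float64)

    exp_idx = slice(0, sc.n_exposure)
    out_idx = slice(n_total - sc.n_outcome, n_total)

    # per-variant linear regression of X on genotype in the exposure sample
    ge, xe = g[exp_idx], x[exp_idx]
    n_e = ge.shape[0]
    gc = ge - ge.mean(axis=0)
    xc = xe - xe.mean()
    ss_g = (gc**2).sum(axis=0)
    bx = (gc * xc[:, None]).sum(axis=0) / ss_g
    resid_ss = ((xc[:, None] - gc * bx[None, :])**2).sum(axis=0)
    se_x = np.sqrt(resid_ss / (n_e - 2) / ss_g)

    # per-variant logistic regression of the outcome on genotype
    by, se_y = _vectorized_logistic(y[out_idx], g[out_idx])

    exposure = [VariantAssociation(ids[i], *alleles[i], beta=float(bx[i]),
                                   se=float(se_x[i]), eaf=float(maf[i]),
                                   n=sc.n_exposure)
                for i in range(j)]
    outcome = [VariantAssociation(ids[i], *alleles[i], beta=float(by[i]),
                                  se=float(se_y[i]), eaf=float(maf[i]),
                                  n=sc.n_outcome)
               for i in range(j)]

    # observational log-OR of outcome on exposure in the outcome sample
    obs_b, _ = _vectorized_logistic(y[out_idx], x[out_idx, None])

    truth = {
        "theta_total": sc.theta,
        "theta_direct": sc.theta,
        "obs_logor": float(obs_b[0]),
        "mean_f": float(np.mean((bx / se_x)**2)),
        "n_shared": n_shared,
    }
    return SyntheticStudy(exposures={"exposure": exposure}, outcome=outcome,
                          ld=LDInfo.identity(ids), truth=truth, scenario=sc)
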