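"""Instrument-strength diagnostics, power, and sample-overlap bias.

Closed forms:

* per-instrument F statistic (beta/SE)^2 — weak instruments (low F) amplify
  bias from participant overlap;
* minimum detectable OR for a binary outcome given the variance in the
  exposure explained by the instruments;
* expected bias under the null and type-I error when the exposure and
  outcome samples overlap: the confounded observational association leaks
  into the MR estimate attenuated by instrument strength and scaled by the
  overlap fraction, shifting the z-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .summary_stats import HarmonizedSet


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for a minimum-detectable-OR calculation.

    ``n`` is the outcome-analysis sample size, ``case_fraction`` its case
    proportion, ``r2`` the variance in the exposure explained by the
    instruments.
    """

    n: int
    case_fraction: float
    r2: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        for name in ("case_fraction", "alpha", "power"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if not (0.0 < self.r2 < 1.0):
            raise ValidationError("r2 must lie in (0, 1)")
        if self.n <= 0:
            raise ValidationError("sample size must be positive")


@dataclass(frozen=True)
class OverlapSpec:
    """Inputs for the sample-overlap bias calculation.

    ``observational_bias`` is the confounded observational log-OR per unit
    exposure; ``mean_f`` the mean instrument F statistic; ``se_mr`` the
    standard error of the MR estimate being tested.
    """

    overlap_fraction: float
    observational_bias: float
    mean_f: float
    se_mr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValidationError("overlap_fraction must lie in [0, 1]")
        if self.mean_f <= 0:
            raise ValidationError("mean_f must be positive")
        if self.se_mr <= 0:
            raise ValidationError("se_mr must be positive")


def f_statistic(beta_x: float, se_x: float) -> float:
    """Single-instrument strength, F = (beta/SE)^2."""
    if se_x <= 0:
        raise ValidationError(f"standard error must be positive, got {se_x}")
    return float((beta_x / se_x) ** 2)


def f_statistics(hset: HarmonizedSet, trait: int = 0) -> np.ndarray:
    """Per-variant F statistics for one exposure column."""
    bx = hset.exposure_betas[:, trait]
    sx = hset.exposure_ses[:, trait]
    return (bx / sx) ** 2


def minimum_detectable_or(spec: PowerSpec) -> float:
    """Smallest OR (> 1 direction) detectable at the given power and alpha.

    The MR estimate's SE is approximated by
    1/sqrt(n * r2 * p * (1 - p)); the detectable log-OR is
    (z_{1-alpha/2} + z_{power}) times that SE.  The protective bound is the
    reciprocal of the returned OR.
    """
    se_theta = 1.0 / np.sqrt(spec.n * spec.r2 * spec.case_fraction
                             * (1.0 - spec.case_fraction))
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0) + stats.norm.ppf(spec.power)
    return float(np.exp(z * se_theta))


def overlap_bias(spec: OverlapSpec) -> tuple[float, float]:
    """Expected MR bias under the null and resulting type-I error.

    bias = overlap_fraction * observational_bias / mean_f: the confounded
    association is attenuated by instrument strength and enters in
    proportion to the overlapping participants.  The type-I error of the
    two-sided z-test at level alpha = 0.05 is the rejection probability of a
    standard normal shifted by bias/se_mr.
    """
    bias = spec.overlap_fraction * spec.observational_bias / spec.mean_f
    shift = bias / spec.se_mr
    z = stats.norm.ppf(0.975)
    type1 = float(stats.norm.cdf(-z + shift) + stats.norm.cdf(-z - shift))
    return float(bias), type1


def instrument_diagnostics(hset: HarmonizedSet,
                           n: int | None = None) -> pd.DataFrame:
    """Per-exposure diagnostics: variant count, F statistics, summed r2.

    r2 per variant uses beta^2 * 2*eaf*(1-eaf) when frequencies are stored
    on the set, else the z^2/n approximation (requires ``n``).
    """
    rows = []
    for k, name in enumerate(hset.trait_names):
        f = f_statistics(hset, k)
        bx = hset.exposure_betas[:, k]
        sx = hset.exposure_ses[:, k]
        if n is not None:
            r2 = float(np.sum((bx / sx) ** 2 / n))
        else:
            r2 = float("nan")
        rows.append({"trait": name, "n_snps": hset.n_variants,
                     "mean_f": float(f.mean()), "min_f": float(f.min()),
                     "r2_sum": r2})
    return pd.DataFrame(rows)
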