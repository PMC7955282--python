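"""Ingestion, validation, harmonization, clumping and filtering of GWAS
summary statistics.

The analysis-ready object is a :class:`HarmonizedSet`: per-variant effect
estimates for K exposure traits and one (binary) outcome, aligned so every
trait's beta refers to the same effect allele.  Harmonization follows the
conventions of two-sample Mendelian randomization: traits are intersected on
variant id (no proxy lookup), alleles are aligned to the first exposure's
effect allele with sign flips where the pair is swapped, palindromic (A/T or
C/G) variants are excluded by default because their strand cannot be resolved
from alleles alone, and variants whose allele pairs disagree are dropped with
a logged count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError

log = logging.getLogger("mrmed")

VALID_BASES = frozenset("ACGT")
PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

#: Genome-wide significance threshold used for instrument selection.
GENOME_WIDE_P = 5e-8

#: Default pairwise LD threshold for clumping.
DEFAULT_R2 = 0.001

#: Canonical column names for tab-delimited summary statistics.
CANONICAL_COLUMNS = ("snp", "effect_allele", "other_allele", "eaf",
                     "beta", "se", "pval", "n")


def two_sided_p(beta: float, se: float) -> float:
    """Two-sided normal p-value for beta/se, clipped into (0, 1]."""
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return float(min(max(p, 5e-324), 1.0))


def _round_sig(x: float) -> float:
    """Round to one significant figure (0 maps to 0)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is the effect per effect-allele copy on the trait scale (log-OR
    for a binary trait); ``se`` its standard error.  ``pvalue`` may be
    omitted, in which case the two-sided normal p-value implied by beta/se is
    used.  ``eaf`` (effect-allele frequency) and ``n`` are optional metadata.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float | None = None
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES:
            raise ValidationError(
                f"{self.variant_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_BASES:
            raise ValidationError(
                f"{self.variant_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"{self.variant_id}: effect and other allele are identical")
        if not (self.se > 0) or not np.isfinite(self.se):
            raise ValidationError(
                f"{self.variant_id}: standard error must be positive, got {self.se}")
        if not np.isfinite(self.beta):
            raise ValidationError(f"{self.variant_id}: non-finite beta")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(
                f"{self.variant_id}: eaf {self.eaf} outside [0, 1]")
        if self.n is not None and self.n <= 0:
            raise ValidationError(f"{self.variant_id}: non-positive sample size")
        if self.pvalue is None:
            object.__setattr__(self, "pvalue", two_sided_p(self.beta, self.se))
        else:
            if not (0.0 < self.pvalue <= 1.0):
                raise ValidationError(
                    f"{self.variant_id}: p-value {self.pvalue} outside (0, 1]")
            implied = two_sided_p(self.beta, self.se)
            # stated and implied p must agree to rounding: compare either on
            # the p scale (one significant figure) or on the z scale (20%),
            # the latter being stable for extreme tail p-values as printed
            # in GWAS tables
            same_sig = _round_sig(self.pvalue) == _round_sig(implied)
            z_stated = stats.norm.isf(self.pvalue / 2.0)
            z_implied = abs(self.beta) / self.se
            z_ok = (max(z_stated, 0.0) <= 1.0 and z_implied <= 1.2) or (
                z_stated > 0 and 0.8 <= z_implied / z_stated <= 1.25)
            if not same_sig and not z_ok:
                raise ValidationError(
                    f"{self.variant_id}: p-value {self.pvalue:g} inconsistent "
                    f"with beta/se (implies {implied:g})")

    @property
    def is_palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)

    def flipped(self) -> "VariantAssociation":
        """The same association expressed for the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff {a1, a2} is {A, T} or {C, G} (strand-ambiguous pair)."""
    if a1 not in VALID_BASES or a2 not in VALID_BASES:
        raise ValidationError(f"invalid allele pair ({a1!r}, {a2!r})")
    if a1 == a2:
        raise ValidationError(f"alleles must be distinct, got {a1}/{a2}")
    return frozenset((a1, a2)) in PALINDROMIC_PAIRS


@dataclass(frozen=True)
class LDInfo:
    """Pairwise LD r-squared for an ordered set of variants."""

    variant_ids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(self.variant_ids)
        object.__setattr__(self, "variant_ids", ids)
        r2 = np.asarray(self.r2, dtype=float)
        object.__setattr__(self, "r2", r2)
        j = len(ids)
        if len(set(ids)) != j:
            raise ValidationError("duplicate variant ids in LD matrix")
        if r2.shape != (j, j):
            raise ValidationError(
                f"LD matrix shape {r2.shape} does not match {j} variants")
        if not np.allclose(r2, r2.T, atol=1e-10):
            raise ValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-10):
            raise ValidationError("LD matrix diagonal must be exactly 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise ValidationError("LD r2 values must lie in [0, 1]")

    @classmethod
    def identity(cls, variant_ids: Sequence[str]) -> "LDInfo":
        """All-independent LD (what pre-clumped instrument sets assume)."""
        return cls(tuple(variant_ids), np.eye(len(variant_ids)))

    def lookup(self, a: str, b: str) -> float:
        i = self.variant_ids.index(a)
        j = self.variant_ids.index(b)
        return float(self.r2[i, j])


def read_summary_stats(path, column_map: Mapping[str, str] | None = None,
                       ) -> list[VariantAssociation]:
    """Read a tab-delimited summary-statistics file.

    ``column_map`` maps canonical names (``snp``, ``effect_allele``,
    ``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``, ``n``) to the
    file's actual headers; by default the canonical names are expected.
    Rows missing beta or SE are dropped with a logged count; duplicate
    variant ids raise.
    """
    colmap = dict(zip(CANONICAL_COLUMNS, CANONICAL_COLUMNS))
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype={colmap["snp"]: str})
    for canonical in ("snp", "effect_allele", "other_allele", "beta", "se"):
        if colmap[canonical] not in df.columns:
            raise ConfigurationError(
                f"{path}: required column {colmap[canonical]!r} "
                f"(mapped from {canonical!r}) not found")

    n_raw = len(df)
    df = df.dropna(subset=[colmap["beta"], colmap["se"]])
    if len(df) < n_raw:
        log.info("%s: dropped %d rows with missing beta/se", path, n_raw - len(df))

    dup = df[colmap["snp"]].duplicated()
    if dup.any():
        first = df.loc[dup, colmap["snp"]].iloc[0]
        raise ValidationError(f"{path}: duplicated variant id {first!r}")

    out: list[VariantAssociation] = []
    for idx, row in df.iterrows():
        se = float(row[colmap["se"]])
        if not se > 0:
            raise ValidationError(
                f"{path}: non-positive SE at row {idx} ({row[colmap['snp']]})")
        def _opt(canonical):
            col = colmap[canonical]
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) else v
        eaf = _opt("eaf")
        pval = _opt("pval")
        n = _opt("n")
        out.append(VariantAssociation(
            variant_id=str(row[colmap["snp"]]),
            effect_allele=str(row[colmap["effect_allele"]]).upper(),
            other_allele=str(row[colmap["other_allele"]]).upper(),
            beta=float(row[colmap["beta"]]),
            se=se,
            pvalue=None if pval is None else float(pval),
            eaf=None if eaf is None else float(eaf),
            n=None if n is None else int(n),
        ))
    return out


def write_summary_stats(assocs: Sequence[VariantAssociation], path) -> None:
    """Write associations in the canonical tab-delimited dialect."""
    df = pd.DataFrame({
        "snp": [a.variant_id for a in assocs],
        "effect_allele": [a.effect_allele for a in assocs],
        "other_allele": [a.other_allele for a in assocs],
        "eaf": [a.eaf for a in assocs],
        "beta": [a.beta for a in assocs],
        "se": [a.se for a in assocs],
        "pval": [a.pvalue for a in assocs],
        "n": [a.n for a in assocs],
    })
    df.to_csv(path, sep="\t", index=False)


def read_ld_matrix(path) -> LDInfo:
    """Read a square tab-delimited r2 matrix with variant-id header row/column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LDInfo(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def select_instruments(assocs: Sequence[VariantAssociation],
                       p_threshold: float = GENOME_WIDE_P,
                       ) -> list[VariantAssociation]:
    """Keep associations with p strictly below ``p_threshold`` (order kept)."""
    if not (0.0 < p_threshold <= 1.0):
        raise ValidationError(f"p_threshold {p_threshold} outside (0, 1]")
    return [a for a in assocs if a.pvalue < p_threshold]


def clump(assocs: Sequence[VariantAssociation], ld: LDInfo,
          r2_threshold: float = DEFAULT_R2,
          rank_p: Mapping[str, float] | None = None,
          ) -> list[VariantAssociation]:
    """Greedy LD clumping prioritised by association p-value.

    Variants are ranked by ``rank_p`` (default: each record's own p-value;
    for multivariable instrument pooling pass the minimum p across traits),
    ties broken lexicographically on variant id.  The best-ranked variant is
    kept and all remaining variants with r2 >= ``r2_threshold`` against it
    are discarded; this repeats until no variants remain.  Every retained
    pair therefore has r2 < ``r2_threshold``.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValidationError(f"r2_threshold {r2_threshold} outside (0, 1]")
    pos = {v: i for i, v in enumerate(ld.variant_ids)}
    for a in assocs:
        if a.variant_id not in pos:
            raise ValidationError(
                f"variant {a.variant_id!r} absent from LD information")

    def rank(a: VariantAssociation) -> tuple[float, str]:
        p = rank_p.get(a.variant_id, a.pvalue) if rank_p else a.pvalue
        return (p, a.variant_id)

    remaining = sorted(assocs, key=rank)
    kept: list[VariantAssociation] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        bi = pos[best.variant_id]
        remaining = [a for a in remaining
                     if ld.r2[bi, pos[a.variant_id]] < r2_threshold]
    # report in the order selected (best p first)
    return kept


@dataclass(frozen=True)
class HarmonizedSet:
    """Aligned effect matrices for K exposures and one outcome.

    All traits share the same effect allele per variant.  ``exposure_betas``
    and ``exposure_ses`` are J x K; ``outcome_betas``/``outcome_ses`` are
    length-J vectors on the log-OR scale.  Allele columns record the common
    orientation so a set can be round-tripped through harmonization.
    """

    variant_ids: tuple[str, ...]
    exposure_betas: np.ndarray
    exposure_ses: np.ndarray
    outcome_betas: np.ndarray
    outcome_ses: np.ndarray
    trait_names: tuple[str, ...]
    palindromic_flags: np.ndarray
    effect_alleles: tuple[str, ...] = ()
    other_alleles: tuple[str, ...] = ()
    outcome_name: str = "outcome"

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant_ids", tuple(self.variant_ids))
        object.__setattr__(self, "trait_names", tuple(self.trait_names))
        object.__setattr__(self, "effect_alleles", tuple(self.effect_alleles))
        object.__setattr__(self, "other_alleles", tuple(self.other_alleles))
        for name in ("exposure_betas", "exposure_ses",
                     "outcome_betas", "outcome_ses"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "palindromic_flags",
                           np.asarray(self.palindromic_flags, dtype=bool))
        j, k = self.n_variants, self.n_exposures
        if j < 1:
            raise ValidationError("harmonized set must contain at least one variant")
        if len(set(self.variant_ids)) != j:
            raise ValidationError("duplicate variant ids in harmonized set")
        if self.exposure_betas.shape != (j, k) or self.exposure_ses.shape != (j, k):
            raise ValidationError("exposure matrices must be J x K")
        if self.outcome_betas.shape != (j,) or self.outcome_ses.shape != (j,):
            raise ValidationError("outcome vectors must have length J")
        if not (self.exposure_ses > 0).all() or not (self.outcome_ses > 0).all():
            raise ValidationError("all standard errors must be positive")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.trait_names)

    def single(self, trait: str | int = 0) -> "HarmonizedSet":
        """Restrict to a single exposure column (for univariable MR)."""
        k = trait if isinstance(trait, int) else self.trait_names.index(trait)
        return replace(
            self,
            exposure_betas=self.exposure_betas[:, [k]],
            exposure_ses=self.exposure_ses[:, [k]],
            trait_names=(self.trait_names[k],),
        )

    def to_assoc_lists(self) -> tuple[dict[str, list[VariantAssociation]],
                                      list[VariantAssociation]]:
        """Expand back into per-trait association lists (metadata-light)."""
        ea = self.effect_alleles or ("A",) * self.n_variants
        oa = self.other_alleles or ("G",) * self.n_variants
        exposures: dict[str, list[VariantAssociation]] = {}
        for k, name in enumerate(self.trait_names):
            exposures[name] = [
                VariantAssociation(self.variant_ids[j], ea[j], oa[j],
                                   beta=float(self.exposure_betas[j, k]),
                                   se=float(self.exposure_ses[j, k]))
                for j in range(self.n_variants)]
        outcome = [
            VariantAssociation(self.variant_ids[j], ea[j], oa[j],
                               beta=float(self.outcome_betas[j]),
                               se=float(self.outcome_ses[j]))
            for j in range(self.n_variants)]
        return exposures, outcome

    def to_dataframe(self) -> pd.DataFrame:
        data: dict[str, object] = {"snp": list(self.variant_ids)}
        if self.effect_alleles:
            data["effect_allele"] = list(self.effect_alleles)
            data["other_allele"] = list(self.other_alleles)
        for k, name in enumerate(self.trait_names):
            data[f"beta_{name}"] = self.exposure_betas[:, k]
            data[f"se_{name}"] = self.exposure_ses[:, k]
        data[f"beta_{self.outcome_name}"] = self.outcome_betas
        data[f"se_{self.outcome_name}"] = self.outcome_ses
        data["palindromic"] = self.palindromic_flags
        return pd.DataFrame(data)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def harmonize(exposures: Mapping[str, Sequence[VariantAssociation]]
              | Sequence[VariantAssociation],
              outcome: Sequence[VariantAssociation],
              drop_palindromic: bool = True,
              outcome_name: str = "outcome") -> HarmonizedSet:
    """Align exposure and outcome associations to a common effect allele.

    Variants are intersected across all traits (no proxies).  The first
    exposure's effect allele is the reference per variant: a trait whose
    allele pair is swapped has its beta sign flipped (and eaf complemented);
    a trait whose pair does not match in either order drops the variant with
    a logged count.  Palindromic variants are excluded when
    ``drop_palindromic`` (the main-analysis convention).
    """
    if not isinstance(exposures, Mapping):
        exposures = {"exposure": list(exposures)}
    if not exposures:
        raise ValidationError("at least one exposure trait is required")

    trait_lists = list(exposures.items()) + [(outcome_name, list(outcome))]
    by_id: list[dict[str, VariantAssociation]] = []
    for name, assocs in trait_lists:
        d: dict[str, VariantAssociation] = {}
        for a in assocs:
            if a.variant_id in d:
                raise ValidationError(
                    f"{name}: duplicate variant id {a.variant_id!r}")
            d[a.variant_id] = a
        by_id.append(d)

    ref = by_id[0]
    common = [v for v in ref if all(v in d for d in by_id[1:])]
    if not common:
        raise ValidationError("no variants present for all traits")

    kept_ids: list[str] = []
    rows: list[list[VariantAssociation]] = []
    n_palindromic = n_mismatch = 0
    for vid in common:
        anchor = ref[vid]
        if anchor.is_palindromic:
            if drop_palindromic:
                n_palindromic += 1
                continue
        row = [anchor]
        ok = True
        for d in by_id[1:]:
            a = d[vid]
            if (a.effect_allele, a.other_allele) == (anchor.effect_allele,
                                                     anchor.other_allele):
                row.append(a)
            elif (a.other_allele, a.effect_allele) == (anchor.effect_allele,
                                                       anchor.other_allele):
                row.append(a.flipped())
            else:
                ok = False
                break
        if not ok:
            n_mismatch += 1
            continue
        kept_ids.append(vid)
        rows.append(row)

    if n_palindromic:
        log.info("harmonize: excluded %d palindromic variants", n_palindromic)
    if n_mismatch:
        log.info("harmonize: dropped %d variants with mismatched alleles",
                 n_mismatch)
    if not kept_ids:
        raise ValidationError("no variants survived harmonization")

    k = len(exposures)
    j = len(kept_ids)
    exp_b = np.empty((j, k))
    exp_s = np.empty((j, k))
    out_b = np.empty(j)
    out_s = np.empty(j)
    flags = np.empty(j, dtype=bool)
    for i, row in enumerate(rows):
        for c in range(k):
            exp_b[i, c] = row[c].beta
            exp_s[i, c] = row[c].se
        out_b[i] = row[k].beta
        out_s[i] = row[k].se
        flags[i] = row[0].is_palindromic

    return HarmonizedSet(
        variant_ids=tuple(kept_ids),
        exposure_betas=exp_b, exposure_ses=exp_s,
        outcome_betas=out_b, outcome_ses=out_s,
        trait_names=tuple(exposures.keys()),
        palindromic_flags=flags,
        effect_alleles=tuple(rows[i][0].effect_allele for i in range(j)),
        other_alleles=tuple(rows[i][0].other_allele for i in range(j)),
        outcome_name=outcome_name,
    )


def rescale_to_sd(hset: HarmonizedSet,
                  sd_per_trait: Sequence[float]) -> HarmonizedSet:
    """Convert per-unit exposure associations to per-SD associations.

    Multiplies each exposure's betas and SEs by the trait's phenotypic SD
    (e.g. 18.68 mmHg for systolic blood pressure), so downstream causal
    estimates are per one SD increase in the exposure.  The outcome (log-OR
    scale) is untouched.
    """
    sds = np.asarray(sd_per_trait, dtype=float)
    if sds.shape != (hset.n_exposures,):
        raise ValidationError(
            f"expected {hset.n_exposures} SD constants, got {sds.shape}")
    if not (sds > 0).all():
        raise ValidationError("SD constants must be positive")
    return replace(hset,
                   exposure_betas=hset.exposure_betas * sds,
                   exposure_ses=hset.exposure_ses * sds)
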