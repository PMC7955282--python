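import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrmed import HarmonizedSet, LDInfo, VariantAssociation

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_hset(bx, by, sy, sx=None, trait="exposure"):
    """HarmonizedSet from raw arrays (single exposure)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 1e-6) if sx is None else np.asarray(sx, dtype=float)
    j = len(bx)
    return HarmonizedSet(
        variant_ids=tuple(f"rs{i + 1}" for i in range(j)),
        exposure_betas=bx[:, None], exposure_ses=sx[:, None],
        outcome_betas=by, outcome_ses=sy,
        trait_names=(trait,), palindromic_flags=np.zeros(j, dtype=bool),
        effect_alleles=("A",) * j, other_alleles=("G",) * j)


def make_assoc(vid="rs1", ea="A", oa="G", beta=0.1, se=0.01, **kw):
    return VariantAssociation(vid, ea, oa, beta=beta, se=se, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
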