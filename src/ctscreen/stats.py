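"""Empirical-Bayes moderated two-group t-test with BH FDR control.

The differential-expression filter of the screening protocol is a moderated
t-statistic: the per-probeset sample variance s_g^2 (residual df d_g) is
shrunk toward a prior variance s0^2 with d0 prior degrees of freedom,

    s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g),

and the t statistic t = (mean_a - mean_b) / sqrt(s~_g^2 (1/n_a + 1/n_b)) is
referred to a Student t distribution with d0 + d_g degrees of freedom
(standard normal when d0 is infinite). The prior (d0, s0^2) is fitted across
probesets by matching the mean and variance of log s_g^2 to those of a
scaled inverse-chi-square distribution, using digamma/trigamma corrections
(the classical method-of-moments fit on the log scale). Two-sided p-values
are adjusted with the Benjamini–Hochberg step-up procedure, one family per
contrast.

Groups with fewer than two samples in total residual df (the protocol has
tissue groups with n = 2 and enriched germ-cell groups even smaller) fall
back to a prior-variance-only contrast (d_g = 0, t with d0 df), flagged in
the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ContractError, CTScreenError, InsufficientDataError

#: floor applied to sample variances before taking logs in the prior fit
VARIANCE_FLOOR = 1e-8

#: minimum number of usable per-probeset variances for the prior fit
MIN_PRIOR_PROBESETS = 10

METHOD_MODERATED = "moderated"
METHOD_PRIOR_ONLY = "prior_only"


@dataclass(frozen=True)
class PriorEstimate:
    """Hyperparameters of the inverse-chi-square variance prior.

    d0 may be ``numpy.inf`` (complete shrinkage: no excess spread of the
    observed log-variances beyond sampling noise).
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise CTScreenError(f"prior d0 must be positive, got {self.d0}")
        if not (self.s0_sq > 0):
            raise CTScreenError(f"prior s0_sq must be positive, got {self.s0_sq}")


@dataclass
class ContrastResult:
    """Per-probeset statistics of one two-group contrast.

    ``table`` columns: log2fc (mean difference, group A minus group B),
    s2 (sample variance), s2_post (posterior variance), t, p, q,
    method_flag. ``df_residual`` is the common residual df d_g of the
    contrast; ``df_total`` the df of the reference t distribution.
    """

    table: pd.DataFrame
    prior: PriorEstimate
    df_residual: float
    df_total: float

    @property
    def q(self) -> pd.Series:
        return self.table["q"]

    def to_tsv(self, path) -> None:
        out = self.table[["log2fc", "t", "p", "q", "method_flag"]]
        out.rename_axis("probeset_id").to_csv(path, sep="\t", float_format="%.6g")


def benjamini_hochberg(p) -> np.ndarray:
    """BH step-up adjusted p-values (q-values), in the original order.

    q_(i) = min_{j>=i} ( p_(j) * n / j ), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise CTScreenError("p must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise CTScreenError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise CTScreenError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s_g_sq, d_g) -> PriorEstimate:
    """Method-of-moments fit of the variance prior on the log scale.

    With z_g = log s_g^2, E[z_g] = log s0^2 + digamma(d_g/2) - log(d_g/2)
    + digamma-type offsets of the prior; matching mean and (trigamma-
    corrected) variance of z_g yields d0 and s0^2. When the empirical
    spread of the log-variances is at or below its pure-sampling
    expectation, d0 is +inf and s0^2 is the (bias-corrected) geometric
    mean of the variances.
    """
    s2 = np.asarray(s_g_sq, dtype=float)
    df = np.broadcast_to(np.asarray(d_g, dtype=float), s2.shape).copy()
    if np.any(s2 < 0):
        raise CTScreenError("sample variances must be nonnegative")
    use = df >= 1
    if use.sum() < MIN_PRIOR_PROBESETS:
        raise InsufficientDataError(
            f"need >= {MIN_PRIOR_PROBESETS} probesets with residual df >= 1, "
            f"got {int(use.sum())}"
        )
    s2 = np.maximum(s2[use], VARIANCE_FLOOR)
    df = df[use]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1) - np.mean(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return PriorEstimate(d0=np.inf, s0_sq=float(np.exp(emean)))
    d0 = 2.0 * trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return PriorEstimate(d0=float(d0), s0_sq=s0_sq)


def _as_2d(x, name):
    a = np.asarray(x, dtype=float)
    if a.ndim != 2:
        raise ContractError(f"{name} must be a 2-D array (probesets x samples)")
    return a


def moderated_t(group_a, group_b, prior: PriorEstimate | None = None, *, d0=None, s0_sq=None,
                index=None) -> ContrastResult:
    """Moderated two-sample t-test, one row per probeset.

    ``group_a``/``group_b`` are 2-D arrays (probesets x samples); both
    groups need at least 2 samples. ``prior`` may instead be given as the
    raw ``d0``/``s0_sq`` pair; ``d0 = 0`` reproduces the classical pooled
    two-sample t-test exactly (no shrinkage).
    """
    a = _as_2d(group_a, "group_a")
    b = _as_2d(group_b, "group_b")
    if a.shape[0] != b.shape[0]:
        raise ContractError("groups must cover the same probesets")
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ContractError(
            f"each group needs >= 2 samples (got {na} and {nb}); "
            "use prior_only_contrast for minimally replicated groups"
        )
    if prior is None:
        if d0 is None or s0_sq is None:
            raise ContractError("pass a PriorEstimate or explicit d0 and s0_sq")
    else:
        d0, s0_sq = prior.d0, prior.s0_sq
    d_g = na + nb - 2
    diff = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d_g
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    q = benjamini_hochberg(p)
    if prior is None:
        prior = PriorEstimate(d0=max(d0, np.finfo(float).tiny), s0_sq=s0_sq)
    table = pd.DataFrame(
        {
            "log2fc": diff,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "q": q,
            "method_flag": METHOD_MODERATED,
        },
        index=pd.Index(index, name="probeset_id") if index is not None else None,
    )
    return ContrastResult(table=table, prior=prior, df_residual=float(d_g),
                          df_total=float(df_total))


def prior_only_contrast(group_a, group_b, prior: PriorEstimate, *, index=None) -> ContrastResult:
    """Fallback contrast for minimally replicated groups (either n < 2).

    No per-probeset variance can be estimated (d_g = 0): the t statistic
    uses the prior variance alone and d0 degrees of freedom. Flagged
    ``prior_only`` in the output.
    """
    a = _as_2d(group_a, "group_a")
    b = _as_2d(group_b, "group_b")
    if a.shape[0] != b.shape[0]:
        raise ContractError("groups must cover the same probesets")
    na, nb = a.shape[1], b.shape[1]
    if na < 1 or nb < 1:
        raise ContractError("each group needs at least one sample")
    diff = a.mean(axis=1) - b.mean(axis=1)
    se = np.sqrt(prior.s0_sq * (1.0 / na + 1.0 / nb))
    t = diff / se
    if np.isinf(prior.d0):
        p = 2.0 * sps.norm.sf(np.abs(t))
        df_total = np.inf
    else:
        p = 2.0 * sps.t.sf(np.abs(t), prior.d0)
        df_total = prior.d0
    q = benjamini_hochberg(p)
    table = pd.DataFrame(
        {
            "log2fc": diff,
            "s2": np.zeros_like(diff),
            "s2_post": np.full_like(diff, prior.s0_sq),
            "t": t,
            "p": p,
            "q": q,
            "method_flag": METHOD_PRIOR_ONLY,
        },
        index=pd.Index(index, name="probeset_id") if index is not None else None,
    )
    return ContrastResult(table=table, prior=prior, df_residual=0.0, df_total=float(df_total))


def two_group_contrast(group_a, group_b, prior: PriorEstimate | None = None, *,
                       index=None) -> ContrastResult:
    """Contrast group A against group B, estimating the prior if not given.

    Dispatches to :func:`moderated_t` when both groups have >= 2 samples and
    to :func:`prior_only_contrast` otherwise (in which case an explicit
    prior is required).
    """
    a = _as_2d(group_a, "group_a")
    b = _as_2d(group_b, "group_b")
    na, nb = a.shape[1], b.shape[1]
    if na >= 2 and nb >= 2:
        if prior is None:
            d_g = na + nb - 2
            ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
                (b - b.mean(axis=1, keepdims=True)) ** 2
            ).sum(axis=1)
            prior = estimate_variance_prior(ss / d_g, d_g)
        return moderated_t(a, b, prior, index=index)
    if prior is None:
        raise ContractError(
            "a group has < 2 samples: the fallback contrast needs an explicit prior"
        )
    return prior_only_contrast(a, b, prior, index=index)
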