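"""Differential-abundance statistics for intensity matrices.

The processing chain mirrors standard label-free proteomics practice:
features observed in too few samples are dropped, samples are quantile
normalized, intensities are log2 transformed, remaining missing cells are
filled with the global observed minimum (a left-censoring convention for
intensity-dependent missingness), and group differences are tested.

Two tests are provided.  ``fold_change_screen`` is the plain
geometric-mean-ratio screen used for plasma miRNA (no p-value gate).
``moderated_de`` is an empirical-Bayes moderated two-sample t in the limma
tradition: per-feature residual variances s_g^2 on d degrees of freedom are
shrunk toward a scaled inverse-chi-square prior (d0, s0^2) fitted to the
variance ensemble by moment matching on log variances, giving

    s_tilde_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

and a t statistic on d0 + d degrees of freedom.  With d0 = 0 this reduces
exactly to the classical pooled t; with d0 = +inf every variance is replaced
by s0^2 and the reference distribution is normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, SeptimarkError, ValidationError
from .matrix import AbundanceMatrix

DE_COLUMNS = ("feature", "log2fc", "fold_change", "t_mod", "p", "p_adj",
              "df_total", "called", "direction")


# ---------------------------------------------------------------------------
# matrix processing
# ---------------------------------------------------------------------------

def missingness_filter(m: AbundanceMatrix, min_nonnull_frac: float = 0.25) -> AbundanceMatrix:
    """Keep features with at least ``min_nonnull_frac`` observed values.

    The bound is inclusive ("at least"): a feature observed in exactly 25% of
    samples survives the default filter.  Feature order is preserved.
    """
    if not 0 < min_nonnull_frac <= 1:
        raise ConfigError(f"min_nonnull_frac must lie in (0, 1], got {min_nonnull_frac}")
    if m.state != "raw":
        raise ValidationError(f"missingness_filter expects a raw matrix, state is {m.state!r}")
    frac = m.values.notna().mean(axis=1)
    return m.with_values(m.values.loc[frac >= min_nonnull_frac], state="raw")


def quantile_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Force every sample onto one shared empirical intensity distribution.

    On complete data this is the textbook algorithm: each sample's sorted
    values are replaced by the across-sample means of sorted values, so
    afterwards all samples share the same sorted vector and the operation is
    idempotent.  With missing values, each sample's observed values are
    ranked, the reference distribution is the across-sample mean of
    per-sample quantile curves on a common grid, and observed values map to
    the reference by linear interpolation of their quantile position; missing
    cells stay missing.  Tied observations receive the mean of their tied
    reference slots.
    """
    if m.state != "raw":
        raise ValidationError(f"quantile_normalize expects a raw matrix, state is {m.state!r}")
    X = m.values.to_numpy(dtype=float)
    n_feat, n_samp = X.shape
    n_obs = np.sum(~np.isnan(X), axis=0)
    for j, n in enumerate(n_obs):
        if n == 0:
            raise ValidationError(f"sample {m.samples[j]!r} has no observed values")
    n_ref = int(n_obs.max())
    if n_ref == 1:
        # degenerate: one observation per sample; reference is the mean
        ref = np.array([np.nanmean(X)])
        probs = np.array([0.0])
    else:
        probs = np.linspace(0.0, 1.0, n_ref)
        curves = np.empty((n_ref, n_samp))
        for j in range(n_samp):
            obs = np.sort(X[~np.isnan(X[:, j]), j])
            curves[:, j] = np.quantile(obs, probs)
        ref = curves.mean(axis=1)

    out = np.full_like(X, np.nan)
    for j in range(n_samp):
        col = X[:, j]
        idx = np.flatnonzero(~np.isnan(col))
        obs = col[idx]
        k = obs.size
        order = np.argsort(obs, kind="mergesort")
        pos = probs if k == n_ref else (
            np.linspace(0.0, 1.0, k) if k > 1 else np.array([0.5])
        )
        targets = np.interp(pos, probs, ref)
        # average targets over runs of tied observations
        sorted_obs = obs[order]
        new_sorted = targets.copy()
        start = 0
        for i in range(1, k + 1):
            if i == k or sorted_obs[i] != sorted_obs[start]:
                if i - start > 1:
                    new_sorted[start:i] = targets[start:i].mean()
                start = i
        normalized = np.empty(k)
        normalized[order] = new_sorted
        out[idx, j] = normalized
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.with_values(values, state="normalized")


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """log2-transform observed values, preserving the missingness mask.

    Used where a downstream computation wants observed-only statistics
    (e.g. trend-step means), for which constant-minimum imputation would be
    a large distortion under intensity-dependent missingness.
    """
    if m.state != "normalized":
        raise ValidationError(f"log2_transform expects a normalized matrix, state is {m.state!r}")
    X = m.values.to_numpy(dtype=float)
    observed = ~np.isnan(X)
    if (X[observed] <= 0).any():
        raise ValidationError("log2 transform undefined: matrix contains non-positive observed values")
    L = np.where(observed, np.log2(X, where=observed, out=np.full_like(X, np.nan)), np.nan)
    values = pd.DataFrame(L, index=m.values.index, columns=m.values.columns)
    return m.with_values(values, state="log2")


def log2_min_impute(m: AbundanceMatrix) -> AbundanceMatrix:
    """log2-transform observed values and fill missing cells with the global minimum.

    The fill value is the minimum over *all* observed log2 values of the
    matrix, not a per-feature minimum: features unobserved in an entire group
    would have no per-feature minimum there, and globally-minimal filling
    encodes the assumption that missingness is concentrated at low intensity.

    Accepts a ``normalized`` matrix (log2 + fill) or an already ``log2``
    matrix (fill only).
    """
    if m.state not in ("normalized", "log2"):
        raise ValidationError(f"log2_min_impute expects a normalized matrix, state is {m.state!r}")
    if m.state == "normalized":
        m = log2_transform(m)
    L = m.values.to_numpy(dtype=float)
    observed = ~np.isnan(L)
    if not observed.any():
        raise ValidationError("matrix has no observed values")
    gmin = np.nanmin(L)
    L = np.where(observed, L, gmin)
    values = pd.DataFrame(L, index=m.values.index, columns=m.values.columns)
    return m.with_values(values, state="imputed")


def process(m: AbundanceMatrix, min_nonnull_frac: float = 0.25) -> AbundanceMatrix:
    """Full chain: missingness filter -> quantile normalize -> log2 + impute."""
    return log2_min_impute(quantile_normalize(missingness_filter(m, min_nonnull_frac)))


# ---------------------------------------------------------------------------
# group handling
# ---------------------------------------------------------------------------

def _group_arrays(m: AbundanceMatrix, group_a: Sequence[str], group_b: Sequence[str],
                  min_size: int = 2) -> tuple[np.ndarray, np.ndarray]:
    if m.state != "imputed":
        raise ValidationError(
            f"differential testing requires an imputed matrix, state is {m.state!r}")
    for name, grp in (("group_a", group_a), ("group_b", group_b)):
        absent = [s for s in grp if s not in m.values.columns]
        if absent:
            raise ValidationError(f"{name} samples not in matrix: {absent}")
        if len(grp) < min_size:
            raise SeptimarkError(f"{name} needs at least {min_size} samples, got {len(grp)}")
    if set(group_a) & set(group_b):
        raise ValidationError("groups overlap")
    A = m.values.loc[:, list(group_a)].to_numpy(dtype=float)
    B = m.values.loc[:, list(group_b)].to_numpy(dtype=float)
    return A, B


# ---------------------------------------------------------------------------
# fold-change screen (miRNA)
# ---------------------------------------------------------------------------

def fold_change_screen(m: AbundanceMatrix, group_a: Sequence[str], group_b: Sequence[str],
                       fc_threshold: float = 2.0) -> pd.DataFrame:
    """Call features by geometric-mean fold change alone (|fold change| > threshold).

    ``fold_change = 2 ** (mean log2 A - mean log2 B)``; a feature is called
    when the fold change exceeds the threshold or falls below its reciprocal
    (strict).  No p-value enters this screen.
    """
    if not fc_threshold > 1:
        raise ConfigError(f"fc_threshold must exceed 1, got {fc_threshold}")
    A, B = _group_arrays(m, group_a, group_b)
    lfc = A.mean(axis=1) - B.mean(axis=1)
    fc = np.exp2(lfc)
    called = (fc > fc_threshold) | (fc < 1.0 / fc_threshold)
    return pd.DataFrame({
        "feature": m.features,
        "log2fc": lfc,
        "fold_change": fc,
        "t_mod": np.nan,
        "p": np.nan,
        "p_adj": np.nan,
        "df_total": np.nan,
        "called": called,
        "direction": np.where(lfc >= 0, "up", "down"),
    })


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EbPrior:
    """Scaled inverse-chi-square prior on residual variances.

    ``d0`` is the prior degrees of freedom (0 disables moderation, +inf
    replaces every variance by ``s0_sq``); ``s0_sq`` is the prior variance on
    the squared log2 scale.
    """

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 >= 0):
            raise ConfigError(f"prior df must be >= 0, got {self.d0}")
        if not (self.s0_sq >= 0):
            raise ConfigError(f"prior variance must be >= 0, got {self.s0_sq}")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def estimate_eb_prior(residual_variances, residual_dfs) -> EbPrior:
    """Fit (d0, s0^2) by moment matching on log variances.

    Under the model s_g^2 ~ s0^2 * F(d, d0), the centered log variance
    e_g = log s_g^2 - digamma(d/2) + log(d/2) has mean
    log s0^2 - digamma(d0/2) + log(d0/2) and variance
    trigamma(d/2) + trigamma(d0/2).  The excess of the observed variance of
    e over trigamma(d/2) identifies d0 through the trigamma inverse; no
    excess (the ensemble is no more spread than sampling alone implies)
    gives d0 = +inf.  Exactly equal variances short-circuit to
    (+inf, common variance).
    """
    var = np.asarray(residual_variances, dtype=float)
    df = np.broadcast_to(np.asarray(residual_dfs, dtype=float), var.shape)
    if var.size and np.ptp(var) == 0:
        return EbPrior(d0=np.inf, s0_sq=float(var.flat[0]))
    ok = (var > 0) & (df > 0)
    if ok.sum() < 10:
        raise SeptimarkError(
            f"prior estimation needs at least 10 features with positive variance, got {int(ok.sum())}")
    var, df = var[ok], df[ok]
    e = np.log(var) - special.digamma(df / 2.0) + np.log(df / 2.0)
    excess = np.var(e, ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(np.mean(e))
    return EbPrior(d0=float(d0), s0_sq=float(s0_sq))


def moderated_de(
    m: AbundanceMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_threshold: float = 1.2,
    p_threshold: float = 0.05,
    prior: EbPrior | None = None,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Moderated two-group differential test on log2 intensities.

    Per feature the two-group linear model yields log2fc = mean(A) - mean(B)
    and a pooled residual variance s^2 on d = nA + nB - 2 df.  Variances are
    shrunk toward the (estimated or supplied) prior and the moderated t is
    referred to a t distribution on d0 + d df (standard normal when
    d0 = +inf).  A feature is called when its fold change clears the
    threshold in either direction *and* its (raw by default, BH-adjusted if
    ``use_adjusted``) p-value is below ``p_threshold``.
    """
    if not fc_threshold > 1:
        raise ConfigError(f"fc_threshold must exceed 1, got {fc_threshold}")
    if not 0 < p_threshold < 1:
        raise ConfigError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    A, B = _group_arrays(m, group_a, group_b)
    nA, nB = A.shape[1], B.shape[1]
    d = nA + nB - 2
    if d < 1:
        raise SeptimarkError("zero residual degrees of freedom: need nA + nB > 2")
    lfc = A.mean(axis=1) - B.mean(axis=1)
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((B - B.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / d
    if prior is None:
        prior = estimate_eb_prior(s2, d)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
        df_total = prior.d0 + d
    se = np.sqrt(s2_post * (1.0 / nA + 1.0 / nB))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(lfc == 0, 0.0, lfc / se)
    t = np.where(np.isnan(t), 0.0, t)  # lfc != 0 with se == 0 -> +-inf stays
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, 0.0, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    fc = np.exp2(lfc)
    gate_p = p_adj if use_adjusted else p
    called = ((fc > fc_threshold) | (fc < 1.0 / fc_threshold)) & (gate_p < p_threshold)
    return pd.DataFrame({
        "feature": m.features,
        "log2fc": lfc,
        "fold_change": fc,
        "t_mod": t,
        "p": p,
        "p_adj": p_adj,
        "df_total": df_total,
        "called": called,
        "direction": np.where(lfc >= 0, "up", "down"),
    })


# ---------------------------------------------------------------------------
# PCA and set intersections
# ---------------------------------------------------------------------------

def pca_scores(m: AbundanceMatrix, n_components: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores and variance fractions from a feature-centered SVD.

    Returns a (samples x components) score frame and the fractions of total
    variance carried by the requested components; fractions are
    non-increasing and over all components sum to 1.
    """
    if n_components < 1:
        raise ConfigError(f"n_components must be >= 1, got {n_components}")
    if m.state != "imputed":
        raise ValidationError(f"PCA requires an imputed matrix, state is {m.state!r}")
    X = m.values.to_numpy(dtype=float).T  # samples x features
    n_samp, n_feat = X.shape
    max_k = min(n_feat, n_samp - 1)
    if n_components > max_k:
        raise ConfigError(
            f"n_components {n_components} exceeds min(features, samples - 1) = {max_k}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float((S ** 2).sum())
    if total == 0:
        raise SeptimarkError("matrix has zero total variance; PCA undefined")
    scores = U[:, :n_components] * S[:n_components]
    frame = pd.DataFrame(scores, index=m.samples,
                         columns=[f"PC{i + 1}" for i in range(n_components)])
    frame.index.name = "sample_id"
    return frame, (S[:n_components] ** 2) / total


@dataclass(frozen=True)
class CommonFeatures:
    """Exact intersection plus all Venn-region cardinalities."""

    intersection: frozenset[str]
    regions: Mapping[str, int]  # "&"-joined sorted member keys -> exclusive count


def common_features(called_sets: Mapping[str, set]) -> CommonFeatures:
    """Features called in every set, with exclusive Venn-region counts."""
    if len(called_sets) < 2:
        raise ConfigError("common_features requires at least 2 sets")
    keys = sorted(called_sets)
    sets = {k: frozenset(called_sets[k]) for k in keys}
    universe = frozenset().union(*sets.values())
    regions: dict[str, int] = {}
    for feat in universe:
        members = tuple(k for k in keys if feat in sets[k])
        label = "&".join(members)
        regions[label] = regions.get(label, 0) + 1
    inter = frozenset.intersection(*sets.values())
    return CommonFeatures(intersection=inter, regions=regions)
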