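"""Moderated differential testing of 5mC/5hmC and region calling.

Per-probe two-group ordinary least squares gives a difference of group
means, a pooled residual variance s2 and residual degrees of freedom df.
Information is then shared across probes with the standard moderated-t
construction: the s2 ensemble is modelled as scaled F around a prior
(d0, s0^2) estimated by moment matching on log s2 (trigamma inversion),
the posterior variance is s2_post = (d0*s0^2 + df*s2) / (d0 + df), and
t_mod = estimate / (sqrt(s2_post) * stdev_unscaled) is referred to a t
distribution with d0 + df degrees of freedom.

Regions are transparent proximity clusters of significant CpGs (successive
gaps <= maxgap, at least min_cpgs members) scored with a Stouffer
combination of the member z-scores.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ValidationError

FIT_COLUMNS = ["estimate", "s2", "df", "stdev_unscaled", "testable"]


# ---------------------------------------------------------------------------
# per-probe fits
# ---------------------------------------------------------------------------

def fit_group_model(values: pd.DataFrame, design: pd.Series, contrast: tuple) -> pd.DataFrame:
    """Two-group OLS per probe with per-probe NA handling.

    ``values`` is probes x samples; ``design`` maps sample id -> condition;
    ``contrast`` is (target, reference). The estimate is
    mean(target) - mean(reference); s2 pools the within-group residual
    variance with df = n_target + n_reference - 2 after NA removal.
    Probes with fewer than 2 defined samples in either group are flagged
    untestable (they are excluded from moderation and BH downstream).
    """
    target, reference = contrast
    design = design.reindex(values.columns)
    for cond in contrast:
        if cond not in set(design.dropna()):
            raise ValidationError(f"contrast condition {cond!r} not present in design")
    a = values.loc[:, design[design == target].index]
    b = values.loc[:, design[design == reference].index]
    n1, n2 = a.notna().sum(axis=1), b.notna().sum(axis=1)
    mean1, mean2 = a.mean(axis=1), b.mean(axis=1)
    ss1 = ((a.sub(mean1, axis=0)) ** 2).sum(axis=1)
    ss2 = ((b.sub(mean2, axis=0)) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    testable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = (ss1 + ss2) / df
        stdev_unscaled = np.sqrt(1.0 / n1 + 1.0 / n2)
    out = pd.DataFrame({
        "estimate": mean1 - mean2,
        "s2": s2,
        "df": df.astype(float),
        "stdev_unscaled": stdev_unscaled,
        "testable": testable,
        "n_target": n1,
        "n_reference": n2,
    }, index=values.index)
    return out


def fit_one_sample(values: pd.DataFrame) -> pd.DataFrame:
    """One-group fit per probe: mean, variance, df = n - 1."""
    n = values.notna().sum(axis=1)
    mean = values.mean(axis=1)
    s2 = values.var(axis=1, ddof=1)
    return pd.DataFrame({
        "estimate": mean,
        "s2": s2,
        "df": (n - 1).astype(float),
        "stdev_unscaled": 1.0 / np.sqrt(n),
        "testable": n >= 2,
    }, index=values.index)


# ---------------------------------------------------------------------------
# empirical Bayes moderation
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Works on log s2: e = log(s2) - digamma(df/2) + log(df/2) is unbiased
    for log(s0^2) when d0 is infinite; the excess spread of e over its
    chi-square sampling floor identifies d0 via trigamma inversion. When
    the observed spread is at or below the floor the prior degrees of
    freedom are infinite (complete shrinkage). d0 above 1e6 is treated as
    infinite.
    """
    ok = (df > 0) & (s2 > 0) & np.isfinite(s2)
    if not ok.any():
        raise ValidationError(
            "all residual variances are zero; moderation is undefined "
            "(more replicates, or jitter degenerate values)"
        )
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * trigamma_inverse(evar)
    if d0 > 1e6:
        return np.inf, float(np.exp(emean))
    s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_2)


def moderate_ebayes(fits: pd.DataFrame, prior_df: float | None = None,
                    side: str = "two-sided") -> pd.DataFrame:
    """Moderated t and p per probe from per-probe fits.

    ``prior_df`` overrides the estimated d0: 0 recovers the classical
    two-sample t exactly; ``numpy.inf`` forces complete shrinkage to the
    common prior variance. ``side`` is "two-sided" or "greater" (the
    one-sided gain test used for 5hmC peaks).

    Requires >= 10 testable probes when the prior is estimated (the moment
    estimator needs an ensemble).
    """
    if side not in ("two-sided", "greater"):
        raise ValidationError(f"unknown side {side!r}")
    testable = fits["testable"].to_numpy(dtype=bool)
    s2 = fits["s2"].to_numpy(dtype=float)
    df = fits["df"].to_numpy(dtype=float)
    if prior_df is None:
        if testable.sum() < 10:
            raise ValidationError("moment estimation of the prior needs >= 10 testable probes")
        d0, s0_2 = estimate_prior(s2[testable], df[testable])
    elif prior_df == 0:
        d0, s0_2 = 0.0, np.nan
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_prior(s2[testable], df[testable])
    with np.errstate(invalid="ignore", divide="ignore"):
        if d0 == 0:
            s2_post = s2
            df_total = df
        elif np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
            df_total = np.full_like(df, np.inf)
        else:
            s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
            df_total = df + d0
        t_mod = fits["estimate"].to_numpy(dtype=float) / (
            np.sqrt(s2_post) * fits["stdev_unscaled"].to_numpy(dtype=float))
    p = _t_pvalue(t_mod, df_total, side)
    out = pd.DataFrame({
        "estimate": fits["estimate"],
        "t_mod": t_mod,
        "p": p,
        "s2_post": s2_post,
        "df_total": df_total,
    }, index=fits.index)
    out.loc[~fits["testable"], ["t_mod", "p"]] = np.nan
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    return out


def _t_pvalue(t: np.ndarray, df_total: np.ndarray, side: str) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    df_total = np.asarray(df_total, dtype=float)
    p = np.full_like(t, np.nan)
    finite_df = np.isfinite(df_total) & (df_total > 0)
    with np.errstate(invalid="ignore"):
        if side == "two-sided":
            p[finite_df] = 2.0 * stats.t.sf(np.abs(t[finite_df]), df_total[finite_df])
            p[~finite_df] = 2.0 * stats.norm.sf(np.abs(t[~finite_df]))
        else:
            p[finite_df] = stats.t.sf(t[finite_df], df_total[finite_df])
            p[~finite_df] = stats.norm.sf(t[~finite_df])
    return np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# multiple testing & calls
# ---------------------------------------------------------------------------

def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-stable)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must be in [0, 1] and non-missing")
    return multipletests(p, method="fdr_bh")[1]


def differential_positions(values: pd.DataFrame, design: pd.Series, contrast: tuple,
                           delta_min: float = 0.20, alpha: float = 0.05) -> pd.DataFrame:
    """Full position-level pipeline: fit, moderate, BH, threshold calls.

    Returns the per-probe table (delta_beta, s2, df, t_mod, p, fdr,
    significant, testable); untestable probes carry NaN statistics and are
    excluded from BH so they never dilute the FDR.
    """
    fits = fit_group_model(values, design, contrast)
    mod = moderate_ebayes(fits)
    out = pd.DataFrame({
        "delta_beta": fits["estimate"],
        "s2": fits["s2"],
        "df": fits["df"],
        "t_mod": mod["t_mod"],
        "p": mod["p"],
        "testable": fits["testable"],
    }, index=values.index)
    out["fdr"] = np.nan
    mask = fits["testable"].to_numpy()
    out.loc[mask, "fdr"] = adjust_bh(out.loc[mask, "p"].to_numpy())
    out["significant"] = call_positions_mask(out, delta_min=delta_min, alpha=alpha)
    out.attrs["d0"] = mod.attrs["d0"]
    out.attrs["s0_2"] = mod.attrs["s0_2"]
    return out


def call_positions_mask(diff: pd.DataFrame, delta_min: float, alpha: float = 0.05) -> pd.Series:
    """Boolean call per probe: fdr < alpha (strict) AND |delta| >= delta_min."""
    fdr = diff["fdr"]
    return (fdr < alpha) & (diff["delta_beta"].abs() >= delta_min) & fdr.notna()


def call_positions(diff: pd.DataFrame, delta_min: float = 0.20, alpha: float = 0.05) -> pd.DataFrame:
    """Significant subset of a position-level differential table."""
    return diff[call_positions_mask(diff, delta_min=delta_min, alpha=alpha)]


def stouffer_combine(z: np.ndarray) -> float:
    """Stouffer combination of z-scores: sum(z) / sqrt(k)."""
    z = np.asarray(z, dtype=float)
    return float(z.sum() / np.sqrt(len(z)))


def call_regions(positions: pd.DataFrame, maxgap: int = 1000, min_cpgs: int = 3) -> pd.DataFrame:
    """Proximity-cluster significant CpGs into regions.

    ``positions`` needs columns chrom, pos, p, delta_beta, significant and
    must be sorted by (chrom, pos). Consecutive significant CpGs whose
    successive gaps are <= ``maxgap`` form a cluster; clusters with at
    least ``min_cpgs`` members become regions spanning
    [first CpG, last CpG + 1). The region statistic is the Stouffer
    combination of the member signed z-scores (z_i from the two-sided
    member p with the sign of its delta), with a two-sided region p and BH
    across regions.
    """
    required = {"chrom", "pos", "p", "delta_beta", "significant"}
    missing = required - set(positions.columns)
    if missing:
        raise ValidationError(f"positions table missing columns: {sorted(missing)}")
    for chrom, grp in positions.groupby("chrom", sort=False):
        if np.any(np.diff(grp["pos"].to_numpy()) < 0):
            raise ValidationError(f"positions not sorted by pos on {chrom}")

    sig = positions[positions["significant"].astype(bool)]
    regions = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > maxgap)[0] + 1
        for cluster in np.split(np.arange(len(pos)), breaks):
            if len(cluster) < min_cpgs:
                continue
            members = grp.iloc[cluster]
            p_clip = np.clip(members["p"].to_numpy(dtype=float), 1e-300, 1.0)
            z = stats.norm.isf(p_clip / 2.0) * np.sign(members["delta_beta"].to_numpy())
            zc = stouffer_combine(z)
            regions.append({
                "chrom": chrom,
                "start": int(members["pos"].iloc[0]),
                "end": int(members["pos"].iloc[-1]) + 1,
                "n_cpgs": len(members),
                "probe_ids": list(members.index),
                "mean_delta": float(members["delta_beta"].mean()),
                "stouffer_z": zc,
                "p": float(2.0 * stats.norm.sf(abs(zc))),
            })
    out = pd.DataFrame(regions, columns=["chrom", "start", "end", "n_cpgs", "probe_ids",
                                         "mean_delta", "stouffer_z", "p"])
    out["fdr"] = adjust_bh(out["p"].to_numpy()) if len(out) else np.nan
    return out


# ---------------------------------------------------------------------------
# rank-based group comparison
# ---------------------------------------------------------------------------

def compare_groups_wilcoxon(values_a, values_b) -> tuple:
    """Two-sided Mann-Whitney U (rank-sum) comparison of two groups.

    Exact enumeration for n_a + n_b <= 12 without ties; normal
    approximation with tie correction otherwise. Degenerate input (every
    value identical across both groups) returns p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1")
        return float(a.size * b.size / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
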