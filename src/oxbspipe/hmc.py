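"""Per-CpG 5mC/5hmC estimation from paired BS/oxBS signals.

The measurement model at one CpG in one culture is

    x_bs ~ Binomial(n_bs, m + h)     (BS reads 5mC + 5hmC)
    x_ox ~ Binomial(n_ox, m)         (oxBS reads 5mC only)

with counts reconstructed from betas as x = round(beta * n) and the joint
log-likelihood maximized over the simplex m >= 0, h >= 0, m + h <= 1.
When the BS rate is at least the oxBS rate, the unconstrained optimum is
interior: m_hat = x_ox / n_ox and h_hat = x_bs / n_bs - x_ox / n_ox.
Otherwise the constrained optimum sits on the boundary h = 0, where the
two channels measure the same quantity and the MLE of m pools the counts:
m_hat = (x_bs + x_ox) / (n_bs + n_ox); h is reported as NA, following the
convention of setting any negative 5hmC estimate to missing.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import (
    AlignmentError,
    BetaMatrix,
    MethylomeEstimate,
    PairingError,
    ValidationError,
    pair_table,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# naive subtraction
# ---------------------------------------------------------------------------

def naive_delta(bs: BetaMatrix, oxbs: BetaMatrix, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-probe, per-culture BS - oxBS beta difference (negatives retained).

    Columns are pair ids ``condition:culture``; missing betas propagate.
    """
    if not bs.probe_ids.equals(oxbs.probe_ids):
        raise AlignmentError("BS and oxBS matrices must share the probe index")
    pairs = pair_table(sheet)
    missing_bs = set(pairs["bs_sample"]) - set(bs.sample_ids)
    missing_ox = set(pairs["oxbs_sample"]) - set(oxbs.sample_ids)
    if missing_bs or missing_ox:
        raise PairingError(f"samples in sheet but not in matrices: {missing_bs | missing_ox}")
    delta = pd.DataFrame(index=bs.probe_ids)
    for pid, row in pairs.iterrows():
        delta[pid] = bs.beta[row["bs_sample"]] - oxbs.beta[row["oxbs_sample"]]
    return delta


# ---------------------------------------------------------------------------
# binomial MLE
# ---------------------------------------------------------------------------

def oxbs_mle(beta_bs: float, n_bs: float, beta_ox: float, n_ox: float):
    """Closed-form constrained MLE of (m, h) at a single CpG in one culture.

    Returns ``(m_hat, h_hat)``; ``h_hat`` is NaN on the h = 0 boundary
    (BS rate below oxBS rate). See the module docstring for the model.
    """
    m, h, _ = _mle_arrays(np.asarray([[beta_bs]], float), np.asarray([[n_bs]], float),
                          np.asarray([[beta_ox]], float), np.asarray([[n_ox]], float))
    return float(m[0, 0]), float(h[0, 0])


def _mle_arrays(beta_bs, n_bs, beta_ox, n_ox):
    if np.any(n_bs < 1) or np.any(n_ox < 1):
        raise ValidationError("coverage must be >= 1")
    with np.errstate(invalid="ignore"):
        if np.any((beta_bs < 0) | (beta_bs > 1)) or np.any((beta_ox < 0) | (beta_ox > 1)):
            raise ValidationError("betas must be in [0, 1]")
    x_bs = np.round(beta_bs * n_bs)
    x_ox = np.round(beta_ox * n_ox)
    r_bs = x_bs / n_bs
    r_ox = x_ox / n_ox
    interior = r_bs >= r_ox  # ties resolve to the interior solution (h = 0 defined)
    m_hat = np.where(interior, r_ox, (x_bs + x_ox) / (n_bs + n_ox))
    h_hat = np.where(interior, r_bs - r_ox, np.nan)
    missing = np.isnan(beta_bs) | np.isnan(beta_ox)
    m_hat = np.where(missing, np.nan, m_hat)
    h_hat = np.where(missing, np.nan, h_hat)
    na_mask = np.isnan(h_hat)
    return m_hat, h_hat, na_mask


def estimate_methylome(bs: BetaMatrix, oxbs: BetaMatrix, sheet: pd.DataFrame) -> MethylomeEstimate:
    """Apply the binomial MLE at every probe x culture of a paired dataset."""
    if not bs.probe_ids.equals(oxbs.probe_ids):
        raise AlignmentError("BS and oxBS matrices must share the probe index")
    pairs = pair_table(sheet)
    m_cols, h_cols = {}, {}
    for pid, row in pairs.iterrows():
        m, h, _ = _mle_arrays(
            bs.beta[row["bs_sample"]].to_numpy()[:, None],
            bs.coverage[row["bs_sample"]].to_numpy()[:, None],
            oxbs.beta[row["oxbs_sample"]].to_numpy()[:, None],
            oxbs.coverage[row["oxbs_sample"]].to_numpy()[:, None],
        )
        m_cols[pid], h_cols[pid] = m[:, 0], h[:, 0]
    m_hat = pd.DataFrame(m_cols, index=bs.probe_ids)
    h_hat = pd.DataFrame(h_cols, index=bs.probe_ids)
    na_mask = h_hat.isna()
    est = MethylomeEstimate(m_hat=m_hat, h_hat=h_hat, na_mask=na_mask,
                            probes=bs.probes.copy(), pairs=pairs)
    for pid, frac in est.na_fraction_per_pair.items():
        logger.info("estimate_methylome: pair %s has %.1f%% NA 5hmC cells", pid, 100 * frac)
    return est


# ---------------------------------------------------------------------------
# global 5hmC
# ---------------------------------------------------------------------------

def global_hmc_loss(bs: BetaMatrix, oxbs: BetaMatrix, sheet: pd.DataFrame,
                    scope=None) -> pd.Series:
    """Global 5hmC per condition as the signal loss after oxidation.

    loss = 1 - mean(oxBS beta) / mean(BS beta) over the scoped probes and
    the condition's samples. With two BS technical replicates supplied as
    the two channels (both ``channel == "BS"`` semantics handled by the
    caller pairing them as bs/oxbs), the same formula yields the
    technical-replicate noise floor analogue.
    """
    if scope is None:
        scope = bs.probe_ids
    scope = pd.Index(scope)
    if len(scope) == 0:
        raise ValidationError("scope must be non-empty")
    out = {}
    for cond, grp in sheet.groupby("condition", sort=False):
        bs_samples = grp.loc[grp["channel"] == "BS", "sample_id"]
        ox_samples = grp.loc[grp["channel"] == "oxBS", "sample_id"]
        mean_bs = bs.beta.loc[scope, bs_samples].to_numpy().mean()
        mean_ox = oxbs.beta.loc[scope, ox_samples].to_numpy().mean()
        if mean_bs == 0:
            raise ValidationError(f"mean BS signal is 0 in condition {cond!r}; loss undefined")
        out[cond] = 1.0 - mean_ox / mean_bs
    return pd.Series(out, name="global_hmc_loss")


# ---------------------------------------------------------------------------
# 5hmC presence peaks
# ---------------------------------------------------------------------------

def call_hmc_peaks(delta: pd.DataFrame, sheet: pd.DataFrame,
                   min_delta: float = 0.10, alpha: float = 0.05) -> pd.DataFrame:
    """Call per-condition 5hmC peaks from the paired BS - oxBS delta matrix.

    A peak is a CpG whose mean paired delta across the condition's cultures
    is significantly positive (one-sided moderated t, BH across probes)
    AND at least ``min_delta`` (default 10%, the sensitivity floor of the
    paired-conversion technique). ``alpha >= 1`` disables the FDR clause so
    that with ``min_delta=0`` every positive-delta probe is returned.

    Returns a tidy DataFrame: probe_id, condition, mean_delta, p, fdr, is_peak.
    """
    from .differential import adjust_bh, fit_one_sample, moderate_ebayes

    pairs = pair_table(sheet)
    frames = []
    for cond, grp in pairs.groupby("condition", sort=False):
        cols = grp.index
        if len(cols) < 2:
            raise ValidationError(f"condition {cond!r} has a single culture; no variance estimate")
        fits = fit_one_sample(delta[cols])
        mod = moderate_ebayes(fits, side="greater")
        fdr = pd.Series(np.nan, index=mod.index)
        testable = fits["testable"]
        fdr[testable] = adjust_bh(mod.loc[testable, "p"].to_numpy())
        mean_delta = fits["estimate"]
        is_peak = (
            testable
            & (mean_delta > 0)
            & (mean_delta >= min_delta)
            & ((fdr < alpha) | (alpha >= 1))
        )
        frames.append(pd.DataFrame({
            "probe_id": delta.index,
            "condition": cond,
            "mean_delta": mean_delta.to_numpy(),
            "p": mod["p"].to_numpy(),
            "fdr": fdr.to_numpy(),
            "is_peak": is_peak.to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)
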