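"""Probe quality filtering and optional within-channel normalization."""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AlignmentError, BetaMatrix, ValidationError


def filter_probes(
    bs: BetaMatrix,
    oxbs: BetaMatrix,
    detp_threshold: float = 0.01,
    sample_frac: float = 0.10,
):
    """Remove low-quality probes from both channels jointly.

    A probe is dropped from BOTH matrices iff, pooling all BS and oxBS
    samples, the number of samples with detection p > ``detp_threshold``
    STRICTLY exceeds ``sample_frac`` of the pooled sample count (a probe
    failing in exactly 10% of samples is kept). BS and oxBS are filtered
    jointly so the matrices stay paired.

    Returns ``(bs_kept, oxbs_kept, report)`` where ``report`` lists removed
    probe_ids with their failing-sample counts.
    """
    if not (0 < detp_threshold < 1 and 0 < sample_frac < 1):
        raise ValidationError("thresholds must be in (0, 1)")
    if not bs.probe_ids.equals(oxbs.probe_ids):
        raise AlignmentError("BS and oxBS matrices must share the probe index")
    pooled = pd.concat([bs.detection_p, oxbs.detection_p], axis=1)
    n_samples = pooled.shape[1]
    n_fail = (pooled > detp_threshold).sum(axis=1)
    remove = n_fail > sample_frac * n_samples
    report = pd.DataFrame({
        "probe_id": bs.probe_ids[remove],
        "n_fail": n_fail[remove].to_numpy(),
        "n_samples": n_samples,
    }).set_index("probe_id")
    kept = bs.probe_ids[~remove]
    if len(kept) == 0:
        raise ValidationError("empty after QC: every probe exceeded the detection-failure limit")
    return bs.subset_probes(kept), oxbs.subset_probes(kept), report


def normalize_stratified_quantile(
    matrix: BetaMatrix,
    strata: pd.Series | None = None,
) -> BetaMatrix:
    """Quantile-normalize betas across samples within probe strata.

    Within each stratum every sample's beta values are mapped onto the
    across-sample mean quantile function, preserving within-sample ranks
    inside the stratum. ``strata`` is a probe_id -> label Series; the
    default is a single stratum. This is the normalization slot of the
    pipeline; the binomial simulator needs none, so it is OFF by default
    in the pipeline driver.

    Strata with fewer than 2 probes are left unnormalized with a warning.
    """
    if matrix.n_samples < 2:
        raise ValidationError("normalization needs >= 2 samples")
    if strata is None:
        strata = pd.Series("all", index=matrix.probe_ids)
    strata = strata.reindex(matrix.probe_ids)
    if strata.isna().any():
        raise AlignmentError("strata must cover every probe")
    out = matrix.beta.copy()
    for label, ids in matrix.beta.groupby(strata, sort=False).groups.items():
        block = matrix.beta.loc[ids]
        if len(ids) < 2:
            warnings.warn(f"stratum {label!r} has <2 probes; left unnormalized")
            continue
        out.loc[ids] = _quantile_normalize(block)
    return BetaMatrix(beta=out, detection_p=matrix.detection_p,
                      coverage=matrix.coverage, probes=matrix.probes,
                      channel=matrix.channel)


def _quantile_normalize(block: pd.DataFrame) -> pd.DataFrame:
    """Map every column onto the mean of the per-column quantile functions."""
    arr = block.to_numpy(dtype=float)
    n, k = arr.shape
    grid = np.linspace(0, 1, n)
    # reference distribution: mean quantile function over samples (NaN-aware)
    qfuncs = np.empty((n, k))
    for j in range(k):
        col = arr[:, j]
        valid = np.sort(col[~np.isnan(col)])
        if len(valid) == 0:
            raise ValidationError("normalization: a sample has no defined betas in a stratum")
        qfuncs[:, j] = np.interp(grid, np.linspace(0, 1, len(valid)), valid)
    reference = qfuncs.mean(axis=1)
    out = np.full_like(arr, np.nan)
    for j in range(k):
        col = arr[:, j]
        mask = ~np.isnan(col)
        nv = mask.sum()
        ranks = stats.rankdata(col[mask], method="average")
        q = (ranks - 1) / max(nv - 1, 1)
        out[mask, j] = np.interp(q, grid, reference)
    return pd.DataFrame(np.clip(out, 0.0, 1.0), index=block.index, columns=block.columns)
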