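"""Shared containers for paired BS/oxBS array analysis.

All genomic coordinates held in these containers are 0-based half-open.
CpG probes are points at the cytosine on the + strand; both-strand evidence
is collapsed (probes are strandless). Beta values are fractions in [0, 1];
missing values propagate as NaN and are never imputed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("proliferative", "differentiating", "ifc")
CHANNELS = ("BS", "oxBS")

PROBE_COLUMNS = ("chrom", "pos")


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class FormatError(ValidationError):
    """A file or table has malformed content; message names the location."""


class AlignmentError(ValidationError):
    """Two objects that must share an index (probes, samples) do not."""


class CapacityError(ValidationError):
    """A simulated genome cannot host the requested features."""


class PairingError(ValidationError):
    """BS/oxBS samples cannot be paired by (condition, culture)."""


@dataclass
class BetaMatrix:
    """Probes x samples beta values with detection p-values and pseudo-coverage.

    Parameters
    ----------
    beta, detection_p, coverage
        DataFrames sharing the same probe index (rows) and sample columns.
        ``coverage`` is the binomial pseudo-count standing in for array
        intensity; it weights the maximum-likelihood estimation.
    probes
        DataFrame indexed by probe_id with columns ``chrom`` and ``pos``
        (0-based position of the CpG cytosine; TSV round-trips write the
        array-manifest 1-based convention and convert on load).
    channel
        ``"BS"`` (conventional bisulfite: reads 5mC+5hmC) or ``"oxBS"``
        (oxidative bisulfite: reads 5mC only).
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    coverage: pd.DataFrame
    probes: pd.DataFrame
    channel: str

    def __post_init__(self) -> None:
        self.validate()

    # -- interface ---------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return len(self.beta.index)

    @property
    def n_samples(self) -> int:
        return len(self.beta.columns)

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        idx = pd.Index(probe_ids)
        return BetaMatrix(
            beta=self.beta.loc[idx],
            detection_p=self.detection_p.loc[idx],
            coverage=self.coverage.loc[idx],
            probes=self.probes.loc[idx],
            channel=self.channel,
        )

    def validate(self) -> None:
        if self.channel not in CHANNELS:
            raise ValidationError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.beta.index.has_duplicates:
            dups = self.beta.index[self.beta.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe_ids: {dups[:5]}")
        for name, frame in (("detection_p", self.detection_p), ("coverage", self.coverage)):
            if not frame.index.equals(self.beta.index) or not frame.columns.equals(self.beta.columns):
                raise AlignmentError(f"{name} index/columns do not match beta matrix")
        if not self.probes.index.equals(self.beta.index):
            raise AlignmentError("probe table index does not match beta matrix")
        missing = [c for c in PROBE_COLUMNS if c not in self.probes.columns]
        if missing:
            raise FormatError(f"probe table missing columns: {missing}")
        _check_unit_interval(self.beta, "beta", allow_nan=True)
        _check_unit_interval(self.detection_p, "detection_p", allow_nan=False)
        cov = self.coverage.to_numpy(dtype=float)
        if not np.all(cov >= 1):
            r, c = np.argwhere(~(cov >= 1))[0]
            raise FormatError(
                f"coverage must be >= 1; offending cell probe={self.beta.index[r]!r} "
                f"sample={self.beta.columns[c]!r} value={cov[r, c]!r}"
            )


def _check_unit_interval(frame: pd.DataFrame, name: str, allow_nan: bool) -> None:
    arr = frame.to_numpy(dtype=float)
    bad = (arr < 0) | (arr > 1)
    if not allow_nan:
        bad |= np.isnan(arr)
    else:
        bad &= ~np.isnan(arr)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{name} outside [0,1] at probe={frame.index[r]!r} "
            f"sample={frame.columns[c]!r} value={arr[r, c]!r}"
        )


# -- sample sheet ----------------------------------------------------------
SAMPLE_SHEET_COLUMNS = ("sample_id", "culture", "condition", "channel")


def validate_sample_sheet(sheet: pd.DataFrame, require_replicates: bool = True) -> pd.DataFrame:
    """Validate a sample sheet (sample_id, culture, condition, channel).

    Each (condition, culture) pair must carry exactly one BS and one oxBS
    sample; with ``require_replicates`` every condition needs >= 2 cultures,
    the minimum for any variance estimate.
    """
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_ids in sample sheet")
    bad_chan = set(sheet["channel"]) - set(CHANNELS)
    if bad_chan:
        raise ValidationError(f"unknown channels in sample sheet: {sorted(bad_chan)}")
    counts = sheet.groupby(["condition", "culture"])["channel"].agg(list)
    for (cond, cult), chans in counts.items():
        if sorted(chans) != ["BS", "oxBS"]:
            raise PairingError(
                f"(condition={cond!r}, culture={cult!r}) must have exactly one BS and "
                f"one oxBS sample, got {chans}"
            )
    if require_replicates:
        ncult = sheet.groupby("condition")["culture"].nunique()
        low = ncult[ncult < 2]
        if len(low):
            raise ValidationError(f"conditions with <2 cultures: {dict(low)}")
    return sheet


def pair_table(sheet: pd.DataFrame) -> pd.DataFrame:
    """Map each (condition, culture) pair to its BS and oxBS sample ids.

    Returns a DataFrame indexed by pair id ``condition:culture`` with columns
    condition, culture, bs_sample, oxbs_sample.
    """
    validate_sample_sheet(sheet, require_replicates=False)
    rows = []
    for (cond, cult), grp in sheet.groupby(["condition", "culture"], sort=False):
        bs = grp.loc[grp["channel"] == "BS", "sample_id"].iloc[0]
        ox = grp.loc[grp["channel"] == "oxBS", "sample_id"].iloc[0]
        rows.append({"pair_id": f"{cond}:{cult}", "condition": cond, "culture": cult,
                     "bs_sample": bs, "oxbs_sample": ox})
    return pd.DataFrame(rows).set_index("pair_id")


@dataclass
class MethylomeEstimate:
    """Per-probe, per-culture maximum-likelihood estimates of 5mC and 5hmC.

    ``h_hat`` is NaN wherever the naive BS-oxBS difference is negative (the
    boundary of the simplex); ``m_hat`` stays defined there (pooled-count
    boundary estimate). ``na_mask`` is True exactly where ``h_hat`` is NaN.
    ``pairs`` maps each column (pair id) to condition and culture.
    """

    m_hat: pd.DataFrame
    h_hat: pd.DataFrame
    na_mask: pd.DataFrame
    probes: pd.DataFrame
    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.m_hat.to_numpy(dtype=float)
        h = self.h_hat.to_numpy(dtype=float)
        defined = ~np.isnan(h)
        if not np.array_equal(~defined, self.na_mask.to_numpy(dtype=bool)):
            raise ValidationError("na_mask must be True exactly where h_hat is NaN")
        if defined.any():
            mm, hh = m[defined], h[defined]
            if np.any(mm < -1e-12) or np.any(hh < -1e-12) or np.any(mm + hh > 1 + 1e-9):
                raise ValidationError("estimates violate 0 <= m, h and m + h <= 1")

    @property
    def na_fraction_per_pair(self) -> pd.Series:
        return self.na_mask.mean(axis=0)


@dataclass
class GenomeAnnotation:
    """Toy-genome annotation: gene models, CGIs, chromatin states, gene sets.

    genes : DataFrame indexed by gene_id with chrom, start, end, strand, tss.
    exons : map gene_id -> list of (start, end) within the gene span.
    cgis / chrom_states : interval tables (chrom, start, end[, state]).
    gene_sets : Series gene_id -> {"up", "down", "housekeeping", "none"}.
    """

    chrom_sizes: dict
    genes: pd.DataFrame
    exons: dict
    cgis: pd.DataFrame
    chrom_states: pd.DataFrame
    gene_sets: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for gid, row in self.genes.iterrows():
            size = self.chrom_sizes.get(row["chrom"])
            if size is None:
                raise ValidationError(f"gene {gid} on unknown chromosome {row['chrom']}")
            if not (0 <= row["start"] < row["end"] <= size):
                raise ValidationError(f"gene {gid} interval [{row['start']},{row['end']}) out of bounds")
            if row["strand"] not in "+-":
                raise ValidationError(f"gene {gid} strand must be + or -")
            exons = sorted(self.exons.get(gid, []))
            prev_end = None
            for s, e in exons:
                if not (row["start"] <= s < e <= row["end"]):
                    raise ValidationError(f"exon ({s},{e}) of gene {gid} not nested in gene span")
                if prev_end is not None and s < prev_end:
                    raise ValidationError(f"overlapping exons in gene {gid}")
                prev_end = e
        for name, table in (("cgis", self.cgis), ("chrom_states", self.chrom_states)):
            for _, row in table.iterrows():
                if row["end"] <= row["start"]:
                    raise FormatError(f"{name}: interval end <= start at {tuple(row)}")
        labels = set(self.gene_sets.unique()) - {"up", "down", "housekeeping", "none"}
        if labels:
            raise ValidationError(f"unknown gene_set labels: {sorted(labels)}")
        unlabeled = self.genes.index.difference(self.gene_sets.index)
        if len(unlabeled):
            raise ValidationError(f"genes without a gene_set label: {list(unlabeled[:5])}")


@dataclass
class TruthMethylome:
    """Latent per-probe (5mC, 5hmC) fractions per condition.

    probes : DataFrame indexed by probe_id with chrom, pos (0-based point)
    and a ``context`` column recording the generator's placement class
    (body/promoter/cgi/intergenic) plus the owning gene where applicable.
    m, h : DataFrames probes x conditions with fractions in [0, 1].
    """

    probes: pd.DataFrame
    m: pd.DataFrame
    h: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.m.index.equals(self.probes.index) and self.h.index.equals(self.probes.index)):
            raise AlignmentError("truth matrices must share the probe index")
        marr, harr = self.m.to_numpy(float), self.h.to_numpy(float)
        if np.any(marr < 0) or np.any(harr < 0) or np.any(marr + harr > 1 + 1e-9):
            raise ValidationError("truth must satisfy 0 <= m, h and m + h <= 1")
        for chrom, grp in self.probes.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(f"probe positions not strictly increasing on {chrom}")

    @property
    def conditions(self) -> list:
        return list(self.m.columns)
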