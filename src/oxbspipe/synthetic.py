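"""Synthetic paired BS/oxBS array datasets on a toy genome.

The generator emulates the statistical structure of a paired
bisulfite / oxidative-bisulfite EPIC-style experiment on differentiating
hepatic progenitor cells: a single toy chromosome with ~50 genes, CpG
probes clustered in gene bodies, promoters, CGIs and intergenic space,
latent per-condition (5mC, 5hmC) fractions, and binomial measurement noise
at a configurable pseudo-coverage standing in for array intensity.

Default condition profiles target the gene-body means of the modelled
study: 5hmC 2.2 / 4.1 / 3.5 % and 5mC 51.7 / 49.1 / 50.5 % for
proliferative / differentiating / adenosine-derivative (ifc) cultures,
with 2 / 2 / 3 culture replicates.

Per-probe 5mC truth is drawn from a two-component (hypo/hyper-methylated)
beta mixture — the canonical bimodal shape of methylome data — with the
mixture weight solved per condition so gene-body means hit the profile
targets. 5hmC truth is a high-concentration beta draw around
context-specific means: gains concentrated on the bodies of up-regulated
genes and introns, depressed at promoters and CGIs, plus a small set of
strong-gain CpG clusters (whole body-probe clusters at true h ~ 0.30) on
up-regulated genes so position/region calling at a 20 % delta threshold
has targets, as in the modelled study.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    BetaMatrix,
    CapacityError,
    GenomeAnnotation,
    TruthMethylome,
    ValidationError,
    validate_sample_sheet,
)

DEFAULT_PROFILES = {
    # condition -> (gene-body mean 5mC, gene-body mean 5hmC)
    "proliferative": (0.517, 0.022),
    "differentiating": (0.491, 0.041),
    "ifc": (0.505, 0.035),
}
DEFAULT_CULTURES = {"proliferative": 2, "differentiating": 2, "ifc": 3}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment; defaults are the study conditions."""

    seed: int = 1
    coverage: int = 1000              # binomial pseudo-coverage per probe x sample
    detection_failure_rate: float = 0.005   # per-cell failure rate of ordinary probes
    bad_probe_fraction: float = 0.05        # planted low-quality probe subpopulation
    bad_probe_failure_rate: float = 0.5
    cultures: dict = field(default_factory=lambda: dict(DEFAULT_CULTURES))
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    # probe layout
    probes_per_gene_body: int = 10
    promoter_probes_per_gene: int = 2
    intergenic_spacing: int = 40_000
    # truth dispersion
    m_component_means: tuple = (0.88, 0.08)  # hyper / hypo methylated components
    m_concentration: float = 80.0
    h_concentration: float = 300.0
    # strong 5hmC-gain clusters (per condition: number of up-genes carrying one)
    strong_gain_genes: dict = field(default_factory=lambda: {"differentiating": 5, "ifc": 3})
    strong_gain_h: float = 0.30

    def __post_init__(self) -> None:
        if self.coverage < 1:
            raise ValidationError("coverage must be >= 1")
        for rate in (self.detection_failure_rate, self.bad_probe_failure_rate):
            if not (0 <= rate < 1):
                raise ValidationError("failure rates must be in [0, 1)")
        for cond, n in self.cultures.items():
            if n < 2:
                raise ValidationError(f"condition {cond!r} needs >= 2 cultures, got {n}")
        for cond, (m, h) in self.profiles.items():
            if m + h > 1 or m < 0 or h < 0:
                raise ValidationError(f"profile for {cond!r} infeasible: m+h must be in [0, 1]")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    seed: int,
    n_genes: int = 50,
    chrom_length: int = 5_000_000,
    chrom: str = "chr1",
    gene_set_props: tuple = (0.25, 0.25, 0.10),
    cgi_fraction: float = 0.6,
) -> GenomeAnnotation:
    """Place non-overlapping genes with exons, CGIs, chromatin states, gene sets.

    Deterministic for a fixed seed. ``gene_set_props`` are the (up, down,
    housekeeping) label fractions; the remainder is labelled "none".
    Raises :class:`CapacityError` when the chromosome cannot host the genes.
    """
    if n_genes < 1:
        raise CapacityError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(8_000, 30_000, size=n_genes)
    min_gap = 15_000  # room for promoter windows, CGI shores/shelves
    slack = chrom_length - int(lengths.sum()) - (n_genes + 1) * min_gap
    if slack < 0:
        raise CapacityError(
            f"cannot place {n_genes} genes (total {lengths.sum()} bp) on {chrom_length} bp"
        )
    extra = rng.multinomial(slack, np.full(n_genes + 1, 1 / (n_genes + 1)))
    gaps = min_gap + extra

    genes, exons = [], {}
    cursor = 0
    for i in range(n_genes):
        cursor += int(gaps[i])
        start, end = cursor, cursor + int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{i + 1:03d}"
        tss = start if strand == "+" else end
        genes.append({"gene_id": gid, "chrom": chrom, "start": start, "end": end,
                      "strand": strand, "tss": tss})
        # alternating exon/intron segmentation of the gene span
        n_exons = int(rng.integers(3, 9))
        cuts = np.sort(rng.uniform(0.02, 0.98, size=2 * n_exons - 2))
        bounds = np.concatenate([[0.0], cuts, [1.0]])
        segs = start + np.round(bounds * (end - start)).astype(int)
        exons[gid] = [(int(segs[j]), int(segs[j + 1]))
                      for j in range(0, 2 * n_exons - 1, 2)
                      if segs[j + 1] > segs[j]]
        cursor = end
    genes_df = pd.DataFrame(genes).set_index("gene_id")

    # CGIs: ~1 kb islands at a fraction of TSSs
    cgi_genes = rng.choice(genes_df.index, size=int(round(cgi_fraction * n_genes)), replace=False)
    cgi_rows = []
    for gid in sorted(cgi_genes):
        tss = int(genes_df.loc[gid, "tss"])
        s = max(0, tss - 500)
        cgi_rows.append({"chrom": chrom, "start": s, "end": min(chrom_length, tss + 500)})
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"]).sort_values("start").reset_index(drop=True)

    # chromatin states: promoter / elongation / weak txn over genes, heterochromatin between
    state_rows = []
    prev_end = 0
    for gid, row in genes_df.iterrows():
        s, e, strand = int(row["start"]), int(row["end"]), row["strand"]
        tss = int(row["tss"])
        if strand == "+":
            prom = (max(0, tss - 2000), min(chrom_length, tss + 500))
        else:
            prom = (max(0, tss - 500), min(chrom_length, tss + 2000))
        left = min(prom[0], s)
        if left > prev_end:
            state_rows.append({"chrom": chrom, "start": prev_end, "end": left, "state": "Heterochromatin"})
        state_rows.append({"chrom": chrom, "start": prom[0], "end": prom[1], "state": "Promoter"})
        body = (max(prom[1], s), e) if strand == "+" else (s, min(prom[0], e))
        if body[1] > body[0]:
            mid = (body[0] + body[1]) // 2
            state_rows.append({"chrom": chrom, "start": body[0], "end": mid, "state": "Txn Elongation"})
            state_rows.append({"chrom": chrom, "start": mid, "end": body[1], "state": "Weak Txn"})
        prev_end = max(e, prom[1])
    if prev_end < chrom_length:
        state_rows.append({"chrom": chrom, "start": prev_end, "end": chrom_length, "state": "Heterochromatin"})
    states = pd.DataFrame(state_rows)

    n_up = int(round(gene_set_props[0] * n_genes))
    n_down = int(round(gene_set_props[1] * n_genes))
    n_hk = int(round(gene_set_props[2] * n_genes))
    labels = (["up"] * n_up + ["down"] * n_down + ["housekeeping"] * n_hk
              + ["none"] * (n_genes - n_up - n_down - n_hk))
    gene_sets = pd.Series(rng.permutation(labels), index=genes_df.index, name="gene_set")

    return GenomeAnnotation(
        chrom_sizes={chrom: chrom_length},
        genes=genes_df,
        exons=exons,
        cgis=cgis,
        chrom_states=states,
        gene_sets=gene_sets,
    )


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def _layout_probes(annotation: GenomeAnnotation, config: SimulationConfig, rng) -> pd.DataFrame:
    """Place probes: clustered in gene bodies, at promoters, CGIs, intergenic."""
    chrom = next(iter(annotation.chrom_sizes))
    length = annotation.chrom_sizes[chrom]
    rows = []
    for gid, g in annotation.genes.iterrows():
        s, e, strand, tss = int(g["start"]), int(g["end"]), g["strand"], int(g["tss"])
        # body probes in CpG-like clusters (sizes 4/3/3 by default layout)
        n_body = config.probes_per_gene_body
        sizes = []
        remaining = n_body
        for base in (4, 3):
            take = min(base, remaining)
            if take:
                sizes.append(take)
            remaining -= take
        if remaining:
            sizes.append(remaining)
        anchors = np.sort(rng.uniform(0.1, 0.85, size=len(sizes))) * (e - s) + s
        cluster = 0
        for anchor, size in zip(anchors, sizes):
            for k in range(size):
                pos = int(anchor) + k * int(rng.integers(100, 300))
                pos = min(pos, e - 1)
                rows.append({"chrom": chrom, "pos": pos, "context": "body",
                             "gene_id": gid, "cluster": f"{gid}.c{cluster}"})
            cluster += 1
        # promoter probes inside the (-2000, +500) oriented window
        offsets = np.linspace(-1200, 300, config.promoter_probes_per_gene)
        for off in offsets:
            pos = tss + int(off) * (1 if strand == "+" else -1)
            rows.append({"chrom": chrom, "pos": int(np.clip(pos, 0, length - 1)),
                         "context": "promoter", "gene_id": gid, "cluster": ""})
    for _, c in annotation.cgis.iterrows():
        rows.append({"chrom": chrom, "pos": int((c["start"] + c["end"]) // 2),
                     "context": "cgi", "gene_id": "", "cluster": ""})
    # sparse intergenic probes
    occupied = [(int(r["start"]) - 2500, int(r["end"]) + 2500) for _, r in annotation.genes.iterrows()]
    pos = config.intergenic_spacing // 2
    while pos < length:
        if not any(a <= pos < b for a, b in occupied):
            rows.append({"chrom": chrom, "pos": int(pos), "context": "intergenic",
                         "gene_id": "", "cluster": ""})
        pos += config.intergenic_spacing

    probes = pd.DataFrame(rows).sort_values(["chrom", "pos"], kind="mergesort")
    probes = probes[~probes.duplicated(subset=["chrom", "pos"])].reset_index(drop=True)
    probes.index = pd.Index([f"cg{i + 1:06d}" for i in range(len(probes))], name="probe_id")
    return probes


def _probe_in_exon(probes: pd.DataFrame, annotation: GenomeAnnotation) -> np.ndarray:
    flags = np.zeros(len(probes), dtype=bool)
    for i, (pid, row) in enumerate(probes.iterrows()):
        gid = row["gene_id"]
        if row["context"] != "body" or not gid:
            continue
        flags[i] = any(s <= row["pos"] < e for s, e in annotation.exons.get(gid, []))
    return flags


def generate_truth(annotation: GenomeAnnotation, config: SimulationConfig) -> TruthMethylome:
    """Draw latent per-condition (m, h) per probe, calibrated to the profiles.

    Gene-body means of both m and h hit the configured per-condition
    targets within +/- 0.002 (enforced). 5mC calibration solves the
    hyper/hypo-methylated mixture weight on the realized draws; 5hmC in
    the non-reference conditions is the reference baseline plus a
    non-negative, gene-set/exon-weighted gain (so the differentiating
    hydroxymethylome dominates the proliferative one pointwise on gene
    bodies). Strong-gain clusters are pinned at ``strong_gain_h`` and
    excluded from the mean recalibration so their delta-beta magnitude is
    preserved.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    probes = _layout_probes(annotation, config, rng)
    n = len(probes)
    conditions = list(config.profiles)
    in_exon = _probe_in_exon(probes, annotation)
    gene_set = probes["gene_id"].map(annotation.gene_sets).fillna("none")
    is_body = (probes["context"] == "body").to_numpy()

    # strong-gain clusters: whole body clusters of up-regulated genes
    up_genes = sorted(annotation.gene_sets.index[annotation.gene_sets == "up"])
    max_strong = max(config.strong_gain_genes.values(), default=0)
    strong_gene_pool = up_genes[:max_strong]
    def _gene_cluster_mask(gid):
        mask = np.zeros(n, dtype=bool)
        cl = probes.loc[(probes["gene_id"] == gid) & (probes["cluster"] == f"{gid}.c0")]
        mask[probes.index.get_indexer(cl.index)] = True
        return mask

    strong_gene_masks = {
        cond: [(gid, _gene_cluster_mask(gid)) for gid in strong_gene_pool[:k]]
        for cond, k in config.strong_gain_genes.items()
    }
    any_strong = np.zeros(n, dtype=bool)
    for pairs in strong_gene_masks.values():
        for _, mask in pairs:
            any_strong |= mask

    # --- 5mC: shared latent component membership + within-component quantile
    u = rng.uniform(size=n)
    u[any_strong] = 0.999  # strong 5hmC-gain loci sit in the hypomethylated component
    t_m = rng.uniform(size=n)
    hi, lo = config.m_component_means
    kappa_m = config.m_concentration
    promoterish = probes["context"].isin(["promoter", "cgi"]).to_numpy()
    hi_vals = stats.beta.ppf(t_m, hi * kappa_m, (1 - hi) * kappa_m)
    lo_vals = stats.beta.ppf(t_m, lo * kappa_m, (1 - lo) * kappa_m)
    prom_vals = stats.beta.ppf(t_m, 0.12 * kappa_m, 0.88 * kappa_m)

    def m_for_weight(w):
        vals = np.where(u < w, hi_vals, lo_vals)
        return np.where(promoterish, prom_vals, vals)

    m = {}
    for cond in conditions:
        m_target = config.profiles[cond][0]
        # solve the mixture weight on the realized draws (monotone in w)
        w_lo, w_hi = 0.0, 1.0
        for _ in range(40):
            w = 0.5 * (w_lo + w_hi)
            if m_for_weight(w)[is_body].mean() < m_target:
                w_lo = w
            else:
                w_hi = w
        vals = m_for_weight(0.5 * (w_lo + w_hi))
        residual = m_target / vals[is_body].mean()  # sub-granularity correction
        m[cond] = np.clip(vals * residual, 0.0, 0.99)

    # --- 5hmC: reference baseline plus non-negative structured gain
    t_h = rng.uniform(size=n)
    t_g = rng.uniform(size=n)
    kappa_h = config.h_concentration
    set_weight = gene_set.map({"up": 1.6, "none": 1.0, "housekeeping": 0.9, "down": 0.8}).to_numpy()
    exon_weight = np.where(in_exon, 0.8, 1.15)
    context_weight = probes["context"].map(
        {"body": 1.0, "promoter": 0.30, "cgi": 0.25, "intergenic": 0.7}
    ).to_numpy()
    gain_rel = context_weight * np.where(is_body, set_weight * exon_weight, 1.0)

    def beta_draw(t, mu, kappa):
        mu = np.clip(mu, 1e-4, 0.9)
        return stats.beta.ppf(t, mu * kappa, (1 - mu) * kappa)

    def rescale_body(vals, target, adjustable):
        """Multiplicatively rescale ``adjustable`` probes to hit the body mean."""
        for _ in range(6):
            body_mean = vals[is_body].mean()
            if abs(body_mean - target) < 1e-5:
                break
            want = target * is_body.sum() - vals[is_body & ~adjustable].sum()
            have = vals[is_body & adjustable].sum()
            if want <= 0 or have <= 0:
                raise ValidationError(f"infeasible gene-body 5hmC target {target}")
            vals = np.where(adjustable, np.clip(vals * (want / have), 0.0, 0.9), vals)
        return vals

    base_cond = conditions[0]
    base_target = config.profiles[base_cond][1]
    if base_target == 0:
        h_base = np.zeros(n)
    else:
        h_base = beta_draw(t_h, base_target * context_weight, kappa_h)
        h_base = rescale_body(h_base, base_target, np.ones(n, dtype=bool))

    h = {base_cond: h_base}
    gain_unit = beta_draw(t_g, 0.02 * gain_rel, kappa_h)  # unit gain pattern, scaled per condition
    for cond in conditions[1:]:
        h_target = config.profiles[cond][1]
        if h_target == 0:
            h[cond] = np.zeros(n)
            continue
        if h_target < base_target:
            h[cond] = h_base * (h_target / base_target)
            continue
        chosen = list(strong_gene_masks.get(cond, []))
        while True:
            strong = np.zeros(n, dtype=bool)
            for _, mask in chosen:
                strong |= mask
            vals = h_base.copy()
            if strong.any():
                sh = config.strong_gain_h
                vals[strong] = np.maximum(vals[strong],
                                          beta_draw(t_h[strong], np.full(strong.sum(), sh), 100))
            fixed_sum = np.where(strong, vals, h_base)[is_body].sum()
            if h_target * is_body.sum() >= fixed_sum or not chosen:
                break
            chosen.pop()  # small genome: planted gain alone overshoots the mean target
        vals = _scale_gain_to_target(vals, h_base, gain_unit, strong, is_body, h_target)
        h[cond] = vals

    m_df = pd.DataFrame(m, index=probes.index)[conditions]
    h_df = pd.DataFrame(h, index=probes.index)[conditions]
    # joint feasibility: shave m first (h carries the planted structure)
    excess = m_df.to_numpy() + h_df.to_numpy() - 1.0
    if (excess > 0).any():
        m_df = pd.DataFrame(np.where(excess > 0, m_df.to_numpy() - excess - 1e-6, m_df.to_numpy()),
                            index=probes.index, columns=conditions)

    truth = TruthMethylome(probes=probes, m=m_df, h=h_df)
    for cond in conditions:
        m_target, h_target = config.profiles[cond]
        got_h = truth.h.loc[is_body, cond].mean()
        got_m = truth.m.loc[is_body, cond].mean()
        if h_target > 0 and abs(got_h - h_target) > 2e-3:
            raise ValidationError(f"h calibration failed for {cond!r}: {got_h:.4f} vs {h_target}")
        if abs(got_m - m_target) > 2e-3:
            raise ValidationError(f"m calibration failed for {cond!r}: {got_m:.4f} vs {m_target}")
    return truth


def _scale_gain_to_target(vals, h_base, gain_unit, strong, is_body, target):
    """Scale the non-strong gain so the gene-body mean hits ``target``.

    The baseline is a floor (gain never negative), preserving pointwise
    dominance over the reference condition; strong-gain probes keep their
    pinned level and are excluded from the scaling.
    """
    n_body = is_body.sum()
    fixed = np.where(strong, vals, h_base)
    out = vals
    for _ in range(4):
        needed = target * n_body - fixed[is_body].sum()
        have = gain_unit[is_body & ~strong].sum()
        if have <= 0 or needed < 0:
            raise ValidationError(f"infeasible gene-body 5hmC target {target}")
        s = needed / have
        out = np.where(strong, vals, np.clip(h_base + s * gain_unit, 0.0, 0.9))
        if abs(out[is_body].mean() - target) < 1e-5:
            break
    return out


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def simulate_paired_arrays(truth: TruthMethylome, config: SimulationConfig):
    """Binomial measurement of the truth: paired BS and oxBS beta matrices.

    For every culture replicate and probe, BS counts are Binomial(N, m+h)
    and oxBS counts Binomial(N, m); betas are counts / N. Detection
    p-values are small for ordinary cells and elevated for failed cells;
    a planted subpopulation of "bad" probes fails at a high per-cell rate
    so the detection-based probe filter has deterministic targets.

    Returns ``(bs, oxbs, sample_sheet)``.
    """
    missing = [c for c in config.cultures if c not in truth.m.columns]
    if missing:
        raise ValidationError(f"conditions missing from truth: {missing}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    n = len(truth.probes)
    N = config.coverage

    bad = np.zeros(n, dtype=bool)
    n_bad = int(round(config.bad_probe_fraction * n))
    if n_bad:
        bad[rng.choice(n, size=n_bad, replace=False)] = True

    sheet_rows, bs_cols, ox_cols, detp_bs, detp_ox = [], {}, {}, {}, {}
    for cond, n_cult in config.cultures.items():
        m = truth.m[cond].to_numpy()
        h = truth.h[cond].to_numpy()
        p_bs = np.clip(m + h, 0.0, 1.0)
        for c in range(1, n_cult + 1):
            culture = f"c{c}"
            for channel, p in (("BS", p_bs), ("oxBS", m)):
                sid = f"{cond}_{culture}_{channel}"
                counts = rng.binomial(N, p)
                beta = counts / N
                fail_rate = np.where(bad, config.bad_probe_failure_rate,
                                     config.detection_failure_rate)
                failed = rng.uniform(size=n) < fail_rate
                detp = np.where(failed, rng.uniform(0.02, 0.8, size=n),
                                rng.uniform(0.0, 0.005, size=n))
                (bs_cols if channel == "BS" else ox_cols)[sid] = beta
                (detp_bs if channel == "BS" else detp_ox)[sid] = detp
                sheet_rows.append({"sample_id": sid, "culture": culture,
                                   "condition": cond, "channel": channel})

    probes = truth.probes[["chrom", "pos"]].copy()
    cov = lambda cols: pd.DataFrame(N, index=probes.index, columns=list(cols), dtype=float)
    bs = BetaMatrix(
        beta=pd.DataFrame(bs_cols, index=probes.index),
        detection_p=pd.DataFrame(detp_bs, index=probes.index),
        coverage=cov(bs_cols),
        probes=probes,
        channel="BS",
    )
    oxbs = BetaMatrix(
        beta=pd.DataFrame(ox_cols, index=probes.index),
        detection_p=pd.DataFrame(detp_ox, index=probes.index),
        coverage=cov(ox_cols),
        probes=probes,
        channel="oxBS",
    )
    sheet = validate_sample_sheet(pd.DataFrame(sheet_rows))
    return bs, oxbs, sheet


def simulate_dataset(config: SimulationConfig | None = None, n_genes: int = 50,
                     chrom_length: int = 5_000_000):
    """One-call default experiment: annotation, truth and paired arrays."""
    config = config or SimulationConfig()
    annotation = generate_annotation(config.seed, n_genes=n_genes, chrom_length=chrom_length)
    truth = generate_truth(annotation, config)
    bs, oxbs, sheet = simulate_paired_arrays(truth, config)
    return annotation, truth, bs, oxbs, sheet


# ---------------------------------------------------------------------------
# planted-effect panels for calibration studies
# ---------------------------------------------------------------------------

def _flat_panel(rng, pos, m, h, coverage, conditions):
    """Paired matrices for explicit per-condition (m, h) vectors."""
    n = len(pos)
    probes = pd.DataFrame({"chrom": "chr1", "pos": pos},
                          index=pd.Index([f"cg{i + 1:06d}" for i in range(n)], name="probe_id"))
    bs_cols, ox_cols, rows = {}, {}, []
    for cond, (mc, hc, n_cult) in conditions.items():
        p_bs = np.clip(mc + hc, 0, 1)
        for c in range(1, n_cult + 1):
            for channel, p in (("BS", p_bs), ("oxBS", mc)):
                sid = f"{cond}_c{c}_{channel}"
                (bs_cols if channel == "BS" else ox_cols)[sid] = rng.binomial(coverage, p) / coverage
                rows.append({"sample_id": sid, "culture": f"c{c}", "condition": cond,
                             "channel": channel})
    make = lambda cols, ch: BetaMatrix(
        beta=pd.DataFrame(cols, index=probes.index),
        detection_p=pd.DataFrame(0.0, index=probes.index, columns=list(cols)),
        coverage=pd.DataFrame(float(coverage), index=probes.index, columns=list(cols)),
        probes=probes, channel=ch)
    return make(bs_cols, "BS"), make(ox_cols, "oxBS"), validate_sample_sheet(pd.DataFrame(rows))


def simulate_peak_panel(seed: int, n_probes: int = 1000, n_peaks: int = 100,
                        h_peak: float = 0.25, m_base: float = 0.5,
                        coverage: int = 1000, n_cultures: int = 3):
    """Panel with ``n_peaks`` true-5hmC probes among nulls, one condition.

    Returns (bs, oxbs, sheet, is_peak) where ``is_peak`` is the boolean
    ground-truth mask over the probe index.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    pos = np.arange(n_probes) * 5000 + 1000
    h = np.zeros(n_probes)
    peak_idx = rng.choice(n_probes, size=n_peaks, replace=False)
    h[peak_idx] = h_peak
    m = np.full(n_probes, m_base)
    bs, oxbs, sheet = _flat_panel(rng, pos, m, h, coverage,
                                  {"panel": (m, h, n_cultures)})
    is_peak = pd.Series(False, index=bs.probe_ids)
    is_peak.iloc[peak_idx] = True
    return bs, oxbs, sheet, is_peak


def simulate_differential_blocks(seed: int, n_blocks: int = 8, block_size: int = 4,
                                 delta_h: float = 0.25, h_base: float = 0.05,
                                 m_base: float = 0.5, coverage: int = 1000,
                                 n_cultures: int = 3, n_null: int = 400,
                                 probe_spacing: int = 200, block_gap: int = 10_000):
    """Two-condition panel with planted contiguous 5hmC-gain blocks.

    Each block is ``block_size`` consecutive probes (``probe_spacing`` bp
    apart, well inside a 1 kb proximity window) whose target-condition true
    5hmC exceeds the reference by ``delta_h``; blocks are separated by
    ``block_gap`` bp. Returns (bs, oxbs, sheet, blocks) where ``blocks``
    is a DataFrame of planted block spans and member probe ids.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 53]))
    pos_list, block_rows, in_block = [], [], []
    cursor = 1000
    for b in range(n_blocks):
        start = cursor
        ids = []
        for k in range(block_size):
            pos_list.append(cursor)
            ids.append(len(pos_list) - 1)
            cursor += probe_spacing
        block_rows.append({"block": b, "start": start, "end": pos_list[-1] + 1, "members": ids})
        in_block.extend(ids)
        cursor += block_gap
    for _ in range(n_null):
        cursor += block_gap
        pos_list.append(cursor)
    pos = np.array(pos_list)
    n = len(pos)
    h_ref = np.full(n, h_base)
    h_tgt = h_ref.copy()
    h_tgt[in_block] += delta_h
    m = np.full(n, m_base)
    bs, oxbs, sheet = _flat_panel(
        rng, pos, m, h_ref, coverage,
        {"reference": (m, h_ref, n_cultures), "target": (m, h_tgt, n_cultures)})
    blocks = pd.DataFrame(block_rows)
    blocks["probe_ids"] = blocks["members"].map(lambda ids: [bs.probe_ids[i] for i in ids])
    return bs, oxbs, sheet, blocks
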