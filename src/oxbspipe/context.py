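"""Genomic-context annotation, enrichment, metagene profiles, gene-set overlap.

Probes are annotated to one genomic feature each with precedence
promoter > exon > intron > intergenic (the toy gene models carry no
CDS/UTR structure, so no UTR classes exist), to a CGI context
(island / shore / shelf / open sea at the universal 2 kb / 2-4 kb
distances) and to the containing chromatin-state segment. Metagene
profiles scale each gene body to a fixed number of bins between TSS and
TES in gene orientation with fixed-width flank bins.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .datamodel import GenomeAnnotation, ValidationError
from .differential import adjust_bh, compare_groups_wilcoxon

FEATURES = ("promoter", "exon", "intron", "intergenic")
CGI_CONTEXTS = ("island", "shore", "shelf", "open_sea")
DEFAULT_PROMOTER_WINDOW = (-2000, 500)  # around TSS, gene orientation


def _promoter_interval(row, window):
    up, down = window
    if row["strand"] == "+":
        return row["tss"] + up, row["tss"] + down
    return row["tss"] - down, row["tss"] - up


def annotate_positions(
    probes: pd.DataFrame,
    annotation: GenomeAnnotation,
    promoter_window: tuple = DEFAULT_PROMOTER_WINDOW,
) -> pd.DataFrame:
    """Annotate probe positions to feature, nearest gene, CGI and state.

    ``probes`` is a DataFrame indexed by probe_id with chrom and pos
    (0-based point). Returns a DataFrame with columns feature,
    nearest_gene, tss_distance (signed, negative upstream of the TSS in
    gene orientation), cgi_context and chrom_state.
    """
    unknown = set(probes["chrom"]) - set(annotation.chrom_sizes)
    if unknown:
        bad = probes.index[probes["chrom"].isin(unknown)]
        raise ValidationError(f"probes on unknown chromosomes {sorted(unknown)}: {list(bad[:5])}")

    prom_tree, exon_tree, gene_tree, cgi_tree, state_tree = {}, {}, {}, {}, {}
    for chrom in annotation.chrom_sizes:
        prom_tree[chrom] = IntervalTree()
        exon_tree[chrom] = IntervalTree()
        gene_tree[chrom] = IntervalTree()
        cgi_tree[chrom] = IntervalTree()
        state_tree[chrom] = IntervalTree()
    for gid, row in annotation.genes.iterrows():
        chrom = row["chrom"]
        s, e = _promoter_interval(row, promoter_window)
        prom_tree[chrom][max(0, s):max(1, e)] = gid
        gene_tree[chrom][row["start"]:row["end"]] = gid
        for xs, xe in annotation.exons.get(gid, []):
            exon_tree[chrom][xs:xe] = gid
    for _, row in annotation.cgis.iterrows():
        cgi_tree[row["chrom"]][row["start"]:row["end"]] = True
    for _, row in annotation.chrom_states.iterrows():
        state_tree[row["chrom"]][row["start"]:row["end"]] = row["state"]

    # per-chromosome sorted CGI edges for shore/shelf distances
    cgi_edges = {
        chrom: np.sort(np.concatenate([grp["start"].to_numpy(), grp["end"].to_numpy() - 1]))
        if len(grp) else np.array([])
        for chrom, grp in annotation.cgis.groupby("chrom")
    }
    genes_by_chrom = {chrom: grp for chrom, grp in annotation.genes.groupby("chrom")}

    rows = []
    for pid, probe in probes.iterrows():
        chrom, pos = probe["chrom"], int(probe["pos"])
        if prom_tree[chrom][pos]:
            feature = "promoter"
        elif exon_tree[chrom][pos]:
            feature = "exon"
        elif gene_tree[chrom][pos]:
            feature = "intron"
        else:
            feature = "intergenic"

        nearest, distance = _nearest_gene(genes_by_chrom.get(chrom), pos)

        if cgi_tree[chrom][pos]:
            cgi = "island"
        else:
            edges = cgi_edges.get(chrom, np.array([]))
            d = np.abs(edges - pos).min() if len(edges) else np.inf
            cgi = "shore" if d <= 2000 else ("shelf" if d <= 4000 else "open_sea")

        hits = state_tree[chrom][pos]
        state = sorted(iv.data for iv in hits)[0] if hits else "Unannotated"
        rows.append({"probe_id": pid, "feature": feature, "nearest_gene": nearest,
                     "tss_distance": distance, "cgi_context": cgi, "chrom_state": state})
    return pd.DataFrame(rows).set_index("probe_id")


def _nearest_gene(genes: pd.DataFrame | None, pos: int):
    if genes is None or not len(genes):
        return "", np.nan
    tss = genes["tss"].to_numpy()
    dist = np.abs(tss - pos)
    best = dist.min()
    # deterministic ties: lexicographically smallest gene_id
    candidates = sorted(genes.index[dist == best])
    gid = candidates[0]
    row = genes.loc[gid]
    signed = pos - row["tss"] if row["strand"] == "+" else row["tss"] - pos
    return gid, int(signed)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enrichment_vs_background(foreground, background, categories: pd.Series) -> pd.DataFrame:
    """Per-category Fisher enrichment of foreground probes vs the array rest.

    ``categories`` maps probe_id -> label and must cover the background;
    the 2x2 table per category is (in/out of category) x (foreground /
    background-minus-foreground). The odds ratio is the sample ad/bc with
    a Haldane +0.5 correction only when a zero cell occurs; p is the
    two-sided Fisher exact test, BH-adjusted across categories.
    """
    fg = pd.Index(foreground)
    bg = pd.Index(background)
    if len(fg) == 0:
        raise ValidationError("empty foreground")
    if not fg.isin(bg).all():
        raise ValidationError("foreground must be a subset of the background")
    cats = categories.reindex(bg)
    if cats.isna().any():
        raise ValidationError("categories must cover every background probe")
    rest = bg.difference(fg)
    fg_counts = cats.loc[fg].value_counts()
    rest_counts = cats.loc[rest].value_counts()
    rows = []
    for cat in sorted(cats.unique()):
        a = int(fg_counts.get(cat, 0))            # fg, in category
        b = int(len(fg) - a)                      # fg, out
        c = int(rest_counts.get(cat, 0))          # rest, in
        d = int(len(rest) - c)                    # rest, out
        if len(rest) == 0:
            # foreground IS the background: enrichment is neutral by definition
            rows.append({"category": cat, "odds_ratio": 1.0, "p": 1.0,
                         "fg_fraction": a / len(fg), "bg_fraction": a / len(bg)})
            continue
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"category": cat, "odds_ratio": orr, "p": p,
                     "fg_fraction": a / len(fg),
                     "bg_fraction": (a + c) / len(bg)})
    out = pd.DataFrame(rows).set_index("category")
    out["fdr"] = adjust_bh(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

def metagene_profile(
    signal: pd.Series,
    probes: pd.DataFrame,
    annotation: GenomeAnnotation,
    flank: int = 2000,
    body_bins: int = 20,
    flank_bins: int = 5,
    gene_sets: tuple = ("up", "down", "housekeeping"),
) -> dict:
    """Scaled gene-body profiles of a per-probe signal, per gene set.

    Each gene body is scaled to ``body_bins`` equal fractions TSS -> TES in
    gene orientation (minus-strand genes flipped); flanks are fixed-width
    bins. Returns ``{gene_set: DataFrame(bin, mean, count)}`` with bins
    ordered upstream-flank, body, downstream-flank. Bin means ignore
    missing signal; counts tally (gene, probe) assignments.
    """
    total_bins = 2 * flank_bins + body_bins
    sums = {gs: np.zeros(total_bins) for gs in gene_sets}
    counts = {gs: np.zeros(total_bins, dtype=int) for gs in gene_sets}
    assigned = {gs: np.zeros(total_bins, dtype=int) for gs in gene_sets}
    bin_width = flank / flank_bins

    for gid, row in annotation.genes.iterrows():
        gs = annotation.gene_sets.get(gid, "none")
        if gs not in sums:
            continue
        length = row["end"] - row["start"]
        if length <= 0:
            warnings.warn(f"gene {gid} has zero length; skipped")
            continue
        chrom_probes = probes[probes["chrom"] == row["chrom"]]
        lo, hi = row["start"] - flank, row["end"] + flank
        window = chrom_probes[(chrom_probes["pos"] >= lo) & (chrom_probes["pos"] < hi)]
        for pid, probe in window.iterrows():
            if row["strand"] == "+":
                rel = probe["pos"] - row["start"]
            else:
                rel = row["end"] - 1 - probe["pos"]
            if rel < 0:
                b = flank_bins + int(np.floor(rel / bin_width))  # upstream flank
                b = max(b, 0)
            elif rel >= length:
                b = flank_bins + body_bins + int((rel - length) // bin_width)
                b = min(b, total_bins - 1)
            else:
                b = flank_bins + int(rel * body_bins // length)
            assigned[gs][b] += 1
            val = signal.get(pid, np.nan)
            if not np.isnan(val):
                sums[gs][b] += val
                counts[gs][b] += 1

    profiles = {}
    for gs in gene_sets:
        with np.errstate(invalid="ignore"):
            mean = np.where(counts[gs] > 0, sums[gs] / np.maximum(counts[gs], 1), np.nan)
        profiles[gs] = pd.DataFrame({
            "bin": np.arange(total_bins),
            "mean": mean,
            "count": counts[gs],
            "n_assigned": assigned[gs],
        }).set_index("bin")
    return profiles


# ---------------------------------------------------------------------------
# gene-body summaries
# ---------------------------------------------------------------------------

def gene_body_probes(probes: pd.DataFrame, annotation: GenomeAnnotation,
                     context: pd.DataFrame | None = None) -> pd.Series:
    """Map gene-body probes (feature exon/intron) to their owning gene."""
    if context is None:
        context = annotate_positions(probes, annotation)
    body = context[context["feature"].isin(["exon", "intron"])]
    gene = pd.Series("", index=body.index, dtype=object)
    for gid, row in annotation.genes.iterrows():
        mask = ((probes.loc[body.index, "chrom"] == row["chrom"])
                & (probes.loc[body.index, "pos"] >= row["start"])
                & (probes.loc[body.index, "pos"] < row["end"]))
        gene[mask.index[mask]] = gid
    return gene[gene != ""]


def gene_body_summary(estimate, annotation: GenomeAnnotation,
                      context: pd.DataFrame | None = None) -> tuple:
    """Per-condition gene-body means of 5mC and 5hmC, plus Wilcoxon tests.

    Means (reported as percent) are over defined (non-NA) gene-body cells
    of the MLE matrices; per-condition NA fractions accompany them.
    Pairwise condition comparisons use the rank-sum test on per-gene body
    means of 5hmC (and 5mC), mirroring unpaired condition comparisons of
    averages.

    Returns ``(summary, tests)`` DataFrames.
    """
    body_gene = gene_body_probes(estimate.probes, annotation, context=context)
    if body_gene.empty:
        raise ValidationError("no gene-body probes; summary undefined")
    conds = estimate.pairs["condition"].unique()
    summary_rows, per_gene = [], {}
    for cond in conds:
        cols = estimate.pairs.index[estimate.pairs["condition"] == cond]
        h_cells = estimate.h_hat.loc[body_gene.index, cols]
        m_cells = estimate.m_hat.loc[body_gene.index, cols]
        n_defined = int(h_cells.notna().sum().sum())
        summary_rows.append({
            "condition": cond,
            "mean_h_pct": float(h_cells.stack().mean() * 100) if n_defined else np.nan,
            "mean_m_pct": float(m_cells.stack().mean() * 100),
            "n_h_cells": n_defined,
            "na_fraction": float(h_cells.isna().to_numpy().mean()),
            "undefined": n_defined == 0,
        })
        gene_h = h_cells.mean(axis=1).groupby(body_gene).mean()
        gene_m = m_cells.mean(axis=1).groupby(body_gene).mean()
        per_gene[cond] = (gene_h, gene_m)
    summary = pd.DataFrame(summary_rows).set_index("condition")

    tests = []
    conds = list(conds)
    for i, ca in enumerate(conds):
        for cb in conds[i + 1:]:
            for name, k in (("h", 0), ("m", 1)):
                va = per_gene[ca][k].dropna()
                vb = per_gene[cb][k].dropna()
                u, p = compare_groups_wilcoxon(va, vb)
                tests.append({"contrast": f"{ca}_vs_{cb}", "signal": name,
                              "U": u, "p": p})
    return summary, pd.DataFrame(tests)


# ---------------------------------------------------------------------------
# gene-set overlap
# ---------------------------------------------------------------------------

def overlap_hypergeometric(set_a, set_b, universe) -> dict:
    """Hypergeometric over-representation of the overlap of two gene sets.

    Returns overlap size k, its expectation |A||B|/|U|, the fold
    enrichment and the exact upper-tail p = P[X >= k] with
    X ~ Hypergeometric(|U|, |A|, |B|).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    a, b = set(set_a), set(set_b)
    if not (a <= universe and b <= universe):
        raise ValidationError("sets must be subsets of the universe")
    k = len(a & b)
    expected = len(a) * len(b) / len(universe)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))
    return {
        "overlap": k,
        "expected": expected,
        "fold": k / expected if expected > 0 else np.nan,
        "p": p,
    }
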