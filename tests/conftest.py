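import numpy as np
import pandas as pd
import pytest

import oxbspipe as ox
from oxbspipe.datamodel import BetaMatrix


@pytest.fixture(scope="session")
def default_dataset():
    """The default simulated experiment (seed 1): study-condition profiles."""
    return ox.simulate_dataset(ox.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_bundle():
    """Full pipeline bundle on the default simulation (seed 1)."""
    return ox.run_pipeline(ox.PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def tiny_annotation():
    """Two hand-built genes (one per strand) with CGI and chromatin states."""
    genes = pd.DataFrame({
        "chrom": ["chr1", "chr1"],
        "start": [10_000, 50_000],
        "end": [20_000, 60_000],
        "strand": ["+", "-"],
        "tss": [10_000, 60_000],
    }, index=pd.Index(["geneA", "geneB"], name="gene_id"))
    exons = {
        "geneA": [(10_000, 12_000), (15_000, 17_000), (19_000, 20_000)],
        "geneB": [(50_000, 52_000), (58_000, 60_000)],
    }
    cgis = pd.DataFrame({"chrom": ["chr1"], "start": [9_500], "end": [10_500]})
    states = pd.DataFrame({
        "chrom": ["chr1"] * 3,
        "start": [0, 10_500, 20_000],
        "end": [10_500, 20_000, 100_000],
        "state": ["Promoter", "Txn Elongation", "Heterochromatin"],
    })
    gene_sets = pd.Series({"geneA": "up", "geneB": "down"}, name="gene_set")
    return ox.GenomeAnnotation(chrom_sizes={"chr1": 100_000}, genes=genes, exons=exons,
                               cgis=cgis, chrom_states=states, gene_sets=gene_sets)


def make_beta_matrix(beta, channel="BS", detection_p=None, coverage=1000.0, positions=None):
    """Convenience constructor for small hand-written matrices."""
    beta = pd.DataFrame(beta)
    beta.index = [f"cg{i + 1:06d}" for i in range(len(beta))] if beta.index.dtype != object else beta.index
    if detection_p is None:
        detection_p = pd.DataFrame(0.0, index=beta.index, columns=beta.columns)
    else:
        detection_p = pd.DataFrame(detection_p)
        detection_p.index, detection_p.columns = beta.index, beta.columns
    cov = pd.DataFrame(float(coverage), index=beta.index, columns=beta.columns)
    pos = positions if positions is not None else np.arange(len(beta)) * 1000 + 500
    probes = pd.DataFrame({"chrom": "chr1", "pos": pos}, index=beta.index)
    return BetaMatrix(beta=beta, detection_p=detection_p, coverage=cov,
                      probes=probes, channel=channel)


def paired_sheet(n_cultures, condition="cond"):
    rows = []
    for c in range(1, n_cultures + 1):
        for channel in ("BS", "oxBS"):
            rows.append({"sample_id": f"{condition}_c{c}_{channel}", "culture": f"c{c}",
                         "condition": condition, "channel": channel})
    return pd.DataFrame(rows)
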