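"""Closed-form bench-assay computations.

Three small calculators used around the array pipeline: relative qPCR
expression by the delta-delta-Ct method, hydroxymethyl-DNA
immunoprecipitation enrichment as percent of input, and the SAM/SAH
methylation index. Amplification efficiency is fixed at 2 in both Ct
formulas.
"""
from __future__ import annotations

import math

import numpy as np

from .datamodel import ValidationError

#: printed compensatory factor for a 1:10 input dilution (log2(10) ~ 3.3219)
DEFAULT_DILUTION_FACTOR = 3.32


def dilution_factor(dilution: float) -> float:
    """Ct compensation for an input diluted 1:dilution, log2(dilution).

    ``dilution_factor(10)`` is 3.3219..., conventionally printed as 3.32.
    """
    if dilution <= 0:
        raise ValidationError("dilution must be positive")
    return math.log2(dilution)


def relative_expression_ddct(ct_gene, ct_housekeeping, control_mean_dct: float) -> float:
    """Relative expression 2^-(ddCt).

    dCt = mean(Ct of the evaluated gene) - mean(Ct of the housekeeping
    gene); ddCt = dCt - mean dCt of the control condition; the returned
    fold change is 2^-ddCt (1.0 when the sample sits at the control mean).
    """
    gene = np.atleast_1d(np.asarray(ct_gene, dtype=float))
    house = np.atleast_1d(np.asarray(ct_housekeeping, dtype=float))
    if gene.size == 0 or house.size == 0:
        raise ValidationError("Ct replicate lists must be non-empty")
    if not (np.isfinite(gene).all() and np.isfinite(house).all() and np.isfinite(control_mean_dct)):
        raise ValidationError("Ct values must be finite")
    dct = gene.mean() - house.mean()
    ddct = dct - control_mean_dct
    return float(2.0 ** (-ddct))


def hmedip_percent_input(ct_ip: float, ct_input10: float,
                         dilution_factor: float = DEFAULT_DILUTION_FACTOR) -> float:
    """hMeDIP enrichment as percent of total input.

    percent = 2^((Ct_input10 - dilution_factor) - Ct_ip) * 100, where the
    default compensatory factor 3.32 accounts for the 1:10 dilution of the
    input (``ct_ip == ct_input10`` therefore recovers ~10%).
    """
    if not (np.isfinite(ct_ip) and np.isfinite(ct_input10)):
        raise ValidationError("Ct values must be finite")
    return float(2.0 ** ((ct_input10 - dilution_factor) - ct_ip) * 100.0)


def methylation_index(sam: float, sah: float) -> float:
    """Methylation index: the SAM/SAH concentration ratio."""
    if sam < 0 or sah < 0:
        raise ValidationError("concentrations must be non-negative")
    if sah == 0:
        raise ValidationError("methylation index undefined for SAH = 0")
    return float(sam / sah)
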