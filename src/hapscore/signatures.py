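"""Formula-defined expression-signature scores and packaged gene lists."""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .errors import DataError

#: MHC class I antigen presentation machinery signature.
MHC_I_SIGNATURE = (
    "B2M", "TAP1", "TAP2", "TAPBP", "HLA-A", "HLA-B", "HLA-C", "HLA-E",
    "HLA-F", "HLA-G",
)

#: MHC class II signature.
MHC_II_SIGNATURE = (
    "HLA-DMA", "HLA-DMB", "HLA-DOA", "HLA-DOB", "HLA-DPA1", "HLA-DPA2",
    "HLA-DPA3", "HLA-DPB1", "HLA-DPB2", "HLA-DQA1", "HLA-DQA2", "HLA-DQB1",
    "HLA-DQB2", "HLA-DRA", "HLA-DRB1", "HLA-DRB2", "HLA-DRB3", "HLA-DRB4",
    "HLA-DRB5", "HLA-DRB6", "HLA-DRB7", "HLA-DRB8", "HLA-DRB9",
)


def cyt_score(expr: Mapping[str, float], pseudocount: float = 0.0) -> float:
    """Cytolytic activity: geometric mean of GZMA and PRF1 expression.

    Expression values are unit-agnostic (TPM, FPKM, normalized counts);
    both genes must be present and non-negative. ``pseudocount`` is added
    to both genes before the geometric mean for zero-inflated data
    (default 0, i.e. either gene at 0 gives CYT = 0).
    """
    for gene in ("GZMA", "PRF1"):
        if gene not in expr:
            raise DataError(f"expression value for {gene} missing")
        v = expr[gene]
        if not (np.isfinite(v) and v >= 0):
            raise DataError(f"{gene} expression must be finite and >= 0, got {v}")
    if pseudocount < 0:
        raise DataError(f"pseudocount must be >= 0, got {pseudocount}")
    return math.sqrt((expr["GZMA"] + pseudocount) * (expr["PRF1"] + pseudocount))
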