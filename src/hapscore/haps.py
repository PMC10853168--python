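"""The HLA tumor-Antigen Presentation Score (HAPS).

HAPS combines, per class I locus i in {A, B, C}, the divergence between
the patient's paired alleles with the neoantigen burden presented by that
locus:

    HAPS = mean_i [ HED_i * log10(TNB_i + 1) ]

A homozygous locus (divergence 0) or a locus presenting no neoantigens
contributes 0. Patients are classified high/low against a cutoff chosen by
hazard-ratio scanning on ICI-treated cohorts: 10 for whole-exome derived
scores, 1.31 for targeted-panel derived scores.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .grantham import DivergenceProfile
from .neoantigen import TNBProfile

WES_CUTOFF = 10.0
PANEL_CUTOFF = 1.31

_MODE_CUTOFFS = {"wes": WES_CUTOFF, "panel": PANEL_CUTOFF}


@dataclass(frozen=True)
class HAPSResult:
    patient_id: str
    term_a: float
    term_b: float
    term_c: float
    haps: float
    haps_class: str | None = None  # "high" | "low"
    cutoff: float | None = None

    def terms(self) -> tuple[float, float, float]:
        return (self.term_a, self.term_b, self.term_c)


def compute_haps(d: DivergenceProfile, t: TNBProfile) -> HAPSResult:
    """Combine a divergence profile and a TNB profile into a HAPS result.

    The two profiles must describe the same patient. The class is left
    unset; see :func:`classify_haps`.
    """
    if d.patient_id != t.patient_id:
        raise DataError(
            f"patient id mismatch: divergence for {d.patient_id!r}, "
            f"TNB for {t.patient_id!r}"
        )
    hed = d.per_locus()
    tnb = t.per_locus()
    terms = {locus: hed[locus] * math.log10(tnb[locus] + 1) for locus in hed}
    haps = sum(terms.values()) / 3.0
    return HAPSResult(
        patient_id=d.patient_id,
        term_a=terms["A"],
        term_b=terms["B"],
        term_c=terms["C"],
        haps=haps,
    )


def classify_haps(
    h: HAPSResult, cutoff: float | None = None, mode: str = "wes"
) -> HAPSResult:
    """Attach a high/low class to a HAPS result.

    ``high`` includes the boundary (haps >= cutoff). The default cutoff is
    selected by ``mode`` ("wes" -> 10, "panel" -> 1.31); an explicit numeric
    cutoff overrides the mode.
    """
    if cutoff is None:
        try:
            cutoff = _MODE_CUTOFFS[mode]
        except KeyError:
            raise DataError(f"mode must be 'wes' or 'panel', got {mode!r}") from None
    if not np.isfinite(cutoff):
        raise DataError(f"cutoff must be finite, got {cutoff}")
    label = "high" if h.haps >= cutoff else "low"
    return dataclasses.replace(h, haps_class=label, cutoff=float(cutoff))
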