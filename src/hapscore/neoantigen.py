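"""Neoantigen filtering, per-locus burden, quality, and mutational burden.

A candidate mutant peptide is called a neoantigen when its predicted MHC-I
binding is stronger than the moderate-affinity threshold: IC50 < 500 nM, or
alternatively percentile rank < 1%. Tumor neoantigen burden (TNB) is
counted per HLA locus: by default a mutant peptide counts once per locus
even when both alleles of the locus are predicted to present it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError
from .hla import CLASS_I_LOCI, HLAGenotype, parse_allele_name

IC50_THRESHOLD_NM = 500.0
RANK_THRESHOLD_PCT = 1.0

_VALID_MODES = ("ic50", "rank")


@dataclass(frozen=True)
class BindingRecord:
    """One MHC-I binding prediction for a mutant peptide / allele pair."""

    patient_id: str
    peptide: str
    allele: str
    ic50: float | None = None
    rank_pct: float | None = None
    wt_peptide: str | None = None

    def __post_init__(self) -> None:
        if not self.peptide:
            raise DataError(f"patient {self.patient_id}: empty peptide")
        if self.ic50 is None and self.rank_pct is None:
            raise DataError(
                f"patient {self.patient_id}, peptide {self.peptide}: neither "
                "ic50 nor rank_pct present"
            )
        if self.ic50 is not None and not self.ic50 > 0:
            raise DataError(
                f"patient {self.patient_id}, peptide {self.peptide}: "
                f"ic50 must be > 0 nM, got {self.ic50}"
            )
        if self.rank_pct is not None and not 0 < self.rank_pct <= 100:
            raise DataError(
                f"patient {self.patient_id}, peptide {self.peptide}: "
                f"rank_pct must be in (0, 100], got {self.rank_pct}"
            )
        # normalize the allele name once, up front
        object.__setattr__(self, "allele", parse_allele_name(self.allele)[1])


def filter_binders(
    records: Sequence[BindingRecord],
    mode: str = "ic50",
    threshold: float | None = None,
) -> list[BindingRecord]:
    """Keep records predicted to bind more strongly than ``threshold``.

    Strict inequality on both scales: ``ic50 < threshold`` (default 500 nM)
    or ``rank_pct < threshold`` (default 1.0%). Input order is preserved and
    the input list is not modified.
    """
    if mode not in _VALID_MODES:
        raise DataError(f"mode must be one of {_VALID_MODES}, got {mode!r}")
    if threshold is None:
        threshold = IC50_THRESHOLD_NM if mode == "ic50" else RANK_THRESHOLD_PCT
    kept = []
    for i, rec in enumerate(records):
        value = rec.ic50 if mode == "ic50" else rec.rank_pct
        if value is None:
            raise DataError(f"record {i} is missing the {mode} field")
        if value < threshold:
            kept.append(rec)
    return kept


@dataclass(frozen=True)
class TNBProfile:
    """Per-locus neoantigen counts of one patient."""

    patient_id: str
    tnb_a: int
    tnb_b: int
    tnb_c: int
    tnb_total: int

    def __post_init__(self) -> None:
        for name in ("tnb_a", "tnb_b", "tnb_c", "tnb_total"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DataError(f"patient {self.patient_id}: {name}={v!r} invalid")

    def per_locus(self) -> dict[str, int]:
        return dict(zip(CLASS_I_LOCI, (self.tnb_a, self.tnb_b, self.tnb_c)))


def tnb_per_locus(
    binders: Iterable[BindingRecord],
    genotype: HLAGenotype,
    dedup: str = "peptide",
) -> TNBProfile:
    """Count neoantigens per HLA locus for one patient.

    ``dedup="peptide"`` (default): a mutant peptide counts once per locus
    regardless of how many alleles of that locus present it; ``tnb_total``
    is the number of distinct neoantigenic peptides across loci.
    ``dedup="pairs"`` counts peptide-allele pairs instead (sensitivity
    analysis mode).
    """
    if dedup not in ("peptide", "pairs"):
        raise DataError(f"dedup must be 'peptide' or 'pairs', got {dedup!r}")
    patient_alleles = {a: locus for locus in CLASS_I_LOCI
                      for a in genotype.pair(locus)}
    per_locus_items: dict[str, set] = {locus: set() for locus in CLASS_I_LOCI}
    all_peptides: set[str] = set()
    for rec in binders:
        if rec.patient_id != genotype.patient_id:
            raise DataError(
                f"record for patient {rec.patient_id} passed with genotype of "
                f"{genotype.patient_id}"
            )
        locus = patient_alleles.get(rec.allele)
        if locus is None:
            raise DataError(
                f"patient {genotype.patient_id}: allele {rec.allele} of a "
                "binding record is absent from the genotype"
            )
        key = rec.peptide if dedup == "peptide" else (rec.peptide, rec.allele)
        per_locus_items[locus].add(key)
        all_peptides.add(rec.peptide)
    counts = {locus: len(items) for locus, items in per_locus_items.items()}
    total = len(all_peptides) if dedup == "peptide" else sum(counts.values())
    return TNBProfile(
        patient_id=genotype.patient_id,
        tnb_a=counts["A"],
        tnb_b=counts["B"],
        tnb_c=counts["C"],
        tnb_total=total,
    )


@dataclass(frozen=True)
class NeoantigenQualityInput:
    """Inputs of the neoantigen quality (self-discrimination) model.

    kd_* are MHC dissociation constants (nM) of the wild-type and mutant
    peptide; ec50_* are the TCR cross-reactivity half-max quantities (any
    consistent unit); w in [0, 1] weights the cross-reactivity term.
    """

    kd_wt: float
    kd_mt: float
    ec50_wt: float
    ec50_mt: float
    w: float = 0.5

    def __post_init__(self) -> None:
        for name in ("kd_wt", "kd_mt", "ec50_wt", "ec50_mt"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise DataError(f"{name} must be positive and finite, got {v}")
        if not 0 <= self.w <= 1:
            raise DataError(f"w must be in [0, 1], got {self.w}")


def neoantigen_quality(q: NeoantigenQualityInput, log_base: float = math.e) -> float:
    """Self-discrimination score D of a mutant peptide against its wild type.

    D = (1 - w) * log(kd_wt / kd_mt) + w * log(ec50_mt / ec50_wt)

    The first term rewards stronger MHC presentation of the mutant than the
    wild type; the second rewards TCR cross-reactivity distance. Natural log
    by default (``log_base`` configurable).
    """
    if not log_base > 1:
        raise DataError(f"log_base must be > 1, got {log_base}")
    ln = math.log(log_base)
    d = (1 - q.w) * math.log(q.kd_wt / q.kd_mt) + q.w * math.log(q.ec50_mt / q.ec50_wt)
    return d / ln


@dataclass(frozen=True)
class MutationSummary:
    """Nonsynonymous mutation count over a sequenced coding footprint."""

    patient_id: str
    n_nonsynonymous: int
    region_size_mb: float

    def __post_init__(self) -> None:
        if self.n_nonsynonymous < 0:
            raise DataError(
                f"patient {self.patient_id}: negative mutation count"
            )
        if not self.region_size_mb > 0:
            raise DataError(
                f"patient {self.patient_id}: region_size_mb must be > 0, "
                f"got {self.region_size_mb}"
            )


def tmb(m: MutationSummary) -> float:
    """Tumor mutational burden: nonsynonymous mutations per Mb of coding region."""
    return m.n_nonsynonymous / m.region_size_mb
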