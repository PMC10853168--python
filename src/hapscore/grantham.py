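"""Grantham distance and HLA-I evolutionary divergence.

The Grantham distance between two amino acids combines three
physicochemical properties — composition ``c`` (atomic weight ratio of
non-carbon side-chain atoms), polarity ``p`` and molecular volume ``v``:

    d(i, j) = rho * [alpha*(c_i - c_j)^2 + beta*(p_i - p_j)^2
                     + gamma*(v_i - v_j)^2]^(1/2)

with property weights alpha = 1.833, beta = 0.1018, gamma = 0.000399 and
``rho`` a scaling factor normalizing the mean of the 190 inter-residue
distances to 100. Under that normalization the most conservative exchange
(Leu/Ile) scores 5 and the most radical (Cys/Trp) scores 215.

The divergence between two aligned allele sequences (HED in the HLA
literature) is the mean per-site Grantham distance over alignment columns
where neither sequence carries a gap; a homozygous locus therefore has
divergence exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .hla import CLASS_I_LOCI, GAP, STANDARD_RESIDUES, AlleleSequenceStore, HLAGenotype

#: Grantham (1974) side-chain property values: residue -> (c, p, v).
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.00, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.00, 8.1, 31.0),
    "V": (0.00, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.00, 5.2, 111.0),
    "F": (0.00, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.00, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

ALPHA = 1.833
BETA = 0.1018
GAMMA = 0.000399


@dataclass(frozen=True)
class AminoAcidProperties:
    """Property table plus formula constants for the Grantham distance.

    ``rho=None`` (the default) requests the normalization the metric is
    defined with: rho is computed so the mean off-diagonal distance equals
    exactly 100. A numeric rho bypasses the normalization.
    """

    properties: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(GRANTHAM_PROPERTIES)
    )
    alpha: float = ALPHA
    beta: float = BETA
    gamma: float = GAMMA
    rho: float | None = None

    def __post_init__(self) -> None:
        missing = STANDARD_RESIDUES - set(self.properties)
        if missing:
            raise ConfigurationError(
                f"property table missing residues: {sorted(missing)}"
            )
        for res, cpv in self.properties.items():
            if res not in STANDARD_RESIDUES:
                raise ConfigurationError(f"unknown residue {res!r} in property table")
            if len(cpv) != 3 or not all(np.isfinite(cpv)):
                raise ConfigurationError(f"residue {res}: non-finite c/p/v {cpv}")
        for name, val in (("alpha", self.alpha), ("beta", self.beta),
                          ("gamma", self.gamma)):
            if not (np.isfinite(val) and val > 0):
                raise ConfigurationError(f"{name} must be positive, got {val}")
        if self.rho is not None and not (np.isfinite(self.rho) and self.rho > 0):
            raise ConfigurationError(f"rho must be positive, got {self.rho}")


def build_grantham_matrix(
    props: AminoAcidProperties | None = None, rounded: bool = False
) -> pd.DataFrame:
    """Build the 20x20 symmetric Grantham distance matrix.

    Parameters
    ----------
    props
        Property table and constants; defaults to the published 1974 values.
    rounded
        Round each entry to the nearest integer (the convention of the
        printed 1974 table); internal computation is in floating point.
    """
    props = props or AminoAcidProperties()
    residues = sorted(STANDARD_RESIDUES)
    cpv = np.array([props.properties[r] for r in residues])
    diff = cpv[:, None, :] - cpv[None, :, :]
    weights = np.array([props.alpha, props.beta, props.gamma])
    raw = np.sqrt((weights * diff**2).sum(axis=2))
    if props.rho is None:
        n = len(residues)
        mean_offdiag = raw.sum() / (n * (n - 1))  # symmetric, zero diagonal
        rho = 100.0 / mean_offdiag
    else:
        rho = props.rho
    dist = rho * raw
    if rounded:
        # round half away from zero, matching printed integer tables
        dist = np.floor(dist + 0.5)
    return pd.DataFrame(dist, index=residues, columns=residues)


def sequence_divergence(
    seq_a: str,
    seq_b: str,
    matrix: pd.DataFrame | None = None,
    per_site: bool = True,
) -> float:
    """Grantham divergence between two aligned protein sequences.

    Positions where either sequence has a gap are excluded from both the
    numerator and the denominator. ``per_site=True`` (default, the HED
    convention) divides the summed distance by the number of compared
    positions; ``per_site=False`` returns the raw sum.
    """
    if matrix is None:
        matrix = build_grantham_matrix()
    if len(seq_a) != len(seq_b):
        raise DataError(
            f"aligned sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    total = 0.0
    n_compared = 0
    for x, y in zip(seq_a, seq_b):
        if x == GAP or y == GAP:
            continue
        try:
            total += matrix.at[x, y]
        except KeyError:
            raise DataError(f"non-standard residue pair ({x!r}, {y!r})") from None
        n_compared += 1
    if n_compared == 0:
        raise DataError("no gap-free positions to compare")
    return total / n_compared if per_site else total


@dataclass(frozen=True)
class DivergenceProfile:
    """Per-locus HLA-I divergence of one patient (A, B, C) and their mean."""

    patient_id: str
    hed_a: float
    hed_b: float
    hed_c: float

    def __post_init__(self) -> None:
        for locus, val in zip(CLASS_I_LOCI, (self.hed_a, self.hed_b, self.hed_c)):
            if not np.isfinite(val) or val < 0:
                raise DataError(
                    f"patient {self.patient_id}: HLA-{locus} divergence {val} invalid"
                )

    @property
    def hed_mean(self) -> float:
        return (self.hed_a + self.hed_b + self.hed_c) / 3.0

    def per_locus(self) -> dict[str, float]:
        return dict(zip(CLASS_I_LOCI, (self.hed_a, self.hed_b, self.hed_c)))


def patient_divergence(
    genotype: HLAGenotype,
    store: AlleleSequenceStore,
    matrix: pd.DataFrame | None = None,
    per_site: bool = True,
) -> DivergenceProfile:
    """Per-locus divergence between a patient's paired class I alleles.

    A homozygous locus scores exactly 0 (its allele name must still resolve
    in the store). Unresolvable alleles raise, naming the missing allele.
    """
    if matrix is None:
        matrix = build_grantham_matrix()
    values = {}
    for locus in CLASS_I_LOCI:
        a1, a2 = genotype.pair(locus)
        seq1 = store[a1]  # raises MissingAlleleError naming the allele
        if genotype.is_homozygous(locus):
            values[locus] = 0.0
            continue
        seq2 = store[a2]
        values[locus] = sequence_divergence(seq1, seq2, matrix, per_site=per_site)
    return DivergenceProfile(
        patient_id=genotype.patient_id,
        hed_a=values["A"],
        hed_b=values["B"],
        hed_c=values["C"],
    )
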