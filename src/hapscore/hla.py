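"""HLA class I nomenclature, genotypes, and aligned allele sequence stores.

A patient's class I genotype is a pair of alleles at each of HLA-A, -B and
-C. Allele names are handled at two-field resolution ("A*02:01"); higher
resolution fields are collapsed, since the peptide-binding-domain protein
sequence is determined by the first two fields for the purposes of
divergence scoring.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .errors import DataError, MissingAlleleError

CLASS_I_LOCI = ("A", "B", "C")

#: 20 standard residues, one-letter codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

GAP = "-"

_ALLELE_RE = re.compile(r"^(?:HLA-)?([A-Z]+[0-9]*)\*(\d+):(\d+)(?::\d+)*[A-Z]?$")


def parse_allele_name(raw: str) -> tuple[str, str]:
    """Normalize an HLA class I allele name to ``(locus, "L*gg:pp")``.

    Accepts "HLA-A*02:01", "A*02:01:01", "A*02:01" and collapses to
    two-field resolution. Class II names (e.g. "DRB1*04:01") and anything
    unparseable raise :class:`DataError`.
    """
    if not raw or not isinstance(raw, str):
        raise DataError(f"empty or non-string allele name: {raw!r}")
    m = _ALLELE_RE.match(raw.strip())
    if m is None:
        raise DataError(f"unparseable HLA allele name: {raw!r}")
    locus, g1, g2 = m.groups()
    if locus not in CLASS_I_LOCI:
        raise DataError(
            f"unsupported locus {locus!r} in allele {raw!r}: only classical "
            f"class I loci {CLASS_I_LOCI} are handled"
        )
    return locus, f"{locus}*{g1}:{g2}"


@dataclass(frozen=True)
class HLAGenotype:
    """Six classical class I alleles of one patient.

    ``alleles`` maps locus -> (allele_1, allele_2); names are normalized at
    construction. A locus is homozygous iff its two names are equal.
    """

    patient_id: str
    alleles: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        normalized: dict[str, tuple[str, str]] = {}
        for locus in CLASS_I_LOCI:
            if locus not in self.alleles:
                raise DataError(
                    f"patient {self.patient_id}: locus {locus} missing from genotype"
                )
            pair = self.alleles[locus]
            if len(pair) != 2:
                raise DataError(
                    f"patient {self.patient_id}: locus {locus} needs exactly 2 alleles"
                )
            norm = []
            for name in pair:
                parsed_locus, norm_name = parse_allele_name(name)
                if parsed_locus != locus:
                    raise DataError(
                        f"patient {self.patient_id}: allele {name!r} filed under "
                        f"locus {locus}"
                    )
                norm.append(norm_name)
            normalized[locus] = (norm[0], norm[1])
        object.__setattr__(self, "alleles", normalized)

    def pair(self, locus: str) -> tuple[str, str]:
        return self.alleles[locus]

    def is_homozygous(self, locus: str) -> bool:
        a1, a2 = self.alleles[locus]
        return a1 == a2

    def all_alleles(self) -> Iterator[str]:
        for locus in CLASS_I_LOCI:
            yield from self.alleles[locus]


@dataclass
class AlleleSequenceStore:
    """Aligned binding-domain protein sequences keyed by 2-field allele name.

    All sequences must share one alignment length (181 columns for the
    exon 2/3 peptide-binding domain alignment this package targets, though
    any consistent length is accepted) and contain only the 20 standard
    residues or the gap character "-".
    """

    sequences: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized: dict[str, str] = {}
        length: int | None = None
        for name, seq in self.sequences.items():
            _, norm = parse_allele_name(name)
            seq = seq.strip().upper()
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise DataError(
                    f"allele {name}: sequence length {len(seq)} != alignment "
                    f"length {length}"
                )
            bad = set(seq) - STANDARD_RESIDUES - {GAP}
            if bad:
                raise DataError(
                    f"allele {name}: non-standard characters {sorted(bad)}"
                )
            if norm in normalized and normalized[norm] != seq:
                raise DataError(f"allele {norm}: conflicting sequences supplied")
            normalized[norm] = seq
        self.sequences = normalized
        self._length = length

    @property
    def alignment_length(self) -> int:
        if self._length is None:
            raise DataError("empty allele sequence store")
        return self._length

    def __contains__(self, name: str) -> bool:
        try:
            _, norm = parse_allele_name(name)
        except DataError:
            return False
        return norm in self.sequences

    def __getitem__(self, name: str) -> str:
        _, norm = parse_allele_name(name)
        try:
            return self.sequences[norm]
        except KeyError:
            raise MissingAlleleError(
                f"allele {norm} not present in the sequence store "
                f"({len(self.sequences)} alleles loaded)"
            ) from None

    def __len__(self) -> int:
        return len(self.sequences)
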