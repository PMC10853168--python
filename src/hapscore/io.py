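"""Readers and writers for the tabular and FASTA formats the pipeline uses.

Canonical dialect: tab-separated, one header row, UTF-8, "." for missing
values. Readers validate column presence and types and reject malformed
rows with their line numbers instead of silently dropping them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .errors import DataError
from .hla import AlleleSequenceStore, HLAGenotype, parse_allele_name  # noqa: F401
from .neoantigen import BindingRecord, MutationSummary
from .survival import SurvivalRecord
from .tcr import Clone, TCRRepertoire

MISSING = "."


def _read_tsv(path, required: Sequence[str], numeric: Sequence[str] = ()):
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file does not exist: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                         na_values=[MISSING, ""], keep_default_na=False)
    except pd.errors.ParserError as err:
        raise DataError(f"{path.name}: malformed TSV ({err})") from err
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path.name}: missing columns {missing}")
    for col in numeric:
        if col not in df.columns:
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as err:
            raise DataError(f"{path.name}: column {col} not numeric ({err})") from err
    return df


def _require_values(df: pd.DataFrame, path, cols: Sequence[str]) -> None:
    for col in cols:
        bad = df.index[df[col].isna()]
        if len(bad):
            # +2: header line and 1-based numbering
            lines = [int(i) + 2 for i in bad[:5]]
            raise DataError(
                f"{Path(path).name}: column {col} empty at line(s) {lines}"
            )


def read_allele_fasta(path) -> AlleleSequenceStore:
    """Aligned allele FASTA: header = allele name, gap character '-'."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file does not exist: {path}")
    sequences = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sequences[rec.id] = str(rec.seq)
    if not sequences:
        raise DataError(f"{path.name}: no FASTA records found")
    return AlleleSequenceStore(sequences)


def read_genotypes(path) -> list[HLAGenotype]:
    cols = ["patient_id", "A1", "A2", "B1", "B2", "C1", "C2"]
    df = _read_tsv(path, required=cols)
    _require_values(df, path, cols)
    genotypes = []
    for row in df.itertuples(index=False):
        genotypes.append(HLAGenotype(
            patient_id=row.patient_id,
            alleles={
                "A": (row.A1, row.A2),
                "B": (row.B1, row.B2),
                "C": (row.C1, row.C2),
            },
        ))
    return genotypes


def read_binding_table(path) -> list[BindingRecord]:
    """NetMHCpan-style binding table.

    Requires patient_id, peptide, allele and at least one of ic50_nm /
    rank_pct per row; comment lines starting with '#' are skipped.
    """
    df = _read_tsv(path, required=["patient_id", "peptide", "allele"],
                   numeric=["ic50_nm", "rank_pct"])
    _require_values(df, path, ["patient_id", "peptide", "allele"])
    if "ic50_nm" not in df.columns and "rank_pct" not in df.columns:
        raise DataError(
            f"{Path(path).name}: need at least one of ic50_nm / rank_pct"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        ic50 = getattr(row, "ic50_nm", None)
        rank = getattr(row, "rank_pct", None)
        wt = getattr(row, "wt_peptide", None)
        try:
            records.append(BindingRecord(
                patient_id=row.patient_id,
                peptide=row.peptide,
                allele=row.allele,
                ic50=None if pd.isna(ic50) else float(ic50),
                rank_pct=None if pd.isna(rank) else float(rank),
                wt_peptide=None if (wt is None or pd.isna(wt)) else str(wt),
            ))
        except DataError as err:
            raise DataError(f"{Path(path).name}, line {i + 2}: {err}") from err
    return records


def read_mutations(path) -> list[MutationSummary]:
    df = _read_tsv(path, required=["patient_id", "n_nonsynonymous",
                                   "region_size_mb"],
                   numeric=["n_nonsynonymous", "region_size_mb"])
    _require_values(df, path, ["patient_id", "n_nonsynonymous", "region_size_mb"])
    return [
        MutationSummary(
            patient_id=row.patient_id,
            n_nonsynonymous=int(row.n_nonsynonymous),
            region_size_mb=float(row.region_size_mb),
        )
        for row in df.itertuples(index=False)
    ]


CLINICAL_NUMERIC = ["os_months", "os_event", "pfs_months", "pfs_event",
                    "age", "pdl1_pct", "tmb"]


def read_clinical(path) -> pd.DataFrame:
    df = _read_tsv(path, required=["patient_id", "os_months", "os_event"],
                   numeric=[c for c in CLINICAL_NUMERIC])
    _require_values(df, path, ["patient_id", "os_months", "os_event"])
    return df


def clinical_survival_records(
    df: pd.DataFrame, endpoint: str = "os"
) -> list[SurvivalRecord]:
    """Turn a clinical table into survival records for OS or PFS."""
    if endpoint not in ("os", "pfs"):
        raise DataError(f"endpoint must be 'os' or 'pfs', got {endpoint!r}")
    tcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
    if tcol not in df.columns or ecol not in df.columns:
        raise DataError(f"clinical table lacks {tcol}/{ecol}")
    sub = df.dropna(subset=[tcol, ecol])
    return [
        SurvivalRecord(patient_id=row.patient_id,
                       time=float(getattr(row, tcol)),
                       event=int(getattr(row, ecol)))
        for row in sub.itertuples(index=False)
    ]


def read_loh(path) -> pd.DataFrame:
    df = _read_tsv(path, required=["patient_id", "locus", "minor_cn",
                                   "p_allelic_imbalance"],
                   numeric=["minor_cn", "p_allelic_imbalance"])
    _require_values(df, path, ["patient_id", "locus", "minor_cn",
                               "p_allelic_imbalance"])
    return df


def read_clones(path) -> dict[tuple[str, str], TCRRepertoire]:
    """Clone table with patient_id, timepoint, cdr3_aa, count columns.

    Extra columns (V/J calls etc.) are ignored. Returns repertoires keyed
    by (patient_id, timepoint).
    """
    df = _read_tsv(path, required=["patient_id", "timepoint", "cdr3_aa",
                                   "count"],
                   numeric=["count"])
    _require_values(df, path, ["patient_id", "timepoint", "cdr3_aa", "count"])
    reps: dict[tuple[str, str], TCRRepertoire] = {}
    for (pid, tp), grp in df.groupby(["patient_id", "timepoint"], sort=True):
        clones = [Clone(row.cdr3_aa, int(row.count))
                  for row in grp.itertuples(index=False)]
        reps[(pid, tp)] = TCRRepertoire(patient_id=pid, timepoint=tp,
                                        clones=clones)
    return reps


def read_features(path) -> pd.DataFrame:
    df = _read_tsv(path, required=["patient_id", "haps", "tmb",
                                   "tcr_diversity"],
                   numeric=["haps", "tmb", "tcr_diversity"])
    _require_values(df, path, ["patient_id", "haps", "tmb", "tcr_diversity"])
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a result table in the canonical TSV dialect (deterministic)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep=MISSING)
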