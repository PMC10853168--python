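"""End-to-end per-patient scoring pipeline over a bundle of input files.

Stages: allele divergence -> neoantigen filtering and per-locus burden ->
HAPS + classification, then optionally LOH stratification, TCR repertoire
metrics and neural-network scoring when the corresponding inputs are
present. Produces one row per patient; stage timings and record counts are
logged to standard error.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as hio
from . import grantham, haps as haps_mod, neoantigen, nn, survival, tcr
from .errors import DataError

log = logging.getLogger("hapscore")


@dataclass
class RunConfig:
    """File paths, thresholds and mode of one pipeline run."""

    alleles_fasta: str
    genotypes_tsv: str
    binding_tsv: str
    mode: str = "wes"  # selects the default HAPS cutoff
    haps_cutoff: float | None = None
    binder_mode: str = "ic50"  # "ic50" | "rank"
    binder_threshold: float | None = None
    tnb_dedup: str = "peptide"
    mutations_tsv: str | None = None
    clinical_tsv: str | None = None
    loh_tsv: str | None = None
    clones_tsv: str | None = None
    nn_model_json: str | None = None
    loh_rule: str = "cn_and_p"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("wes", "panel"):
            raise DataError(f"mode must be 'wes' or 'panel', got {self.mode!r}")


def _stage(name: str, t0: float, n: int) -> None:
    log.info("stage %-12s %6.2fs  %d records", name, time.perf_counter() - t0, n)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run the scoring pipeline, returning one row per patient."""
    t0 = time.perf_counter()
    store = hio.read_allele_fasta(config.alleles_fasta)
    genotypes = hio.read_genotypes(config.genotypes_tsv)
    if not genotypes:
        raise DataError("genotype table is empty")
    pids = [g.patient_id for g in genotypes]
    dup = {p for p in pids if pids.count(p) > 1}
    if dup:
        raise DataError(f"duplicate genotype rows for patients: {sorted(dup)}")
    _stage("inputs", t0, len(genotypes))

    t0 = time.perf_counter()
    matrix = grantham.build_grantham_matrix()
    divergences = {
        g.patient_id: grantham.patient_divergence(g, store, matrix)
        for g in genotypes
    }
    _stage("divergence", t0, len(divergences))

    t0 = time.perf_counter()
    records = hio.read_binding_table(config.binding_tsv)
    by_patient: dict[str, list] = {p: [] for p in pids}
    unknown = sorted({r.patient_id for r in records} - set(pids))
    if unknown:
        raise DataError(
            f"binding table names patients absent from the genotype table: "
            f"{unknown}"
        )
    for r in records:
        by_patient[r.patient_id].append(r)
    binders = {
        p: neoantigen.filter_binders(by_patient[p], mode=config.binder_mode,
                                     threshold=config.binder_threshold)
        for p in pids
    }
    geno_by_pid = {g.patient_id: g for g in genotypes}
    tnbs = {
        p: neoantigen.tnb_per_locus(binders[p], geno_by_pid[p],
                                    dedup=config.tnb_dedup)
        for p in pids
    }
    _stage("tnb", t0, len(records))

    t0 = time.perf_counter()
    rows = []
    for p in pids:
        d, t = divergences[p], tnbs[p]
        res = haps_mod.classify_haps(
            haps_mod.compute_haps(d, t),
            cutoff=config.haps_cutoff, mode=config.mode,
        )
        rows.append({
            "patient_id": p,
            "hed_A": d.hed_a, "hed_B": d.hed_b, "hed_C": d.hed_c,
            "tnb_A": t.tnb_a, "tnb_B": t.tnb_b, "tnb_C": t.tnb_c,
            "term_A": res.term_a, "term_B": res.term_b, "term_C": res.term_c,
            "haps": res.haps, "haps_class": res.haps_class,
            "cutoff": res.cutoff,
        })
    out = pd.DataFrame(rows)
    _stage("haps", t0, len(out))

    if config.mutations_tsv:
        t0 = time.perf_counter()
        muts = hio.read_mutations(config.mutations_tsv)
        tmb_map = {m.patient_id: neoantigen.tmb(m) for m in muts}
        missing = [p for p in pids if p not in tmb_map]
        if missing:
            raise DataError(f"mutation table missing patients: {missing}")
        out["tmb"] = out["patient_id"].map(tmb_map)
        _stage("tmb", t0, len(muts))

    if config.loh_tsv:
        t0 = time.perf_counter()
        loh_df = hio.read_loh(config.loh_tsv)
        statuses = {}
        for pid, grp in loh_df.groupby("patient_id"):
            cn = dict(zip(grp["locus"], grp["minor_cn"]))
            pv = dict(zip(grp["locus"], grp["p_allelic_imbalance"]))
            statuses[pid] = survival.classify_loh(pid, cn, pv,
                                                 rule=config.loh_rule).status
        missing = [p for p in pids if p not in statuses]
        if missing:
            raise DataError(f"LOH table missing patients: {missing}")
        out["loh_status"] = out["patient_id"].map(statuses)
        strata = survival.stratify_haps_loh(
            dict(zip(out["patient_id"], out["haps_class"])),
            statuses, collapse="four",
        )
        out["haps_loh_stratum"] = out["patient_id"].map(strata)
        _stage("loh", t0, len(loh_df))

    if config.clones_tsv:
        t0 = time.perf_counter()
        reps = hio.read_clones(config.clones_tsv)
        div_col, clon_col = {}, {}
        for (pid, tp), rep in reps.items():
            if tp == "baseline":
                div_col[pid] = tcr.shannon_diversity(rep)
                clon_col[pid] = tcr.clonality(rep)
        out["tcr_diversity"] = out["patient_id"].map(div_col)
        out["tcr_clonality"] = out["patient_id"].map(clon_col)
        _stage("tcr", t0, len(reps))

    if config.nn_model_json:
        t0 = time.perf_counter()
        model = nn.NNModel.from_json(Path(config.nn_model_json).read_text())
        needed = [c for c in model.feature_names if c not in out.columns]
        if needed:
            raise DataError(
                f"NN scoring needs feature columns {needed}; supply the "
                "corresponding input tables"
            )
        scores = nn.predict(model, out[list(model.feature_names)])
        out["nn_score"] = scores
        if model.threshold is not None:
            out["nn_class"] = [
                "high" if s >= model.threshold else "low" for s in scores
            ]
        _stage("nn", t0, len(out))

    return out
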