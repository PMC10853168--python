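"""Seeded synthetic-cohort generator.

Emulates every input the scoring pipeline consumes — an aligned allele
"pool" with genotypes, MHC-I binding predictions, mutation counts,
survival, HLA-LOH calls, TCR clone tables and response labels — with
controllable effect sizes, so the full pipeline is testable without any
external data. Sequences are synthetic (a random consensus with a limited
number of substituted sites per allele, giving realistic per-site
divergences); they are not real HLA alleles.

Reproducibility: a master seed fans out to per-stage seeds through a fixed
rule, ``SeedSequence([master_seed, stage_index])``, where the stage index
comes from :data:`STAGES`. Each stage is therefore individually
reproducible regardless of which other stages run.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import grantham, haps as haps_mod, neoantigen, tcr
from .errors import DataError
from .hla import CLASS_I_LOCI, AlleleSequenceStore, HLAGenotype
from .nn import _sigmoid

RESIDUES = sorted("ACDEFGHIKLMNPQRSTVWY")

#: fixed stage -> seed-stream index table (the fan-out rule)
STAGES = {
    "alleles": 0,
    "genotypes": 1,
    "binding": 2,
    "mutations": 3,
    "survival": 4,
    "loh": 5,
    "repertoire": 6,
    "response": 7,
}


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), STAGES[stage]])
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a synthetic cohort (defaults: WES-like cohort)."""

    seed: int
    n_patients: int = 300
    # alleles / genotypes
    alleles_per_locus: int = 8
    alignment_length: int = 181
    n_variable_sites: int = 8
    homozygosity_prob: float = 0.15
    # binding predictions
    tnb_log10_mean: float = 1.8   # scale of log10(TNB_i + 1) per locus
    tnb_log10_sd: float = 0.5
    max_tnb_per_locus: int = 5000
    nonbinder_fraction: float = 0.3
    # mutations
    region_size_mb: float = 30.0
    mutations_per_neoantigen: float = 3.0
    mutation_noise_sd: float = 0.3
    # survival
    baseline_median_os_months: float = 12.0
    hr_high: float = 0.5
    haps_cutoff: float = 10.0
    censoring_rate: float = 0.2
    # LOH
    loh_prevalence: float = 0.17
    # repertoires
    n_clones: int = 200
    powerlaw_exponent: float = 1.0
    repertoire_reads: int = 20_000
    exponent_shift_dcb: float = 0.3
    exponent_shift_pd: float = -0.1
    # response model (logistic on z-scored haps, tmb, diversity)
    response_coefs: tuple = (0.8, 0.5, 0.5)
    response_intercept: float = -0.4

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise DataError("n_patients must be >= 1")
        if self.alignment_length < 1:
            raise DataError("alignment_length must be >= 1")
        if self.alleles_per_locus < 2:
            raise DataError("allele pool needs >= 2 alleles per locus")
        for name in ("homozygosity_prob", "censoring_rate", "loh_prevalence",
                     "nonbinder_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        if self.hr_high <= 0:
            raise DataError(f"hr_high must be > 0, got {self.hr_high}")
        if self.powerlaw_exponent <= 0:
            raise DataError(
                f"powerlaw_exponent must be > 0, got {self.powerlaw_exponent}"
            )
        if self.baseline_median_os_months <= 0:
            raise DataError("baseline_median_os_months must be > 0")


def simulate_alleles(
    config: CohortConfig,
) -> tuple[AlleleSequenceStore, list[HLAGenotype]]:
    """Allele pool (consensus + limited substitutions) and patient genotypes."""
    rng = stage_rng(config.seed, "alleles")
    length = config.alignment_length
    consensus = rng.choice(RESIDUES, size=length)
    sequences: dict[str, str] = {}
    pools: dict[str, list[str]] = {}
    for locus in CLASS_I_LOCI:
        pools[locus] = []
        for i in range(config.alleles_per_locus):
            name = f"{locus}*{i + 1:02d}:01"
            seq = consensus.copy()
            k = min(config.n_variable_sites, length)
            sites = rng.choice(length, size=k, replace=False)
            for pos in sites:
                choices = [r for r in RESIDUES if r != seq[pos]]
                seq[pos] = choices[rng.integers(len(choices))]
            sequences[name] = "".join(seq)
            pools[locus].append(name)
    store = AlleleSequenceStore(sequences)

    grng = stage_rng(config.seed, "genotypes")
    genotypes = []
    for i in range(config.n_patients):
        alleles = {}
        for locus in CLASS_I_LOCI:
            pool = pools[locus]
            a1 = pool[grng.integers(len(pool))]
            if grng.random() < config.homozygosity_prob:
                a2 = a1
            else:
                a2 = pool[grng.integers(len(pool))]
            alleles[locus] = (a1, a2)
        genotypes.append(HLAGenotype(patient_id=f"P{i + 1:04d}", alleles=alleles))
    return store, genotypes


def _random_peptides(rng: np.random.Generator, n: int, length: int = 9,
                     taken: set | None = None) -> list[str]:
    taken = taken if taken is not None else set()
    out: list[str] = []
    while len(out) < n:
        block = rng.choice(RESIDUES, size=(n - len(out) + 8, length))
        for row in block:
            pep = "".join(row)
            if pep not in taken:
                taken.add(pep)
                out.append(pep)
                if len(out) == n:
                    break
    return out


def simulate_binding(
    config: CohortConfig, genotypes: Sequence[HLAGenotype]
) -> pd.DataFrame:
    """NetMHCpan-style prediction table: true binders plus background rows."""
    rng = stage_rng(config.seed, "binding")
    log500 = math.log10(500.0)
    rows = []
    for g in genotypes:
        taken: set = set()
        n_binders = 0
        for locus in CLASS_I_LOCI:
            n_i = int(round(10 ** rng.normal(config.tnb_log10_mean,
                                             config.tnb_log10_sd) - 1))
            n_i = int(np.clip(n_i, 0, config.max_tnb_per_locus))
            peptides = _random_peptides(rng, n_i, taken=taken)
            pair = g.pair(locus)
            for pep in peptides:
                allele = pair[rng.integers(2)]
                rows.append({
                    "patient_id": g.patient_id,
                    "peptide": pep,
                    "allele": allele,
                    "ic50_nm": round(10 ** rng.uniform(0.7, log500), 4),
                    "rank_pct": round(rng.uniform(0.01, 0.99), 4),
                    "wt_peptide": "",
                })
            n_binders += n_i
        n_bg = int(round(config.nonbinder_fraction * n_binders))
        bg_peptides = _random_peptides(rng, n_bg, taken=taken)
        all_alleles = list(g.all_alleles())
        for pep in bg_peptides:
            rows.append({
                "patient_id": g.patient_id,
                "peptide": pep,
                "allele": all_alleles[rng.integers(len(all_alleles))],
                "ic50_nm": round(10 ** rng.uniform(2.7, 4.5), 4),
                "rank_pct": round(rng.uniform(1.5, 50.0), 4),
                "wt_peptide": "",
            })
    return pd.DataFrame(rows)


def simulate_survival(
    haps_values, config: CohortConfig, seed: int | None = None
) -> list:
    """Exponential survival with a hazard multiplier above the HAPS threshold.

    ``haps_values`` maps patient id -> score. Patients at or above
    ``config.haps_cutoff`` have their baseline hazard multiplied by
    ``config.hr_high``. Censoring times are independent Uniform(0, c) with
    ``c`` solved so the expected censoring fraction equals
    ``config.censoring_rate``.
    """
    from .survival import SurvivalRecord

    s = pd.Series(haps_values, dtype=float)
    rng = (stage_rng(config.seed, "survival") if seed is None
           else np.random.default_rng(seed))
    lam0 = math.log(2) / config.baseline_median_os_months
    high = (s >= config.haps_cutoff).to_numpy()
    lam = np.where(high, lam0 * config.hr_high, lam0)
    t_event = rng.exponential(1.0 / lam)

    rate = config.censoring_rate
    if rate <= 0:
        c_max = math.inf
        censor = np.full(s.size, math.inf)
    else:
        p_high = float(high.mean())

        def expected_censoring(c):
            def f(l):
                return (1 - math.exp(-l * c)) / (l * c)
            return (p_high * f(lam0 * config.hr_high)
                    + (1 - p_high) * f(lam0)) - rate

        c_max = brentq(expected_censoring, 1e-9, 1e9)
        censor = rng.uniform(0.0, c_max, size=s.size)

    records = []
    for pid, te, tc in zip(s.index, t_event, censor):
        event = int(te <= tc)
        records.append(SurvivalRecord(
            patient_id=str(pid),
            time=float(min(te, tc)),
            event=event,
        ))
    return records


def simulate_repertoire(
    config: CohortConfig,
    patient_id: str = "P0001",
    timepoint: str = "baseline",
    exponent: float | None = None,
    rng: np.random.Generator | None = None,
) -> tcr.TCRRepertoire:
    """Power-law clone repertoire with CASS...F-framed random CDR3s."""
    if config.n_clones < 1:
        raise DataError("n_clones must be >= 1")
    exponent = config.powerlaw_exponent if exponent is None else exponent
    if exponent <= 0:
        raise DataError(f"power-law exponent must be > 0, got {exponent}")
    rng = rng if rng is not None else stage_rng(config.seed, "repertoire")
    n = config.n_clones
    freqs = np.arange(1, n + 1, dtype=float) ** (-exponent)
    freqs /= freqs.sum()
    counts = rng.multinomial(config.repertoire_reads, freqs)
    seqs: set = set()
    cdr3s = []
    while len(cdr3s) < n:
        length = int(rng.integers(8, 21))
        middle = "".join(rng.choice(RESIDUES, size=max(length - 5, 1)))
        seq = f"CASS{middle}F"
        if seq not in seqs:
            seqs.add(seq)
            cdr3s.append(seq)
    clones = [tcr.Clone(seq, int(c)) for seq, c in zip(cdr3s, counts) if c > 0]
    return tcr.TCRRepertoire(patient_id=patient_id, timepoint=timepoint,
                             clones=clones)


@dataclass
class CohortBundle:
    """All pipeline inputs of one synthetic cohort, plus generative truth."""

    config: CohortConfig
    store: AlleleSequenceStore
    genotypes: list
    binding: pd.DataFrame
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    loh: pd.DataFrame
    clones: pd.DataFrame
    features: pd.DataFrame
    truth: dict = field(default_factory=dict)


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a mutually consistent bundle of all pipeline inputs.

    The response labels and survival times are generated from the scores
    the real scoring modules compute on the generated inputs, so every
    downstream effect direction is by construction consistent with the
    generated data.
    """
    try:
        store, genotypes = simulate_alleles(config)
    except DataError as err:
        raise DataError(f"stage alleles: {err}") from err
    matrix = grantham.build_grantham_matrix()
    binding = simulate_binding(config, genotypes)

    # score the generated inputs with the real modules
    records_by_patient: dict[str, list] = {g.patient_id: [] for g in genotypes}
    for row in binding.itertuples(index=False):
        records_by_patient[row.patient_id].append(
            neoantigen.BindingRecord(
                patient_id=row.patient_id, peptide=row.peptide,
                allele=row.allele, ic50=row.ic50_nm, rank_pct=row.rank_pct,
            )
        )
    haps_by_patient: dict[str, float] = {}
    truth_rows = []
    for g in genotypes:
        div = grantham.patient_divergence(g, store, matrix)
        binders = neoantigen.filter_binders(records_by_patient[g.patient_id])
        tnb = neoantigen.tnb_per_locus(binders, g)
        res = haps_mod.compute_haps(div, tnb)
        haps_by_patient[g.patient_id] = res.haps
        truth_rows.append({
            "patient_id": g.patient_id,
            "hed_A": div.hed_a, "hed_B": div.hed_b, "hed_C": div.hed_c,
            "tnb_A": tnb.tnb_a, "tnb_B": tnb.tnb_b, "tnb_C": tnb.tnb_c,
            "tnb_total": tnb.tnb_total, "haps": res.haps,
        })
    truth_df = pd.DataFrame(truth_rows)

    # mutations / TMB linked to the realized neoantigen totals
    mrng = stage_rng(config.seed, "mutations")
    mut_rows = []
    for row in truth_df.itertuples(index=False):
        noise = math.exp(mrng.normal(0.0, config.mutation_noise_sd))
        n_mut = max(
            int(row.tnb_total),
            int(round(row.tnb_total * config.mutations_per_neoantigen * noise)),
        )
        mut_rows.append({
            "patient_id": row.patient_id,
            "n_nonsynonymous": n_mut,
            "region_size_mb": config.region_size_mb,
        })
    mutations = pd.DataFrame(mut_rows)
    tmb_by_patient = {
        r["patient_id"]: r["n_nonsynonymous"] / r["region_size_mb"]
        for r in mut_rows
    }

    # survival driven by the realized HAPS
    surv_records = simulate_survival(haps_by_patient, config)

    # LOH
    lrng = stage_rng(config.seed, "loh")
    loh_rows = []
    for g in genotypes:
        lost_locus = None
        if lrng.random() < config.loh_prevalence:
            lost_locus = CLASS_I_LOCI[lrng.integers(3)]
        for locus in CLASS_I_LOCI:
            if locus == lost_locus:
                cn = lrng.uniform(0.05, 0.45)
                p = lrng.uniform(1e-4, 5e-3)
            else:
                cn = lrng.uniform(0.7, 1.3)
                p = lrng.uniform(0.05, 1.0)
            loh_rows.append({
                "patient_id": g.patient_id, "locus": locus,
                "minor_cn": round(cn, 4), "p_allelic_imbalance": round(p, 6),
            })
    loh = pd.DataFrame(loh_rows)

    # repertoires: baseline + on-treatment; diversity from baseline
    rrng = stage_rng(config.seed, "repertoire")
    clone_rows = []
    diversity_by_patient = {}
    baseline_reps = {}
    for g in genotypes:
        rep = simulate_repertoire(config, g.patient_id, "baseline", rng=rrng)
        baseline_reps[g.patient_id] = rep
        diversity_by_patient[g.patient_id] = tcr.shannon_diversity(rep)
        for c in rep.clones:
            clone_rows.append({
                "patient_id": g.patient_id, "timepoint": "baseline",
                "cdr3_aa": c.cdr3_aa, "count": c.count,
            })

    # response from the logistic model on z-scored (haps, tmb, diversity)
    pids = [g.patient_id for g in genotypes]
    feats = np.array([
        [haps_by_patient[p], tmb_by_patient[p], diversity_by_patient[p]]
        for p in pids
    ])
    if config.n_patients > 1 and np.all(feats.std(axis=0) > 0):
        z = (feats - feats.mean(axis=0)) / feats.std(axis=0)
    else:
        z = np.zeros_like(feats)
    coefs = np.asarray(config.response_coefs, dtype=float)
    p_dcr = _sigmoid(config.response_intercept + z @ coefs)
    prng = stage_rng(config.seed, "response")
    response = np.where(prng.random(len(pids)) < p_dcr, "DCR", "PD")

    # on-treatment repertoires: responders grow more clonal
    for pid, resp in zip(pids, response):
        shift = (config.exponent_shift_dcb if resp == "DCR"
                 else config.exponent_shift_pd)
        exponent = max(config.powerlaw_exponent + shift, 1e-6)
        rep = simulate_repertoire(config, pid, "on_treatment",
                                  exponent=exponent, rng=rrng)
        for c in rep.clones:
            clone_rows.append({
                "patient_id": pid, "timepoint": "on_treatment",
                "cdr3_aa": c.cdr3_aa, "count": c.count,
            })
    clones = pd.DataFrame(clone_rows)

    # clinical table
    surv_by_pid = {r.patient_id: r for r in surv_records}
    demo_rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 99])
    )
    clin_rows = []
    for pid in pids:
        rec = surv_by_pid[pid]
        pfs_frac = demo_rng.uniform(0.3, 0.9)
        clin_rows.append({
            "patient_id": pid,
            "os_months": round(rec.time, 4),
            "os_event": rec.event,
            "pfs_months": round(rec.time * pfs_frac, 4),
            "pfs_event": rec.event,
            "response": response[pids.index(pid)],
            "stage": int(demo_rng.integers(1, 5)),
            "gender": ["female", "male"][demo_rng.integers(2)],
            "age": int(demo_rng.integers(35, 85)),
            "pdl1_pct": round(float(demo_rng.uniform(0, 100)), 1),
            "tmb": round(tmb_by_patient[pid], 4),
        })
    clinical = pd.DataFrame(clin_rows)

    features = pd.DataFrame({
        "patient_id": pids,
        "haps": [haps_by_patient[p] for p in pids],
        "tmb": [tmb_by_patient[p] for p in pids],
        "tcr_diversity": [diversity_by_patient[p] for p in pids],
        "response": response,
    })

    return CohortBundle(
        config=config,
        store=store,
        genotypes=genotypes,
        binding=binding,
        mutations=mutations,
        clinical=clinical,
        loh=loh,
        clones=clones,
        features=features,
        truth={
            "per_patient": truth_df,
            "p_dcr": dict(zip(pids, p_dcr.round(6))),
            "haps_cutoff": config.haps_cutoff,
            "hr_high": config.hr_high,
        },
    )


def write_bundle(bundle: CohortBundle, outdir) -> dict:
    """Write all bundle files (TSV/FASTA + manifest JSON) into a directory.

    Deterministic formatting: the same bundle always produces byte-identical
    files. Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fasta = outdir / "alleles.fasta"
    with fasta.open("w") as fh:
        for name in sorted(bundle.store.sequences):
            fh.write(f">{name}\n{bundle.store.sequences[name]}\n")

    geno_rows = [
        {
            "patient_id": g.patient_id,
            "A1": g.pair("A")[0], "A2": g.pair("A")[1],
            "B1": g.pair("B")[0], "B2": g.pair("B")[1],
            "C1": g.pair("C")[0], "C2": g.pair("C")[1],
        }
        for g in bundle.genotypes
    ]
    tables = {
        "genotypes.tsv": pd.DataFrame(geno_rows),
        "binding.tsv": bundle.binding,
        "mutations.tsv": bundle.mutations,
        "clinical.tsv": bundle.clinical,
        "loh.tsv": bundle.loh,
        "clones.tsv": bundle.clones,
        "features.tsv": bundle.features,
    }
    for name, df in tables.items():
        df.to_csv(outdir / name, sep="\t", index=False, float_format="%.10g",
                  na_rep=".")

    manifest = {
        "config": dataclasses.asdict(bundle.config),
        "stage_seed_rule": "SeedSequence([seed, stage_index])",
        "stages": STAGES,
        "files": sorted([*tables, "alleles.fasta"]),
        "n_patients": bundle.config.n_patients,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest
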