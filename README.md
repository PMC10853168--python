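# hapscore

Quantitative scoring of HLA class I tumor-antigen presentation capacity for
immune-checkpoint-inhibitor (ICI) response stratification, with the
companion analyses such a study needs: survival-based cutoff scanning,
HLA loss-of-heterozygosity (LOH) stratification, TCR β CDR3 repertoire
metrics, neoantigen quality, simple expression signatures, and a
three-factor neural-network response model. A seeded synthetic-cohort
generator makes every pipeline stage runnable and testable without any
patient data.

It is aimed at cancer immunogenomics analysts who already have HLA
genotypes, MHC-I binding predictions (NetMHCpan-style tables), somatic
mutation counts, clinical follow-up and — optionally — LOH calls and
MiXCR-style TCR clone tables, and want a reproducible path from those
inputs to per-patient scores and strata.

## The score

For a patient with paired alleles at each classical class I locus
*i* ∈ {A, B, C}:

- **HED_i** — HLA-I evolutionary divergence: the mean per-site Grantham
  distance between the two aligned peptide-binding-domain sequences
  (181 columns, exons 2–3). The Grantham distance combines side-chain
  composition *c*, polarity *p* and volume *v*:

      d(x, y) = ρ · [α(c_x − c_y)² + β(p_x − p_y)² + γ(v_x − v_y)²]^½

  with α = 1.833, β = 0.1018, γ = 0.000399 and ρ normalizing the mean
  inter-residue distance to 100. A homozygous locus has HED = 0.

- **TNB_i** — tumor neoantigen burden at locus *i*: the number of distinct
  mutant peptides predicted to bind at least one allele of the locus more
  strongly than the moderate-affinity threshold (IC50 < 500 nM, or
  %rank < 1 as an alternative filter).

- **HAPS** — HLA tumor-Antigen Presentation Score:

      HAPS = mean_i [ HED_i × log10(TNB_i + 1) ]

  Patients are classified high/low against a cutoff of 10 for
  whole-exome-derived scores or 1.31 for targeted-panel scores, both
  chosen by hazard-ratio minimization over observed cutoffs
  (`hapscore.scan_cutoff` implements that scan).

Supporting definitions: TMB = nonsynonymous mutations per Mb of coding
region; repertoire diversity H = −Σ p_i ln p_i and clonality
1 − H/ln(n); HLA-LOH calls per locus when minor-allele copy number < 0.5
with allelic-imbalance p < 0.01; CYT = √(GZMA × PRF1); and a 3→1→1
logistic network over (HAPS, TMB, TCR diversity) trained with RPROP on a
sum-of-squared-errors loss, thresholded at the Youden-optimal point.

## Worked example

```python
import hapscore as hs

matrix = hs.build_grantham_matrix()          # 20x20, mean off-diagonal 100
store = hs.io.read_allele_fasta("alleles.fasta")   # aligned 181-column pool
genotype = hs.HLAGenotype("PT001", {
    "A": ("A*01:01", "A*02:01"),
    "B": ("B*07:02", "B*08:01"),
    "C": ("C*03:03", "C*07:01"),
})
hed = hs.patient_divergence(genotype, store, matrix)

records = hs.io.read_binding_table("binding.tsv")  # NetMHCpan-style
binders = hs.filter_binders(records)               # IC50 < 500 nM
tnb = hs.tnb_per_locus(binders, genotype)
result = hs.classify_haps(hs.compute_haps(hed, tnb), mode="wes")
print(result.haps, result.haps_class)
```

On the toy alignment shipped with the test suite (a consensus with one,
two and one substituted columns at A, B and C) and five example binding
records, this prints per-locus divergences `(0.0269, 0.8172, 1.0542)`,
per-locus burdens `(2, 1, 1)`, and

```
0.1921 low
```

i.e. HAPS = mean(0.0128, 0.2460, 0.3173) ≈ 0.19, far below the
whole-exome cutoff of 10 — toy sequences differing at one or two of 181
sites present a much narrower peptide space than real heterozygous HLA
pairs, whose divergences are of order 5–10.

The same flow is available from the shell:

```bash
haps simulate --seed 7 --n-patients 300 --outdir cohort/
haps run --bundle cohort/ --out results.tsv
haps scan-cutoff --scores results.tsv --clinical cohort/clinical.tsv
haps tcr --clones cohort/clones.tsv
haps nn train --features cohort/features.tsv --seed 1 --out model.json
```

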