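# ionmut

Analysis toolkit for heavy-ion-beam mutagenesis experiments in rice
(*Oryza sativa*): radiation dose–response modelling of M1 damage,
inference of the number of panicle progenitor cells from M2 mutant
segregation, and a multi-caller variant-consensus pipeline that
separates heritable induced mutations from background variation and
characterizes their spectrum. It is aimed at mutation-breeding and
plant-genomics researchers who want each of these steps as tested,
reusable code exercisable on synthetic data with known ground truth.

## What it computes

**Dose–response (single-hit multi-target model).** M1 seedling survival
or seed set relative to control follows

    S(D) = (1 − (1 − e^(−D/D₀))^N) · 100        [%]

with mean lethal dose D₀ (Gy) and extrapolation number N. N > 1
produces the low-dose "shoulder" of width Dq = D₀·ln N (quasi-threshold
dose); high-LET beams have small shoulders. `fit_shmt` estimates
(D₀, N) by multi-start nonlinear least squares and
`dose_at_response(fit, 50)` gives the 50% iso-effect dose used for dose
recommendation.

**Panicle progenitor cells (chimera model).** An M1 plant grown from a
mutagenized dry seed is a genetic chimera: each of its k harvested
panicles descends from one of P embryo progenitor cells, each
independently mutated with probability m, with per-panicle detection
probability d (≈1 for a recessive marker scored on 36 M2 seedlings).
`panicle_mutant_distribution` gives the exact distribution of the number
x of mutant-bearing panicles; `fit_progenitor_number` recovers P by
profile likelihood over P = 1..6, conditioning on plants with x ≥ 1.

**Induced-mutation identification.** Per-sample VCFs from three callers
are left-normalized, variants shared by any two plants (control
included) are excluded as background, calls are filtered to
10 ≤ DP ≤ 100 and AF ≥ 0.25 (inclusive), and only sites reported by all
three callers become consensus mutations, which are then classified
(Ti/Tv over the six strand-collapsed substitution classes, InDel size
spectrum) and annotated against gene models (region by precedence
exonic > splicing > UTR > intronic > up/downstream > intergenic; codon-level
effects for coding variants).

## Worked example

The numbered scripts under `analysis/` run the whole chain on synthetic
data (bulky intermediates go to `scratch/`, tables to `results/`):

```bash
python analysis/01_simulate.py --seed 1   # genome, truth sets, VCFs, tables
python analysis/02_fit_dose_response.py
python analysis/03_infer_progenitors.py
python analysis/04_call_mutations.py
python analysis/05_report.py
```

`02_fit_dose_response.py` prints (seed 1):

```
Ar : D0 =   54.8 Gy, N =  1.31, shoulder Dq =   14.7 Gy, 50% survival at   48.7 Gy
C  : D0 =  116.7 Gy, N =  3.12, shoulder Dq =  132.8 Gy, 50% survival at  188.2 Gy
Ne : D0 =  103.7 Gy, N =  3.10, shoulder Dq =  117.4 Gy, 50% survival at  166.8 Gy
```

The high-LET beam (Ar) shows the small shoulder and the low 50%
iso-effect dose; C and Ne need roughly twice the dose for the same
effect. `03_infer_progenitors.py` recovers the planted progenitor
numbers (P̂ = 3 for the 3-panicle group, P̂ = 4 for the 5-panicle group)
together with the full likelihood profile, and `04_call_mutations.py`
reports per-sample consensus mutations with precision 1.000 and recall
≈ 0.95 against the planted truth (recall < 1 because the simulated
callers miss 2% of true variants each).

Library use mirrors the scripts:

```python
from ionmut import synthetic_data as sd, dose_response as dr

series = sd.generate_dose_response(60, 3, [0, 50, 100, 150, 200, 300],
                                   noise_sd=3, replicates=10, seed=1)
fit = dr.fit_shmt(series)
print(fit.D0, fit.N, fit.Dq, dr.dose_at_response(fit, 50))
```

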