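# pvsignals

Signal detection for spontaneous adverse-event reporting systems.
`pvsignals` ingests FAERS-style quarterly ASCII file sets (DEMO/DRUG/REAC,
dollar-delimited), deduplicates case versions, and screens a drug–event
pair with the standard pharmacovigilance disproportionality statistics —
crude, stratified with Mantel-Haenszel combination, and per calendar
quarter. It is aimed at pharmacoepidemiologists and drug-safety analysts
who want an auditable, scriptable desk-scale pipeline rather than a
database appliance, and it ships a synthetic report generator with known
ground truth so every stage can be validated offline.

## The statistics

All statistics derive from the fourfold table of deduplicated case counts
for a target drug and a target MedDRA preferred term (PT):

|             | target event | other events |
|-------------|--------------|--------------|
| target drug | a            | b            |
| other drugs | c            | d            |

with N = a+b+c+d. The package computes:

- **ROR** (reporting odds ratio) = (a/c)/(b/d), with the 95% Wald interval
  exp(log ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d));
- **PRR** (proportional reporting ratio) = (a/(a+b))/(c/(c+d)), same
  log-scale interval form;
- **EBGM**, here the observed-to-expected relative reporting ratio
  a·N/((a+b)(a+c)) (exactly 1 under independence; no interval attached);
- **IC₂** (BCPNN information component), the posterior expectation of
  log₂(observed/expected) under Dirichlet-style priors on the cell
  probabilities, with a credibility interval E(IC) ± 2·√V(IC) from the
  posterior variance. The priors regularize empty cells, so IC₂ is defined
  even when a = 0.

A pair is flagged as a *signal* when the ROR/PRR interval lies entirely
above 1, or the IC interval entirely above 0 — a screening flag over a
spontaneous-reporting system, not evidence of causation.

Stratified analyses (by sex, or by the age bins <18 / 18–24 / 25–64 / ≥65 /
unspecified) are combined across strata with the Mantel-Haenszel odds-ratio
and risk-ratio estimators. Quarterly trend series report per-quarter
counts, the actual vs expected percentage of drug-event cases (whose ratio
is the quarter's EBGM, by construction), and per-quarter statistics with
interval bands.

## Worked example

The packaged worked-example dataset is the published FAERS 2020 Q1–2024 Q1
fourfold table for teduglutide (a GLP-2 analog for short bowel syndrome)
and pancreatitis: a=79, b=11,617, c=13,673, d=7,499,604. From the shell:

```
$ pvsignals stats 79 11617 13673 7499604
Disproportionality analysis
============================================================
Contingency table: a=79  b=11617  c=13673  d=7499604  (N=7524973)

statistic   estimate              95% CI criterion  signal
------------------------------------------------------------
ROR             3.73        (2.99, 4.66)    CI > 1     yes
PRR             3.71        (2.97, 4.63)    CI > 1     yes
EBGM             3.7
IC2             1.84        (1.51, 2.16)    CI > 0     yes
```

Reading: pancreatitis is reported among teduglutide cases about 3.7 times
as often as expected under independence, all three interval criteria
exclude the null, so the pair is flagged on every statistic. The same
numbers through the library:

```python
from pvsignals import DisproportionalityModel
res = DisproportionalityModel.from_counts(79, 11617, 13673, 7499604).fit()
print(res.summary())          # table above
res.ror.value                 # 3.729989593692405
```

An end-to-end run over files — here synthetic ones with an injected
relative risk of 4 — uses the `generate` and `analyze` verbs:

```
$ pvsignals generate --out data --quarters 2020Q1:2020Q4 --n-reports 2000 \
      --drug-prevalence 0.02 --event-rate 0.01 --relative-risk 4 --seed 3
$ pvsignals analyze --in data --out results --quarters 2020Q1:2020Q4 \
      --drug TEDUGLUTIDE --event Pancreatitis
```

which writes `contingency.tsv`, `signals.tsv`, `strata_sex.tsv`,
`strata_age.tsv`, `demographics.tsv`, `trends.tsv`, `top_events.tsv` (each
with a full-precision JSON sidecar), a parse/dedup run log, and a manifest.

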