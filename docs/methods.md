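# Methods

## Setting and counting unit

Spontaneous reporting systems such as FAERS collect voluntary reports of
suspected adverse drug events. Each *case* may be re-published in later
quarters as a corrected version under a new `primaryid` while retaining its
`caseid`. The analysis unit throughout this package is the deduplicated
case: after linkage, exactly one report per `caseid` is retained — the one
with the numerically largest `primaryid` (the latest version), ties broken
by the later ingestion quarter. A case contributes to exactly one cell of
any fourfold table no matter how many drug or reaction rows it listed.
Published margins alone cannot discriminate between earliest-version and
latest-version deduplication; latest-version is the convention for removing
superseded case versions and is the package's fixed rule.

Linkage requirements: a report must have at least one drug row and one
reaction row to be classifiable in a 2×2 table; reports failing that, rows
whose field count does not match the header (the dialect has no quoting, so
embedded delimiters are not guessed at), and DRUG/REAC rows whose
`primaryid` has no DEMO row are dropped and *counted* in the run log —
ingestion is deterministic and auditable, never imputing.

Matching is exact on normalized (uppercased, trimmed) strings: the drug
query is a synonym set (default {TEDUGLUTIDE, GATTEX}), the event query a
set of MedDRA preferred terms (default {Pancreatitis}). Substring matching
is deliberately not offered — "Pancreatitis" must not silently absorb
"Pancreatitis acute", which would change cell a.

Age is normalized to years from the FAERS unit codes (YR ×1, DEC ×10,
MON ÷12, WK ÷52.1429, DY ÷365.25, HR ÷8766); missing values, unknown codes
and negative results map to the "unspecified age" stratum. Age bins are
left-closed at 18, 25 and 65. Missing sex maps to "unspecified sex".
Demographic percentages are computed within the reports that provide the
attribute.

## Statistics

For the fourfold table (a, b, c, d), N = a+b+c+d:

- ROR = (a/c)/(b/d); PRR = (a/(a+b))/(c/(c+d)). Both carry the 95% Wald
  interval exp(log θ ± 1.96·√(1/a+1/b+1/c+1/d)). They are undefined when a
  working cell is zero; an optional Haldane–Anscombe +0.5 correction (all
  four cells, applied only when some cell is zero, always flagged in the
  output) can be requested, otherwise the component is reported as
  not-estimable — a distinct state, never a silent 0 or NaN.
- EBGM is implemented as the observed-to-expected relative reporting ratio
  a·N/((a+b)(a+c)), without empirical-Bayes shrinkage and without an
  interval; a true MGPS gamma-Poisson shrinkage estimator is out of scope.
  Under exact independence it is 1, and per quarter it equals the ratio of
  the actual to the expected percentage of drug-event cases by algebraic
  identity (tested to 1e-12 relative).
- IC₂ is the BCPNN posterior expectation of log₂(observed/expected) with
  prior pseudo-counts α₁ = β₁ = γ₁₁ = 1 on the margins/joint cell and
  α = β = 2 on their denominators:

      γ     = γ₁₁ (N+α)(N+β) / ((a+b+α₁)(a+c+β₁))
      E(IC) = log₂[ (a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁)) ]
      V(IC) = (1/ln 2)² [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
                        + (N−(a+b)+α−α₁)/((a+b+α₁)(1+N+α))
                        + (N−(a+c)+β−β₁)/((a+c+β₁)(1+N+β)) ]

  with credibility interval E(IC) ± z·√V(IC) and z = 2 posterior-SD units
  (not 1.96: the interval is a posterior-moment approximation, and the
  2-SD convention is what reproduces the worked example's published bounds
  at printed precision). The priors keep IC defined for a = 0; for
  proportionally growing cells E(IC) → log₂(EBGM), the gap being the
  Bayesian shrinkage toward 0.
- Signal flags: ROR/PRR lower bound > 1, IC lower bound > 0. No
  multiple-comparison adjustment is applied across PTs in the event
  ranking, matching screening practice.
- Mantel-Haenszel combination across sex or age strata uses the classical
  fixed-weight estimators Σaᵢdᵢ/Nᵢ ÷ Σbᵢcᵢ/Nᵢ (odds ratio) and
  Σaᵢ(cᵢ+dᵢ)/Nᵢ ÷ Σcᵢ(aᵢ+bᵢ)/Nᵢ (risk ratio, the PRR analogue — the
  natural stratified counterpart of a proportion ratio). Empty strata are
  skipped; a zero denominator is not-estimable. With a single stratum both
  collapse exactly to the crude ROR/PRR.
- Reported tables round half-up at the configured precision (default 2
  decimals); JSON sidecars keep full precision. Internal computation is
  never rounded.

## Quarterly trends

Per-quarter analyses are cross-sectional: each quarter's fourfold table is
built from that quarter's reports only (quarter = the release quarter of
ingestion, not an in-record date field), so per-quarter intervals are
independent and systematically wider than the pooled interval on the same
data — a property the test suite checks on synthetic data. Quarters inside
the span with no reports yield zero counts and not-estimable statistics. A
cumulative-table mode was considered and not implemented.

## Synthetic data generator

The generator emulates the three-file quarterly structure with a known
ground truth: per report, target-drug exposure ~ Bernoulli(prevalence);
target-event occurrence ~ Bernoulli(background rate × RR if exposed,
capped at 1); 1–4 additional background PTs and 0–3 background drugs from
toy Zipf-weighted vocabularies, drawn independently of exposure; sex from a
three-level categorical; age from a bimodal mixture (pediatric mode
N(8, 5²) clipped to [0, 18), older-adult mode N(55, 16²) clipped to
[18, 100]) with a missing fraction; a configurable fraction of cases
emitted twice under an incremented primaryid. Identical config and seed
give byte-identical output files.

Defaults mirror the worked example's marginal reporting frequencies at
desk scale: 17 quarters (2020Q1–2024Q1), 10,000 reports/quarter, drug
prevalence 0.0016 and background event rate 0.0018 (the worked example's
drug and event margins over its 7.5M reports), RR 3.7, sex mix 55/40/5
female/male/unspecified, 32% missing age, duplicate rate 0.10.

In the rare-event regime ROR ≈ PRR ≈ RR, so the injected RR is the
recoverable ground truth for all three ratio estimators. By default there
is *no* confounding — background terms and demographics are independent of
exposure — so crude and Mantel-Haenszel estimates coincide in expectation;
an optional confounder hook inflates both exposure prevalence and event
rate in the ≥65 stratum, which separates crude from age-adjusted estimates
and is tested qualitatively. What passing tests on this generator do not
show about real data: free-text drug-name noise, MedDRA coding drift,
reporting waves, co-prescription structure, and non-random missingness are
all absent by design.

For Monte-Carlo calibration the cells (a, b, c, d) are drawn directly from
the generative model's binomial structure (`simulate_crude_cells`), which
is distributionally identical to generating full reports and tabulating —
the cells depend only on the exposure/event indicators — and orders of
magnitude faster; a test asserts the agreement between the two routes.

## Calibration choices and problem sizes

Null coverage of the 95% ROR interval is assessed at exposure and event
probabilities of 0.01 with 200,000 reports per replicate over 10,000
replicates (Monte-Carlo SE ≈ 0.2%), a size at which all four cells are ≥ 5
with probability ≈ 1. That cell-size condition is what makes the nominal
level meaningful: the log-Wald interval is conservative when the expected
drug-event cell is small (measured ≈ 96.6% coverage at expected a = 5),
and attains ≈ 95.3% once expected a ≈ 20. RR recovery (mean crude ROR
within 3 Monte-Carlo SEs of RR at RR ∈ {2, 4}) uses the same regime with
100 replicates. All simulation seeds are fixed constants.

## Known limitations

Disproportionality over spontaneous reports measures reporting association,
not incidence or causation; selection and stimulated-reporting biases pass
through untouched. No MedDRA hierarchy expansion (SMQ/HLT), no drug-name
dictionary mapping, no shrinkage EBGM or exact intervals, no
figure rendering (numeric series export only), and ingestion covers only
the DEMO/DRUG/REAC files — outcome, source and therapy files are out of
scope.
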