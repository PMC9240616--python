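# Methods

## The collapsing burden model

The unit of inference is the per-individual carrier indicator: an
individual carries the (gene, class) burden if they have at least one
alternate allele at at least one qualifying variant of that class in the
gene. Zygosity is ignored (any ≥ 1 alternate allele ⇒ carrier), and an
individual carrying several qualifying variants counts once. This is the
classical collapsing design: it trades per-variant resolution for power
when individual variants are too rare to test, and it is the right
statistic when case ascertainment is at the person level.

Conditioning on all margins of the resulting 2×2 table, the case-carrier
count X follows a hypergeometric distribution under the null of equal
carrier odds, and a Fisher noncentral hypergeometric distribution with
odds parameter ψ otherwise. Everything in `varburden.stats` is derived
from that conditional model:

* **Two-sided P** — minimum-likelihood summation: the probabilities of
  all outcomes whose point probability is ≤ that of the observed table
  (up to a 10⁻⁷ relative tolerance guarding floating-point ties) are
  summed. This is the rule used by mainstream statistical software, and
  the one that reproduces published two-sided exact P-values.
* **Sample OR** — the cross-product a(n₂−b)/((n₁−a)b), reported as the
  default point estimate. Zero cells yield 0 or ∞; the all-zero-carrier
  table is flagged degenerate rather than raising.
* **Conditional-MLE OR** — the ψ at which the conditional mean of X
  equals the observed count, found by Brent root-finding on log ψ. It is
  slightly shrunk relative to the cross-product on sparse tables and is
  provided as an option because published reports sometimes mix the two
  (e.g. a pooled sparse table printed as 14.96 where the cross-product
  is 14.97).
* **Exact-conditional CI** — tail inversion: the 95% bounds are the ψ
  values at which P(X ≥ a | ψ) and P(X ≤ a | ψ) equal 0.025, solved by
  monotone root-finding on log ψ with the noncentral weights evaluated
  in log space (`gammaln` + `logsumexp`). At the support boundary the
  corresponding bound is 0 or ∞ (a one-sided interval). This method —
  not log-Woolf — reproduces published intervals such as 1.19–48.30 for
  3/419 vs 4/4523, and is therefore the frozen default; log-Woolf is
  kept as an option for large tables.
* **Pooling** — carriers and totals are summed across cohorts. Published
  pooled counts are exact sums, so no Mantel–Haenszel or
  inverse-variance weighting is applied; pooling refuses to run when
  supplied per-cohort identifier sets overlap.
* **No multiple-testing correction** across classes: per-class nominal
  P-values at the 0.05 level, matching the reporting convention of the
  single-gene design.

P-values are carried at full double precision; any rounding happens in
the report layer only.

## Qualifying-variant selection

Consequence classification is a pure, case-insensitive lookup over a
shipped vocabulary covering Sequence-Ontology-style and ANNOVAR-style
spellings. Only canonical ±1/±2 splice acceptor/donor annotations count
as truncating; extended splice-region tokens are on the documented
OTHER list. Unknown tokens raise rather than silently binning, so
vocabulary drift in an annotator surfaces as an error.

Rarity requires the allele frequency to be **strictly** below the
threshold (default 10⁻⁴) in every subpopulation present in the record; a
variant absent from all frequency resources is rare by default
(`missing_af_policy="treat-as-rare"`), because novel variants are the
norm in this regime. The subpopulation list is whatever the input
carries — the filter does not assume a fixed panel.

Deleterious missense requires REVEL ≥ 0.5 **and** VEST3 ≥ 0.5. The
thresholds are not canonical — 0.5 is a commonly used midpoint for both
scores — so both are configurable, and the shipped reference fixture is
constructed so its deleterious subset (3 of 22 missense) is invariant to
any threshold choice in [0.4, 0.7]; conclusions drawn from it do not
hinge on the cutoff. Missing scores make a variant non-deleterious.

Inframe indels are classified (INFRAME_INDEL) but never qualify for any
burden class: their pathogenicity is hard to ascertain and they are
excluded from association analysis by design.

## Clinical baseline reconstruction

Continuous rows use the unpaired Student's t-test with pooled variance —
sp² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2), df = n₁+n₂−2 — which is an
exact function of the published mean ± SD + n and identical to a t-test
on any raw sample with those moments. Welch's correction is deliberately
not applied: the pooled form is what reproduces published baseline
P-values (0.003 / 0.032 / 0.037 from the echocardiographic rows).

Categorical rows default to Pearson chi-square **without** continuity
correction regardless of expected counts, because that is the method the
published table evidently used throughout (the non-fatal-stroke row,
with a minimum expected count of 2.29, matches uncorrected chi-square at
0.003 and not Fisher's exact at 0.008). The textbook expected-count rule
(chi-square only when all expected cells ≥ 5, else Fisher) is
implemented and selectable (`method_rule="expected-count"`), as is
always-Fisher. Multi-level rows are tested as R×2 chi-square with an
exact Freeman–Halton fallback by direct enumeration (feasible because
baseline-table row totals are small). Rows carry their own per-group n,
since missing data make row denominators smaller than the column-header
n (e.g. a 3-level functional-class row with 13 of 28 graded).

## Synthetic cohorts

The generator plants per-class sites and draws carrier status per
individual: controls with probability p₀(c), cases with the probability
whose odds are θ(c) times the control odds, p₁ = θp₀/(1−p₀+θp₀).
Enrichment is injected at the carrier level because the collapsing
statistic only sees carrier status; sites exist so the filtering and
collapsing code paths are exercised (carriers are attached to concrete
sites uniformly). Allele frequencies come from a Beta(0.5, 1) spectrum
scaled into (0, 10⁻⁴) — only the threshold behaviour matters to the
pipeline — with an optional fraction of sites planted above threshold to
exercise the filter. Missense scores come from a two-component model
(high range 0.75–0.98, low range 0.02–0.35) whose ranges straddle any
reasonable threshold.

Defaults are the study conditions of the motivating analysis: 793 cases
vs 4,523 controls; p₀ from the observed control counts (4, 46, 15 of
4,523 for truncating / missense / synonymous); θ from the observed
study-cohort cross-products (5.73, 3.17, 1.0 — synonymous is the null
class); 3/22/6 sites per class with a 3/22 deleterious fraction.

What the generator does **not** emulate: linkage disequilibrium,
haplotype structure, site-specific recurrence, sequencing error,
population stratification, or relatedness. Passing tests therefore show
that the inference chain is correct and calibrated under its own
assumptions — independent carrier draws with class-level enrichment —
not that those assumptions hold in any real cohort.

Determinism: one master seed expands to per-stage child seeds via
`numpy.random.SeedSequence(seed, spawn_key=(stage,))` with fixed stage
indices (0 sites, 1 carriers, 2 clinical, 3 replicate streams), so
stages re-run independently and byte-identically across platforms.

## Numerical choices and degenerate inputs

* Hypergeometric and noncentral weights are computed in log space from
  `gammaln`; tails via `logsumexp`. Root-finding uses Brent's method on
  log ψ with an expanding bracket starting at ±40.
* Allele normalization trims shared leading bases first (advancing the
  position), then trailing, always retaining one base per allele; it is
  idempotent and leaves SNVs untouched. `ref == alt` is rejected as a
  non-variant.
* Zero pooled variance with equal means gives t = 0, P = 1; with unequal
  means it is a degenerate-input error.
* The all-zero-carrier table returns P = 1 with a degenerate flag on the
  odds ratio instead of raising, so scans over many genes do not abort
  on empty classes.

## Problem sizes used in the checks

The simulation-based checks use 1,000 full pipeline replicates for the
null type-I error (rejection rate at α = 0.05 must not exceed 0.06;
exact tests are conservative, so the observed rate is typically ≈ 0.04)
and 2,000 carrier-model tables per odds ratio in {1, 5, 8} for the
empirical 95%-CI coverage (required ≥ 93%; observed ≈ 0.97–0.99,
reflecting the conservatism of exact intervals at these carrier
frequencies). These sizes keep each run in the tens of seconds while
leaving Monte-Carlo error well inside the asserted margins.

## Known limitations

* Controls enter as carrier counts; genotype-level control data (and
  hence covariate adjustment or firth-type regression) are out of scope.
* The pipeline is per-gene over a configured gene list — no genome-wide
  scan, no SKAT-style variance-component tests.
* One canonical transcript per gene is assumed to have been used
  upstream; the classifier consumes annotations, it does not compute
  them.
* Survival/endpoint modelling and expression-based (TWAS-style)
  analyses are outside the package's scope.
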