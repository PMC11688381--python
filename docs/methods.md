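# Methods

## The screening problem

A spontaneous reporting system accumulates reports, each naming one or
more drugs (with role codes: primary suspect PS, secondary suspect SS,
concomitant C, interacting I) and one or more MedDRA preferred terms (PTs)
describing the adverse event.  There is no denominator of exposed
patients, so absolute risks are unidentifiable; instead each drug's share
of event reports is compared with the rest of the database.  `pvsignal`
screens drugs against a configurable PT set — by default the 26
coagulopathy PTs (consumptive coagulopathies such as disseminated
intravascular coagulation, factor inhibitions, hyper-/hypo-coagulable
states, heparin resistance) — using three complementary statistics on the
2×2 table (a, b, c, d defined in the README).

## Statistics and numerical choices

**ROR** ad/bc with the Woolf log-normal interval
exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).  **PRR** a(c+d)/(c(a+b)) with the
Pearson χ² of the table, computed by the closed form
(ad−bc)²N/((a+b)(c+d)(a+c)(b+d)); the test suite verifies bit-level
agreement with an independently coded Pearson statistic.  **BCPNN IC**
log₂(aN/((a+b)(a+c))), the log₂ observed/expected reporting ratio.

*Credible interval for IC.*  The four cell probabilities receive a flat
Dirichlet(1,1,1,1) prior; the posterior given (a,b,c,d) is
Dirichlet(a+1,…,d+1).  E(IC) and V(IC) are the posterior mean and variance
of log₂(p₁₁/(p₁·p·₁)), estimated by seeded Monte-Carlo sampling (default
10⁵ draws, fixed recorded seed), and IC025/IC975 = E(IC) ∓ 2√V(IC).  This
is a definition choice: V(IC) has several closed-form approximations in
the literature and none is canonical, so the posterior moments themselves
are the primary definition here, with determinism guaranteed by the seed.
Doubling the draw count moves IC025 by < 0.02 bits on typical screening
tables.

*Zero cells.*  If any cell is 0, all four cells get +0.5
(Haldane–Anscombe) for ROR/PRR/χ²/IC and the result is flagged
`corrected`; the a ≥ 3 report-count criterion always uses the raw a.  A
zero *margin* (e.g. an entity covering every report) makes PRR undefined
and is reported as a per-entity error rather than NaN.

*Criteria.*  flag_ror = (a ≥ 3 ∧ CI_low > 1); flag_prr = (a ≥ 3 ∧ PRR ≥ 2
∧ χ² ≥ 4); flag_bcpnn = (IC025 > 0); consensus positive = any flag.  All
thresholds are configurable (`Thresholds`).

*Monotonicity caveat.*  ROR and PRR are strictly increasing in a (b, c, d
fixed).  IC is not, in general: raising a also raises N and both margins,
and for tables where a dominates its margins the observed/expected ratio
can stall or fall ((1,1,1,5) → (2,1,1,5) leaves IC at exactly 1 bit).  In
the screening regime — both margins dominated by other entities — IC is
strictly increasing, and the property test asserts exactly that.

*Rounding.*  Report tables round statistics to 2 decimals and percentages
to 1–2 decimals, half away from zero (the usual convention in published
tables; Python's banker's rounding would disagree on exact halves).

## Pipeline semantics

**Dedup.**  One record per `caseid`: latest `fda_dt` wins; ties go to the
numerically larger `primaryid` (lexicographic fallback for non-numeric
legacy IDs); unparseable dates sort before all valid dates; a final pass
drops exact `primaryid` duplicates keeping the first occurrence.  The
operation is idempotent and never invents records.

**Event flagging.**  A case is an event case iff ≥ 1 of its PTs matches
the dictionary, case-insensitively after whitespace normalisation, with a
numeric-code fallback to survive capitalisation drift across MedDRA
versions.  The PT-distribution report counts (case, matched-PT) *pairs*
with multiplicity — a case matching k PTs contributes k pairs — and its
percentages are over total pairs, which is the only convention under which
such a table's percentages are internally consistent when cases match
several PTs.

**Drug catalog.**  Normalisation is deterministic (uppercase, trim,
collapse whitespace, strip trailing dose/form/salt tokens, exact synonym
lookup); combination products are single entities; blocklisted ambiguous
names are dropped with a count.  Only PS mentions enter the screen; a case
mentioning the same PS ingredient twice counts once.  The
anticoagulant/antiplatelet exclusion list and the ATC class map are
packaged editable TSV files: drugs given *to* affect coagulation are
excluded from ranking because their event reports reflect indication, not
signal.  The packaged class map follows the common published grouping of
paracetamol and ibuprofen under "analgesics" even though ATC proper places
ibuprofen among anti-inflammatories; the label set, not the ATC tree, is
the unit here.

**Screen.**  Entities are ranked by a (event-case count with the entity as
PS), descending, ties alphabetical, after exclusions, truncated to top_n
(default 30).  The contingency universe is always the full deduplicated
case set, so a + c is identical across entities.  Class-level screening
unions the member drugs' case sets (a case with two member drugs counts
once) and ranks classes by ROR.  The annual trend uses the FDA receipt
year.  Fixed input + config + seed ⇒ byte-identical outputs.

## The synthetic generator

The generator emulates the structure a screening pipeline must survive:
multiple drug mentions per case with role codes, multiple reaction PTs,
demographics, outcome codes, duplicate follow-up reports, quarterly
packaging, and — crucially — a known generative model to test against.

Model: each case draws its PS drug from the catalog, where `use_prob` is
the probability of being the case's primary suspect (residual mass goes to
a pool of null background drugs, RR = 1); the case reports an event PT
with probability min(1, p0·RR_PS), so extreme RRs stay valid
probabilities; 0–2 extra SS/C mentions are drawn uniformly (1–3 drugs per
case); event PTs are sampled with weights defaulting to the packaged
dictionary's relative report frequencies; non-event reactions come from a
filler PT list disjoint from the dictionary.  Defining `use_prob` on the
PS slot makes the analytic oracle exact: E[a] = n·p_use·min(1, p0·RR),
E[a+b] = n·p_use (`expected_contingency`).

Duplicates: a configured fraction of cases is emitted twice under one
caseid with a larger second primaryid; alternate pairs get fda_dt + 30
days vs. an equal fda_dt, so both dedup branches are exercised and dedup
must restore exactly n_cases.

Default study conditions (used by the acceptance checks): 50,000 cases, 30
catalog drugs at use_prob 0.02, three planted at RR = 8, baseline event
probability p0 = 0.01, 50 replicates — sizes at which a desk machine runs
the full pipeline per replicate in ~2 s while the planted a ≈ 80 gives all
three methods essentially full power.  Demographic category defaults
(slight female excess, death the most common serious outcome, the US the
largest reporter country) are shaped like a large real-world coagulopathy
report series and are fully configurable.

What the generator does *not* emulate: drug-name misspellings beyond the
synonym table, reporting delays and time-varying reporting rates,
correlated polypharmacy (co-prescription structure), event probabilities
driven by non-PS drugs, and notoriety effects.  Passing tests therefore
demonstrate correctness of the pipeline's mechanics and calibration of the
statistics under a clean generative model — not robustness to the
messiness of real FAERS data (name variants are exercised only through
the normaliser's unit tests).

## Verification summary

Tests pin hand-derived values for every statistic, verify the χ² closed
form against an independent Pearson implementation to < 10⁻¹⁰ relative
error, property-test sign equivalence (ROR > 1 ⇔ PRR > 1 ⇔ IC > 0 for
all-positive cells), measure 94–96% coverage of the ROR CI on multinomial
tables with known odds ratio, and run the full
simulate → write → read → assemble → dedup → flag → screen loop against
the generator's manifest: event sets match exactly, counts are conserved
at every join, and planted RR = 8 drugs are recovered by all three
methods in ≥ 95% of replicates with ≤ 10% null consensus false positives.

## Limitations

Single-threaded; in-memory (a full 20-year FAERS snapshot would need
chunked ingestion); the packaged synonym/ATC/exclusion lists cover the
screening set used here, not a full RxNorm/WHO-DD vocabulary; no shrinkage
(EBGM) or multiple-testing control across entities — consensus-positive
flags are screening signals, not causal claims.
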