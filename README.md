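# pvsignal

Disproportionality-based signal detection for spontaneous adverse-event
reports, built around drug-induced **coagulopathies** in FAERS-style data.

Spontaneous reporting systems such as the FDA Adverse Event Reporting
System (FAERS) collect voluntary reports of suspected adverse drug
reactions but have no exposure denominator, so drug–event associations are
screened by *disproportionality*: is the event reported with the target
drug more often than the rest of the database predicts under independence?
`pvsignal` implements the full screening pipeline:

* a **synthetic reporting-system generator** that emits FAERS-format
  quarterly ASCII packages (`$`-delimited DEMO/DRUG/REAC/OUTC/THER/INDI/RPSR
  tables) with *known ground truth* — planted drug–event relative risks,
  injected duplicate reports, configurable demographics;
* **ingestion** of FAERS-style quarterly packages, including the legacy
  pre-2012Q4 ISR/CASE schema;
* **case deduplication** (latest `fda_dt` per `caseid` wins, ties broken by
  the larger `primaryid`);
* a **MedDRA PT event dictionary** — the packaged default is the 26
  coagulopathy preferred terms, from *Coagulopathy* and *Disseminated
  intravascular coagulation* to single-factor inhibitions;
* a **drug catalog**: verbatim-name normalisation, primary-suspect (PS)
  filtering, an editable anticoagulant/antiplatelet exclusion list, and ATC
  therapeutic-class grouping;
* the three classical **signal statistics** on the 2×2 table
  (a = event ∧ drug, b = other-event ∧ drug, c = event ∧ other drugs, d = rest):

  | method | statistic | positive when |
  |---|---|---|
  | ROR | ad/bc, 95% CI = e^(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)) | a ≥ 3 and CI low > 1 |
  | PRR | a(c+d)/(c(a+b)); χ² = (ad−bc)²N/((a+b)(c+d)(a+c)(b+d)) | a ≥ 3, PRR ≥ 2, χ² ≥ 4 |
  | BCPNN | IC = log₂(aN/((a+b)(a+c))); IC025 = E(IC) − 2√V(IC) | IC025 > 0 |

  with the consensus rule that an entity is *positive* if **any** method
  fires.  E(IC)/V(IC) are Dirichlet-posterior moments estimated by seeded
  Monte Carlo; zero cells fall back to the Haldane–Anscombe +0.5 correction.

## Worked example

```python
from pvsignal import ContingencyTable, compute_signal

table = ContingencyTable(a=20, b=80, c=100, d=9800)
r = compute_signal("example drug", table, n_draws=100_000, seed=1)
```

prints (see `examples/03_signal_statistics.py`):

```
ROR   24.50  (95% CI 14.45-41.55)  flag=True
PRR   19.80  chi2 301.1                 flag=True
IC     4.06  (IC025 3.53, IC975 4.58)  flag=True
consensus positive: True
```

The event appears in 20% of the drug's reports versus ~1% elsewhere: the
reporting odds ratio is 24.5, the event is reported ≈16.7× (2^4.06) more
often than independence predicts, and all three screening criteria fire.

The narrative scripts in `examples/` walk the whole pipeline: `01` plants
three RR = 8 drugs in a 10,000-case synthetic database, `02` ingests and
deduplicates it (11,000 reports → exactly 10,000 cases), `04` runs the full
screen — the planted drugs top the ranking with ROR ≈ 8–9 and consensus
`positive=True` while null drugs stay near ROR 1 — and writes
`signals.csv`, `groups.csv`, `demographics.csv`, `pt_distribution.csv` and
`trend.csv`.

A thin CLI wraps the same calls:

```bash
pvsignal simulate --config sim.yaml --out db/ --seed 7
pvsignal signals db/ --out screen/ --top 30 --seed 7
```

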