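"""Generate a synthetic FAERS-format database with planted signals.

Builds a 10,000-case reporting database in which three drugs carry an
eight-fold relative risk of coagulopathy reports and 10% of cases are
emitted twice under one case ID, then prints what was planted.
"""

from pathlib import Path

from pvsignal import DrugSpec, SyntheticConfig, expected_contingency, generate_database

catalog = [
    DrugSpec(f"STUDY DRUG {i:02d}", use_prob=0.02, rr=8.0 if i < 3 else 1.0,
             atc_class="planted class" if i < 3 else "null class")
    for i in range(30)
]
config = SyntheticConfig(
    n_cases=10_000,
    drug_catalog=catalog,
    baseline_event_prob=0.01,   # a null-drug case reports the event 1% of the time
    duplicate_fraction=0.10,
    seed=2024,
)
out = generate_database(config, Path("scratch") / "example_db")
print(f"wrote quarterly packages and ground-truth manifest under {out}")

a, b, c, d = expected_contingency(config, "STUDY DRUG 00")
print(f"expected 2x2 cells for the planted drug: a={a:.0f} b={b:.0f} c={c:.0f} d={d:.0f}")
print(f"implied odds ratio {(a * d) / (b * c):.1f} — the screen should flag this drug")
# a = n * use_prob * min(1, p0*RR) = 10000 * 0.02 * 0.08 = 16 expected
# event reports with the drug as primary suspect.
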