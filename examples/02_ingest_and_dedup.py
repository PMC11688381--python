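"""Read quarterly packages, join the tables and collapse follow-up reports.

Run 01_simulate_database.py first.  Prints the conservation accounting of
the join and the dedup report: with 10% duplicate injection, 11,000 reports
collapse back to exactly 10,000 cases.
"""

from pvsignal import deduplicate
from pvsignal.io import assemble_cases, read_package

tables = read_package("scratch/example_db")
print({kind: len(df) for kind, df in tables.items()})

assembly = assemble_cases(tables)
print(f"assembled {len(assembly.cases)} reports; attached rows {assembly.attached}; "
      f"unmatched {assembly.unmatched}")

cases, report = deduplicate(assembly.cases)
print(f"{report.n_input} reports -> {report.n_kept} cases "
      f"({report.n_dropped_followup} follow-ups dropped, "
      f"{report.n_dropped_exact} exact duplicates)")
# every kept case now has a unique caseid; the kept report per case is the
# one with the latest FDA receipt date (ties: larger primaryid)
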