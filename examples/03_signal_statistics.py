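"""The three disproportionality statistics on a single 2x2 table.

20 of 100 target-drug reports mention the event versus 100 of 9,900 reports
for all other drugs: a strong signal by every method.
"""

from pvsignal import ContingencyTable, compute_signal

table = ContingencyTable(a=20, b=80, c=100, d=9800)
r = compute_signal("example drug", table, n_draws=100_000, seed=1)

print(f"ROR  {r.ror:6.2f}  (95% CI {r.ror_lo:.2f}-{r.ror_hi:.2f})  flag={r.flag_ror}")
print(f"PRR  {r.prr:6.2f}  chi2 {r.chi2:.1f}                 flag={r.flag_prr}")
print(f"IC   {r.ic:6.2f}  (IC025 {r.ic025:.2f}, IC975 {r.ic975:.2f})  flag={r.flag_bcpnn}")
print(f"consensus positive: {r.positive}")
# ROR = ad/bc = 24.5; PRR = a(c+d)/(c(a+b)) = 19.8; IC = log2(aN/((a+b)(a+c)))
# ~ 4.06 bits, i.e. the event is reported ~16.7x more often with the drug
# than independence predicts.  Flags: ROR needs a>=3 and CI low > 1; PRR
# needs a>=3, PRR>=2 and chi2>=4; BCPNN needs IC025 > 0.
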