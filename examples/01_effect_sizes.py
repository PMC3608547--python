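"""Convert reported test statistics to correlations and Fisher's Z.

Primary studies report t, F, chi-square or p values; meta-analysis needs
a common, variance-stabilised scale.  Each statistic becomes a signed
Pearson r, then Fisher's Z with sampling variance 1/(n-3).
"""

from metacare import EffectSize, TestStatistic, statistic_to_r

reported = [
    ("t test",      TestStatistic("t", 2.5, df1=23, n=25, sign=1)),
    ("F test",      TestStatistic("F", 4.0, df1=1, df2=30, n=32, sign=-1)),
    ("chi-square",  TestStatistic("chi2", 3.84, df1=1, n=100, sign=1)),
    ("p value",     TestStatistic("p_two_tailed", 0.04, n=60, sign=1)),
]

print(f"{'source':<12}{'r':>9}{'Zr':>9}{'var(Zr)':>10}{'weight':>9}")
for label, stat in reported:
    es = EffectSize.from_statistic(stat)
    print(f"{label:<12}{es.r:>9.3f}{es.zr:>9.3f}{es.var_zr:>10.4f}{es.weight:>9.1f}")

print("\nPositive r: paternal care declines when paternity is lost.")
print("Weights (n-3) let precise studies dominate the pooled effect.")
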