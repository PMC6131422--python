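"""Chi-square association and the allele-frequency contrast rule.

The chi-square tests whether the pooled allele counts differ between the
bulks; the contrast rule additionally demands an allele at >= 50% in one
bulk and <= 50% in the other.
"""

import tetrabsa as tb

# a site fixed for the reference in one bulk and heterozygous in the other
stat, df, p = tb.chi_square([25, 0], [13, 14])
print(f"counts (25,0) vs (13,14): chi2={stat:.3f} df={df} p={p:.3g}")

# the 48%/52% heterozygous low bulk vs a fixed high bulk passes the rule
print("rule, 1.00/0.00 vs 0.48/0.52:", tb.contrast_rule([0.48, 0.52], [1.00, 0.00]))
# a 100% vs 71%/29% site fails the literal >=50/<=50 predicate
print("rule, 1.00/0.00 vs 0.71/0.29:", tb.contrast_rule([0.71, 0.29], [1.00, 0.00]))
# identical 50/50 bulks carry no between-bulk difference
print("rule, 0.50/0.50 vs 0.50/0.50:", tb.contrast_rule([0.5, 0.5], [0.5, 0.5]))

print(
    "A small p with a passing rule marks a trait-associated variant candidate; "
    "sites differing only within a bulk, or without an allele crossing the 50% "
    "line in opposite directions, are excluded."
)
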