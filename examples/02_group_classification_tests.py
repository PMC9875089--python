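"""Group-level tests on the built-in reference classification tables.

For each behavior x genotype cell, tests the left/ambilateral/right animal
counts against a uniform (random) distribution, runs gated binomial
post-hocs, and verifies the recomputed statistics against the values the
original analysis reported — flagging the one misprinted cell.
"""

import warnings

from laterality.datasets import reported_tables, verify_reported_statistics
from laterality.group_tests import chi2_random_distribution

print("behavior genotype   L  A  R    chi2      p  post-hocs (Bonferroni)")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # several cells have expected counts < 5
    for table in reported_tables():
        res = chi2_random_distribution(table)
        ph = "; ".join(
            f"{p.comparison} p={p.p_adjusted:.3f}" for p in res.posthocs
            if p.p_adjusted is not None
        )
        print(f"{table.behavior:>8} {table.genotype:>8} {table.n_left:>3}"
              f" {table.n_ambi:>2} {table.n_right:>2} {res.chi2:>7.3f}"
              f" {res.p:>6.3f}  {ph}")

check = verify_reported_statistics()
flagged = check[check["discrepant"]]
print("\ncells whose recomputed chi2 disagrees with the reported statistic:")
print(flagged[["behavior", "genotype", "chi2", "reported_chi2", "p",
               "reported_p"]].round(3).to_string(index=False))
print("\nSelf-grooming is dominated by ambilateral animals (both post-hocs")
print("reject), and the FRT/KO cell reproduces the reported p = 0.078 but")
print("not the reported statistic of 2 - an evident misprint (chi2 = 5.09).")
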