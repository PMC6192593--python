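"""Permutation ANOVA: do counts vary over months, and differently by roost?

F statistics use sequential (type-I) sums of squares; p-values come from
resampling (response permutation for one term, Freedman-Lane residual
permutation with several terms), not from F-distribution theory.
"""
import roostcount as rc
from roostcount.permutation import ModelSpec, permutation_test

table = rc.generate(rc.default_config(), seed=42)

pooled = rc.pool_roosts(table).df
month_only = ModelSpec.build("all_parrots", ["month"], kinds={"month": "factor"})
res = permutation_test(month_only, pooled, n_perm=4999, seed=7)
term = res.term("month")
print(f"pooled ~ month:        F({term.df[0]}, {term.df[1]}) = {term.F:.2f}, "
      f"p_perm = {term.p_perm:.4g}, r2 = {res.r2:.2f}")

interaction = ModelSpec.from_formula("all_parrots ~ roost * month")
res2 = permutation_test(interaction, table.df, n_perm=999, seed=7)
for t in res2.terms:
    print(f"  {t.name:>12}: F({t.df[0]}, {t.df[1]}) = {t.F:6.2f}, p_perm = {t.p_perm:.4g}")
print(f"full model R2 = {res2.r2:.2f}")

# A significant roost x month interaction means the roosts follow different
# seasonal patterns, so each roost's series must be decomposed separately.
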