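"""Generate a synthetic five-roost study, validate it, and summarise it.

Counts arriving at a roost are stratified by flock size; the strata must
satisfy  all = singles + 2*pairs + family_flock_birds + large_flock_birds.
The annual summary expresses each stratum as a percentage of the June-July
attendance maximum (the population denominator).
"""
import roostcount as rc

table = rc.generate(rc.default_config(), seed=42)
violations = rc.validate_counts(table)
print(f"{len(table)} monthly records across {len(table.roosts())} roosts; "
      f"{len(violations)} stratification violations")

summary = rc.summary_table(table)
pooled = summary[summary["roost"] == "pooled"]
print("\nPooled annual summaries (median / IQR over years):")
for _, row in pooled.iterrows():
    print(f"  {row['stratum']:>15}: median {row['median']:8.2f}   IQR {row['iqr']:7.2f}")

# The singles_pct median is the minimum percentage of birds whose pair
# attempted to breed (one pair member roosts alone during incubation).
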