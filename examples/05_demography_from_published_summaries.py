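"""Breeding effort, recruitment and post-fledging loss from the published
annual summaries of the five-roost southern-Pantanal study.

The singleton percentage (Aug-Sep singletons / Jun-Jul total) is a minimum
proportion of pairs attempting to breed; the fledgling percentage measures
recruitment about six months after fledging.  Their gap estimates
post-fledging mortality.
"""
import roostcount as rc
from roostcount import reference

totals = rc.median_iqr(reference.annual_values("pooled", "all_parrots"))
singles = rc.median_iqr(reference.annual_values("pooled", "singles_pct"))
fledglings = rc.median_iqr(reference.annual_values("pooled", "fledglings_pct"))

print(f"pooled Jun-Jul total:   median {totals.median:.1f} (IQR {totals.iqr:.1f})")
print(f"singleton percentage:   median {singles.median:.1f}% (IQR {singles.iqr:.1f})")
print(f"fledgling percentage:   median {fledglings.median:.1f}% (IQR {fledglings.iqr:.1f})")

rec_singleton = rc.expected_recruits(singles.median, totals.median, fledge_rate=1.0)
rec_fledgling = rc.expected_recruits(fledglings.median, totals.median, fledge_rate=1.0)
loss = rc.post_fledging_loss(rec_singleton, rec_fledgling)

print(f"\nexpected recruits, singleton-based: {rec_singleton} young/year")
print(f"expected recruits, fledgling-based: {rec_fledgling} young/year")
print(f"implied post-fledging loss:         {100 * loss:.0f}%")

# The fledgling-based estimate counts survivors ~6 months after fledging;
# the singleton-based one counts breeding attempts, so their ratio bounds
# first-months mortality of the fledged young.
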