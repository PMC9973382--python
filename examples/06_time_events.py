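"""Infer the chronological order of somatic events from CCF rankings.

Events with higher cancer cell fraction are present in more tumor cells
and hence inferred earlier. Per-tumor partial rankings feed a
Plackett-Luce model; bootstrap over tumors gives a 95% CI on each
event's rank position.
"""

from panhallmark.synthdata import generate_event_orderings
from panhallmark.timing import (bootstrap_timing_ci, build_rankings,
                                fit_plackett_luce)

truth = {"TP53_mut": 8.0, "5q_del": 4.0, "WGD": 2.0, "8q_amp": 1.0}
orderings = generate_event_orderings(truth, n_tumors=100, missing_rate=0.2,
                                     seed=11)
rankings = build_rankings(orderings[["tumor", "event", "ccf"]])
fit = fit_plackett_luce(rankings, seed=11)
ci = bootstrap_timing_ci(rankings, B=500, seed=11)

print(f"tumors used: {rankings.ranks.shape[0]}  "
      f"(20% of events unobserved per tumor)")
print(f"inferred order (earliest first): {' -> '.join(fit.order)}")
print("\nworths and 95% CI of rank position (1 = earliest):")
for e in fit.order:
    print(f"  {e:10s} worth={fit.worths[e]:.3f}  "
          f"rank CI [{ci.loc[e, 'ci_low']:.1f}, {ci.loc[e, 'ci_high']:.1f}]")
print("\nTrue worths were 8:4:2:1, so the correct order is TP53_mut ->")
print("5q_del -> WGD -> 8q_amp; tight CIs mean the order is stable under")
print("resampling of tumors.")
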