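"""Severe-asthma vs healthy feature comparison, intersected across cohorts.

Severe asthma = treatment intensity GINA step 4-5. Every variable is compared
between severe and healthy subjects by a two-sample K-S test per cohort, and
features significant with the same direction in BOTH cohorts are reported
(the study's Table-III-style analysis).
"""

from endomapper import RunConfig, default_study_config, run_study, sample_cohort
from endomapper.pipeline import severe_vs_healthy

config = default_study_config(seed=2)
per_cohort = {}
for cid in ("derivation", "validation"):
    table, _ = sample_cohort(config, cid, seed=2)
    results = severe_vs_healthy(table)
    per_cohort[cid] = {(r.feature, r.direction) for r in results}
    print(f"{cid}: {len(results)} features differ (top 5 by K-S score):")
    for r in results[:5]:
        print(f"  {r.feature}: D={r.ks_score:.2f}, p={r.p_value:.2g}, {r.direction}")

common = per_cohort["derivation"] & per_cohort["validation"]
inc = sorted(f for f, d in common if d == "higher")
dec = sorted(f for f, d in common if d == "lower")
print(f"\nsignificant in BOTH cohorts: {len(inc)} increased, {len(dec)} decreased")
print("increased:", ", ".join(inc[:12]), "...")
print("decreased:", ", ".join(dec[:12]), "...")
# The planted severe signature (raised YKL-40, MMPs, IL-5/6/8; depressed
# TIMP-1, FGF, IL-2, lung function) should dominate both lists.
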