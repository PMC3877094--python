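"""Group-wise differential filter on a small simulated cohort.

Simulates 4 disease + 4 baseline arrays with planted effects, runs every
pairwise comparison (16 per probe-set) and applies the homogeneous /
heterogeneous significance queries.
"""

from ifnsig import FilterConfig, SimulationConfig, simulate_cohort
from ifnsig.diff_filter import run_group_filter

config = SimulationConfig(
    n_common=10, n_disease_specific=10, n_immunisation_specific=0,
    n_non_ifn_de=5, n_null=75, n_absent=5,
)
cohort = simulate_cohort(config, seed=42)
significant, table = run_group_filter(
    cohort.groups["disease"], cohort.groups["baseline"], FilterConfig()
)

print(f"{len(significant)} of {len(table)} probe-sets significant\n")
print(table.head(8)[["probeset_id", "pct_increase", "mean_log2fc", "bonf_p", "category"]]
      .to_string(index=False))

true_de = (
    cohort.truth.probesets_of_class("common_ifn")
    | cohort.truth.probesets_of_class("disease_specific")
    | cohort.truth.probesets_of_class("non_ifn_de")
)
tp = len(set(significant) & true_de)
print(f"\n{tp}/{len(true_de)} planted differential probe-sets recovered, "
      f"{len(significant) - tp} false positives.")
print("Each row summarises 16 pairwise change calls; 'category' names the\n"
      "query that selected the probe-set (homogeneous = call fraction +\n"
      "Bonferroni t-test, heterogeneous = call fraction alone).")
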