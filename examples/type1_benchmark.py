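"""Estimate empirical type I error for a row of the virtual benchmark.

Replays the null scenario with 10 CpGs from a common beta marginal
(mean 0.6) at exchangeable correlation r = 0.8, at a reduced replication
count so the example runs in seconds.  Under the null every calibrated test
should reject close to the nominal 5%; the Bonferroni min-p t-test is
expected to be conservative (well below 0.05) at this strong correlation.
"""

import cpgset as cp

scenario = cp.get_scenario("1.1", r=0.8, null=True)
summaries = cp.estimate_rejection_rate(
    scenario, ["pca", "skat", "sir", "t2", "minp_t"],
    n_replications=300, alpha=0.05, base_seed=2016,
)
print(f"{'method':<8} {'type I error':>12} {'MC s.e.':>9}")
for s in summaries:
    print(f"{s.method:<8} {s.rejection_rate:>12.4f} {s.mc_standard_error:>9.4f}")
print("\nAt 300 replications the Monte Carlo s.e. is ~0.013; rates within "
      "~2-3 s.e. of 0.05 are consistent with a calibrated test.")
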