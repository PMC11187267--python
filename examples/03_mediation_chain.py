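"""Two-step MR mediation: how much of the total effect flows via a mediator?

Simulates an exposure -> mediator -> outcome chain with direct effect 0.3
and mediated path 0.2 * 0.5 = 0.1 (true proportion mediated = 25%), then
estimates the mediated share by the product-of-coefficients method with a
delta-method confidence interval.
"""

from mrmediate import SimulationConfig, run_mediation, simulate_chain

config = SimulationConfig(seed=13)  # theta_direct 0.3, b1 0.2, b2 0.5
exposure, mediator, outcome, truth = simulate_chain(config)
print(f"true proportion mediated: {truth['true_proportion']:.1%}")

results, ledger = run_mediation(exposure, [mediator], outcome)
r = results[0]
print(f"b1 (exposure -> mediator)  = {r.b1:+.4f} (SE {r.se1:.4f})")
print(f"b2 (mediator -> outcome)   = {r.b2:+.4f} (SE {r.se2:.4f})")
print(f"total (exposure -> outcome)= {r.total:+.4f} (SE {r.se_total:.4f})")
print(f"indirect effect            = {r.indirect:+.4f} (SE {r.se_indirect:.4f})")
print(f"proportion mediated        = {r.proportion_pct:.1f}% "
      f"(95% CI {r.ci_pct[0]:.1f}% to {r.ci_pct[1]:.1f}%)")
overlap = ledger.count(reason="exposure_instrument_overlap")
print(f"exposure instruments excluded from the mediator leg: {overlap}")
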