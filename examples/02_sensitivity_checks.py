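"""Sensitivity battery: heterogeneity, pleiotropy, outliers.

Simulates a clean study, then plants a single 10-standard-error pleiotropic
outlier and shows how Cochran's Q, the MR-Egger intercept, leave-one-out,
radial MR and MR-PRESSO each react.
"""

from mrmediate import (
    cochran_q,
    egger_intercept_test,
    harmonize_pair,
    kept_instruments,
    leave_one_out,
    mr_presso,
    plant_outliers,
    radial_mr,
    simulate_pair,
)

exposure, outcome, _ = simulate_pair(theta=0.443, seed=21)
target = exposure.rsids[0]
outcome = plant_outliers(outcome, [target], shift=10 * outcome[target].se)
instruments, _ = harmonize_pair(exposure, outcome)
kept = kept_instruments(instruments)
print(f"planted outlier: {target}")

q = cochran_q(kept, "ivw")
print(f"Cochran's Q = {q.q_stat:.1f} on {q.df} df, p = {q.pval:.2e}")

icpt, se, p = egger_intercept_test(kept)
print(f"Egger intercept = {icpt:+.4f} (SE {se:.4f}), p = {p:.3f}")

loo = leave_one_out(kept).set_index("omitted")
most_influential = loo.drop(index="none (all SNPs)")["beta"].idxmin()
print(f"leave-one-out: largest downward shift when omitting {most_influential}")

radial = radial_mr(kept)
print(f"radial MR outliers: {radial.outlier_rsids}")

presso = mr_presso(kept, n_sim=1000, seed=1)
print(f"MR-PRESSO global p = {presso.global_p:.4f}, outliers: {presso.outlier_rsids}")
print(f"  outlier-corrected IVW beta = {presso.corrected.beta:.3f}")
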