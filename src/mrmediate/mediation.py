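"""Two-step MR mediation: indirect effects, proportion mediated, uncertainty.

For each candidate mediator M between exposure X and outcome Y, three
univariable MR estimates are combined on the log-odds scale:

* b1 — X -> M, using the exposure's instruments;
* b2 — M -> Y, using the mediator's own instruments;
* total — X -> Y, using the exposure's instruments.

The indirect effect is the product b1*b2 with the first-order product
(Sobel) standard error sqrt(b1^2 se2^2 + b2^2 se1^2); the proportion
mediated is indirect/total with a delta-method CI treating the two legs and
the total as independent (they come from non-overlapping samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .estimators import EstimatorError, Z_95, ivw
from .harmonization import harmonize_pair, kept_instruments
from .instruments import ClumpParams, select_instruments
from .summary_data import ExclusionLedger, SummaryDataset


class MediationError(ValueError):
    pass


@dataclass(frozen=True)
class MediationResult:
    mediator_name: str
    b1: float
    se1: float
    b2: float
    se2: float
    total: float
    se_total: float
    indirect: float
    se_indirect: float
    proportion: float
    se_proportion: float
    ci_low: float
    ci_high: float
    pval: float
    inconsistent: bool  # indirect and total of opposite sign

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion

    @property
    def ci_pct(self) -> tuple[float, float]:
        return 100.0 * self.ci_low, 100.0 * self.ci_high


def indirect_effect(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Product-of-coefficients indirect effect and its Sobel SE."""
    if not (se1 > 0 and se2 > 0):
        raise MediationError("leg standard errors must be positive")
    indirect = b1 * b2
    se = math.sqrt(b1**2 * se2**2 + b2**2 * se1**2)
    return indirect, se


def proportion_mediated(
    indirect: float, se_indirect: float, total: float, se_total: float
) -> tuple[float, float, float, float, float]:
    """(proportion, se, ci_low, ci_high, p) for the mediated share.

    The SE treats the total as estimated, with zero covariance between the
    indirect and total legs (independent samples): the full ratio-variance
    delta form var(p) = var(ind)/total^2 + ind^2 var(total)/total^4.  The
    p-value tests the indirect effect itself (Sobel z), not the ratio.
    """
    if total == 0:
        raise MediationError("undefined_proportion: total effect is zero")
    prop = indirect / total
    var_p = se_indirect**2 / total**2 + indirect**2 * se_total**2 / total**4
    se_p = math.sqrt(var_p)
    ci_low, ci_high = prop - Z_95 * se_p, prop + Z_95 * se_p
    p = 2 * stats.norm.sf(abs(indirect / se_indirect)) if se_indirect > 0 else float(indirect == 0)
    return prop, se_p, ci_low, ci_high, p


def _mr_leg(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    leg_name: str,
    params: ClumpParams,
    f_min: float,
    af_window: tuple[float, float],
    ivw_mode: str,
    ledger: ExclusionLedger,
    drop_rsids: frozenset[str] = frozenset(),
):
    selected, led = select_instruments(exposure, params=params, f_min=f_min)
    ledger.extend(led)
    if drop_rsids:
        overlap = [r for r in selected.rsids if r in drop_rsids]
        for rsid in overlap:
            ledger.add(rsid, leg_name, "exposure_instrument_overlap")
        selected = selected.subset([r for r in selected.rsids if r not in drop_rsids])
    if len(selected) == 0:
        raise MediationError(f"no_instruments in leg {leg_name}")
    insts, led2 = harmonize_pair(selected, outcome, af_window)
    ledger.extend(led2)
    kept = kept_instruments(insts)
    if not kept:
        raise MediationError(f"no harmonized instruments in leg {leg_name}")
    try:
        return ivw(kept, mode=ivw_mode)
    except EstimatorError as exc:
        raise MediationError(f"estimation failed in leg {leg_name}: {exc}") from exc


def run_mediation(
    exposure_ds: SummaryDataset,
    mediator_ds_list: Sequence[SummaryDataset],
    outcome_ds: SummaryDataset,
    params: ClumpParams = ClumpParams(),
    f_min: float = 10.0,
    af_window: tuple[float, float] = (0.42, 0.58),
    ivw_mode: str = "multiplicative_random",
) -> tuple[list[MediationResult], ExclusionLedger]:
    """Estimate the mediated share of the exposure->outcome effect per mediator.

    Each leg is a univariable IVW MR with its own instrument selection:
    the exposure's instruments for b1 and the total effect, the mediator's
    own instruments for b2.  Variants that are themselves exposure
    instruments are excluded from the mediator's set (their outcome
    association runs through the exposure's direct path, which would
    contaminate b2); no multivariable adjustment is applied beyond that, a
    surfaced limitation.
    """
    ledger = ExclusionLedger()
    exposure_instruments = frozenset(
        r.rsid for r in exposure_ds if r.pval < params.p_threshold
    )
    total_est = _mr_leg(
        exposure_ds, outcome_ds, "exposure->outcome", params, f_min, af_window, ivw_mode, ledger
    )
    results = []
    for med in mediator_ds_list:
        est1 = _mr_leg(
            exposure_ds, med, f"exposure->{med.trait_name}", params, f_min, af_window, ivw_mode, ledger
        )
        est2 = _mr_leg(
            med, outcome_ds, f"{med.trait_name}->outcome", params, f_min, af_window, ivw_mode, ledger,
            drop_rsids=exposure_instruments,
        )
        ind, se_ind = indirect_effect(est1.beta, est1.se, est2.beta, est2.se)
        prop, se_p, lo, hi, p = proportion_mediated(ind, se_ind, total_est.beta, total_est.se)
        results.append(
            MediationResult(
                mediator_name=med.trait_name,
                b1=est1.beta,
                se1=est1.se,
                b2=est2.beta,
                se2=est2.se,
                total=total_est.beta,
                se_total=total_est.se,
                indirect=ind,
                se_indirect=se_ind,
                proportion=prop,
                se_proportion=se_p,
                ci_low=lo,
                ci_high=hi,
                pval=p,
                inconsistent=(ind * total_est.beta < 0),
            )
        )
    return results, ledger
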