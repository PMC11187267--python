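"""Causal-effect estimators for two-sample MR on harmonized instruments.

Five estimators are provided, each pooling per-SNP Wald ratios
(beta_out / beta_exp) under different validity assumptions:

* ``ivw`` — inverse-variance-weighted meta-analysis of the Wald ratios; the
  primary estimator.  Fixed-effect or multiplicative random-effects (the
  default, inflating the SE by max(1, sqrt(Q/(k-1)))).
* ``mr_egger`` — weighted regression of outcome on exposure effects with a
  free intercept; the intercept estimates directional pleiotropy.
* ``weighted_median`` — consistent when instruments carrying at least half
  the weight are valid.
* ``mode_estimate`` (simple / weighted) — mode of the kernel-smoothed Wald
  ratio density; consistent when the largest cluster of similar ratios is
  valid.

All binary-trait effects are on the log-odds scale; estimates are reported
with their odds-ratio transform exp(beta) and a normal-theory 95% CI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .harmonization import HarmonizedInstrument, kept_instruments

Z_95 = 1.959964


class EstimatorError(ValueError):
    pass


@dataclass(frozen=True)
class MREstimate:
    """A causal estimate on the log-odds scale with its OR form."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    or_value: float
    ci_low: float
    ci_high: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None


def to_odds_ratio(beta: float, se: float, z: float = Z_95) -> tuple[float, float, float]:
    """(OR, CI low, CI high) = exp(beta), exp(beta -+ z*se)."""
    if se < 0:
        raise EstimatorError("se must be >= 0")
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se)


def _make_estimate(method, beta, se, pval, n_snp, **kw) -> MREstimate:
    or_value, ci_low, ci_high = to_odds_ratio(beta, se)
    return MREstimate(method, float(beta), float(se), float(pval), n_snp, or_value, ci_low, ci_high, **kw)


def _arrays(insts: Sequence[HarmonizedInstrument]):
    insts = kept_instruments(list(insts))
    bx = np.array([h.beta_exp for h in insts], dtype=float)
    sx = np.array([h.se_exp for h in insts], dtype=float)
    by = np.array([h.beta_out for h in insts], dtype=float)
    sy = np.array([h.se_out for h in insts], dtype=float)
    rsids = [h.rsid for h in insts]
    return bx, sx, by, sy, rsids


def wald_ratios(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ratio estimates and first-order delta-method SEs."""
    if np.any(bx == 0):
        raise EstimatorError("undefined Wald ratio: beta_exp = 0")
    return by / bx, sy / np.abs(bx)


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-SNP causal estimate beta_out / beta_exp."""
    bx, _, by, sy, _ = _arrays([inst])
    r, s = wald_ratios(bx, by, sy)
    p = 2 * stats.norm.sf(abs(r[0] / s[0]))
    return _make_estimate("wald", r[0], s[0], p, 1)


def _ivw_fixed(ratios: np.ndarray, ses: np.ndarray) -> tuple[float, float, float]:
    """Fixed-effect pooled estimate, its SE, and Cochran's Q."""
    w = 1.0 / ses**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (ratios - beta) ** 2))
    return beta, se, q


def ivw(
    insts: Sequence[HarmonizedInstrument], mode: str = "multiplicative_random"
) -> MREstimate:
    """Inverse-variance-weighted meta-analysis of the Wald ratios."""
    if mode not in ("fixed", "multiplicative_random"):
        raise EstimatorError(f"unknown IVW mode {mode!r}")
    bx, _, by, sy, _ = _arrays(insts)
    k = len(bx)
    if k < 1:
        raise EstimatorError("no_instruments")
    if k == 1:
        est = wald_ratio(kept_instruments(list(insts))[0])
        return _make_estimate("ivw", est.beta, est.se, est.pval, 1)
    ratios, ses = wald_ratios(bx, by, sy)
    beta, se, q = _ivw_fixed(ratios, ses)
    if mode == "multiplicative_random":
        se *= max(1.0, math.sqrt(q / (k - 1)))
    p = 2 * stats.norm.sf(abs(beta / se))
    return _make_estimate("ivw", beta, se, p, k)


def _orient_positive(bx, by):
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign


def mr_egger(insts: Sequence[HarmonizedInstrument]) -> MREstimate:
    """Weighted regression of beta_out on beta_exp with a free intercept.

    Instruments are oriented so all exposure effects are positive (the fit is
    not orientation-invariant).  SEs use multiplicative random-effects
    scaling floored at 1; p-values use the t distribution on k - 2 df.
    """
    bx, _, by, sy, _ = _arrays(insts)
    k = len(bx)
    if k < 3:
        raise EstimatorError("insufficient_instruments")
    bx, by = _orient_positive(bx, by)
    w = 1.0 / sy**2
    # Closed-form weighted least squares with intercept.
    sw = w.sum()
    mx = np.sum(w * bx) / sw
    my = np.sum(w * by) / sw
    sxx = np.sum(w * (bx - mx) ** 2)
    sxy = np.sum(w * (bx - mx) * (by - my))
    slope = sxy / sxx
    intercept = my - slope * mx
    resid = by - intercept - slope * bx
    rss = np.sum(w * resid**2)
    sigma2 = rss / (k - 2)
    scale = max(1.0, sigma2)  # multiplicative random effects, floored at 1
    se_slope = math.sqrt(scale / sxx)
    se_int = math.sqrt(scale * (1.0 / sw + mx**2 / sxx))
    p_slope = 2 * stats.t.sf(abs(slope / se_slope), df=k - 2)
    p_int = 2 * stats.t.sf(abs(intercept / se_int), df=k - 2)
    return _make_estimate(
        "egger",
        slope,
        se_slope,
        p_slope,
        k,
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_p=float(p_int),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, v))


def _bootstrap_se(bx, sx, by, sy, weights_from, point_fn, n_boot, seed) -> float:
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxi = rng.normal(bx, sx)
        byi = rng.normal(by, sy)
        bxi = np.where(bxi == 0, 1e-300, bxi)
        r = byi / bxi
        s = sy / np.abs(bxi)
        boots[i] = point_fn(r, weights_from(s))
    return float(np.std(boots, ddof=1))


def weighted_median(
    insts: Sequence[HarmonizedInstrument], n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of the Wald ratios (inverse-variance weights).

    The SE comes from a parametric bootstrap resampling each
    (beta_exp, beta_out) from its normal sampling distribution.
    """
    bx, sx, by, sy, _ = _arrays(insts)
    k = len(bx)
    if k < 3:
        raise EstimatorError("insufficient_instruments")
    ratios, ses = wald_ratios(bx, by, sy)
    beta = _weighted_median(ratios, 1.0 / ses**2)
    se = _bootstrap_se(
        bx, sx, by, sy, lambda s: 1.0 / s**2, _weighted_median, n_boot, seed
    )
    p = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else (0.0 if beta != 0 else 1.0)
    return _make_estimate("weighted_median", beta, se, p, k)


def _mbe_bandwidth(ratios: np.ndarray, bandwidth_factor: float) -> float:
    # Modified Silverman rule on the ratio scale.
    n = len(ratios)
    sd = float(np.std(ratios, ddof=1))
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    spread = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    return bandwidth_factor * 0.9 * spread * n ** (-1.0 / 5.0)


def smoothed_ratio_density(x: np.ndarray, ratios: np.ndarray, weights: np.ndarray, h: float) -> np.ndarray:
    """Weighted normal-kernel density of the Wald ratios evaluated at x."""
    w = weights / weights.sum()
    return np.sum(w[None, :] * stats.norm.pdf(x[:, None], loc=ratios[None, :], scale=h), axis=1)


def _density_mode(ratios: np.ndarray, weights: np.ndarray, h: float) -> float:
    lo = ratios.min() - 3 * h
    hi = ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 2048)
    dens = smoothed_ratio_density(grid, ratios, weights, h)
    i = int(np.argmax(dens))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]

    # Direct maximization of a smooth density can only localize the mode to
    # about sqrt(machine-eps); refine by finding the zero of the analytic
    # derivative instead, which is accurate to full float precision.
    w = weights / weights.sum()

    def ddx(x):
        z = (x - ratios) / h
        return float(np.sum(w * -z / h * stats.norm.pdf(z) / h))

    da, db = ddx(a), ddx(b)
    if da > 0 > db:
        return float(optimize.brentq(ddx, a, b, xtol=1e-15))
    res = optimize.minimize_scalar(
        lambda x: -smoothed_ratio_density(np.array([x]), ratios, weights, h)[0],
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-13},
    )
    return float(res.x)


def mode_estimate(
    insts: Sequence[HarmonizedInstrument],
    variant: str = "weighted",
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode of the kernel-smoothed Wald-ratio density (mode-based estimate).

    ``variant="simple"`` weights every ratio equally; ``"weighted"`` uses
    inverse-variance weights.  If all ratios coincide the bandwidth is zero
    and that common ratio is returned directly.
    """
    if variant not in ("simple", "weighted"):
        raise EstimatorError(f"unknown mode variant {variant!r}")
    bx, sx, by, sy, _ = _arrays(insts)
    k = len(bx)
    if k < 3:
        raise EstimatorError("insufficient_instruments")
    ratios, ses = wald_ratios(bx, by, sy)

    def weights_from(s):
        return 1.0 / s**2 if variant == "weighted" else np.ones_like(s)

    def point(r, w):
        h = _mbe_bandwidth(r, bandwidth_factor)
        if h == 0 or np.ptp(r) == 0:
            return float(r[0])
        return _density_mode(r, w, h)

    beta = point(ratios, weights_from(ses))
    se = _bootstrap_se(bx, sx, by, sy, weights_from, point, n_boot, seed)
    p = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else (0.0 if beta != 0 else 1.0)
    method = "simple_mode" if variant == "simple" else "weighted_mode"
    return _make_estimate(method, beta, se, p, k)


#: Estimator registry used by the pipeline layer.
ALL_METHODS = ("ivw", "egger", "weighted_median", "weighted_mode", "simple_mode")


def estimate_all(
    insts: Sequence[HarmonizedInstrument],
    ivw_mode: str = "multiplicative_random",
    n_boot: int = 1000,
    seed: int = 0,
) -> list[MREstimate]:
    """Run every estimator whose instrument-count precondition is met."""
    kept = kept_instruments(list(insts))
    k = len(kept)
    out: list[MREstimate] = []
    if k >= 1:
        out.append(ivw(kept, mode=ivw_mode))
    if k >= 3:
        out.append(mr_egger(kept))
        out.append(weighted_median(kept, n_boot=n_boot, seed=seed))
        out.append(mode_estimate(kept, "weighted", n_boot=n_boot, seed=seed + 1))
        out.append(mode_estimate(kept, "simple", n_boot=n_boot, seed=seed + 2))
    return out
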