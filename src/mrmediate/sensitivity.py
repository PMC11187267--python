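"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

The suite covers Cochran's Q (IVW and Egger residual forms), the MR-Egger
intercept test for directional pleiotropy, leave-one-out influence analysis,
funnel-plot data, radial MR with per-SNP Q contributions, and MR-PRESSO
(global residual test, per-SNP outlier test, and distortion test, all by
parametric simulation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, _arrays, _ivw_fixed, ivw, mr_egger, wald_ratios
from .harmonization import HarmonizedInstrument, kept_instruments


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class HeterogeneityResult:
    method: str  # ivw | egger
    q_stat: float
    df: int
    pval: float


@dataclass(frozen=True)
class RadialResult:
    beta: float
    se: float
    q_stat: float
    q_per_snp: dict[str, float]
    outlier_rsids: list[str]
    n_iterations: int


@dataclass(frozen=True)
class PressoResult:
    global_rss: float
    global_p: float
    outlier_rsids: list[str]
    distortion_p: float | None
    corrected: MREstimate | None
    n_sim: int


def cochran_q(insts: Sequence[HarmonizedInstrument], method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q heterogeneity test around the IVW or Egger fit.

    Q = sum_j w_j (ratio_j - fit_j)^2 with inverse ratio-variance weights for
    IVW (df = k-1), or the weighted residual sum of squares of the Egger
    regression (df = k-2).
    """
    bx, _, by, sy, _ = _arrays(insts)
    k = len(bx)
    if method == "ivw":
        if k < 2:
            raise SensitivityError("insufficient_instruments")
        ratios, ses = wald_ratios(bx, by, sy)
        _, _, q = _ivw_fixed(ratios, ses)
        df = k - 1
    elif method == "egger":
        if k < 3:
            raise SensitivityError("insufficient_instruments")
        est = mr_egger(insts)
        sign = np.where(bx < 0, -1.0, 1.0)
        bxo, byo = bx * sign, by * sign
        resid = byo - est.intercept - est.beta * bxo
        q = float(np.sum(resid**2 / sy**2))
        df = k - 2
    else:
        raise SensitivityError(f"unknown method {method!r}")
    return HeterogeneityResult(method, float(q), df, float(stats.chi2.sf(q, df)))


def egger_intercept_test(insts: Sequence[HarmonizedInstrument]) -> tuple[float, float, float]:
    """(intercept, se, two-sided p) for directional pleiotropy."""
    est = mr_egger(insts)
    return est.intercept, est.intercept_se, est.intercept_p


def leave_one_out(
    insts: Sequence[HarmonizedInstrument], ivw_mode: str = "multiplicative_random"
) -> pd.DataFrame:
    """IVW re-estimated with each SNP omitted, plus the all-SNP row.

    Flags omissions that change the estimate's sign or whether its 95% CI
    excludes the null.
    """
    kept = kept_instruments(list(insts))
    k = len(kept)
    if k < 3:
        raise SensitivityError("insufficient_instruments")
    full = ivw(kept, mode=ivw_mode)
    rows = []
    full_sig = full.ci_low > 1.0 or full.ci_high < 1.0
    for omit in kept:
        sub = [h for h in kept if h.rsid != omit.rsid]
        est = ivw(sub, mode=ivw_mode)
        sig = est.ci_low > 1.0 or est.ci_high < 1.0
        rows.append(
            {
                "omitted": omit.rsid,
                "n_snp": est.n_snp,
                "beta": est.beta,
                "se": est.se,
                "or": est.or_value,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "influential": (np.sign(est.beta) != np.sign(full.beta)) or (sig != full_sig),
            }
        )
    rows.append(
        {
            "omitted": "none (all SNPs)",
            "n_snp": full.n_snp,
            "beta": full.beta,
            "se": full.se,
            "or": full.or_value,
            "ci_low": full.ci_low,
            "ci_high": full.ci_high,
            "pval": full.pval,
            "influential": False,
        }
    )
    return pd.DataFrame(rows)


def funnel_data(insts: Sequence[HarmonizedInstrument]) -> tuple[pd.DataFrame, dict]:
    """Per-SNP (Wald ratio, precision = 1/SE) plus IVW/Egger reference lines."""
    kept = kept_instruments(list(insts))
    if not kept:
        return pd.DataFrame(columns=["rsid", "ratio", "precision"]), {}
    bx, _, by, sy, rsids = _arrays(kept)
    ratios, ses = wald_ratios(bx, by, sy)
    table = pd.DataFrame({"rsid": rsids, "ratio": ratios, "precision": 1.0 / ses})
    refs: dict[str, float] = {}
    if len(kept) >= 2:
        refs["ivw"] = ivw(kept).beta
    if len(kept) >= 3:
        refs["egger"] = mr_egger(kept).beta
    return table, refs


def radial_mr(
    insts: Sequence[HarmonizedInstrument],
    alpha: float = 0.05,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> RadialResult:
    """Radial (modified second-order weight) IVW with per-SNP Q outliers.

    Fits the radial regression of ratio_j * sqrt(w_j) on sqrt(w_j) through
    the origin, with weights w_j = beta_exp_j^2 / (se_out_j^2 +
    beta_hat^2 * se_exp_j^2) iterated to convergence.  Each SNP's
    contribution q_j = w_j (ratio_j - beta_hat)^2 is referred to chi-square(1);
    upper-tail p below ``alpha`` flags the SNP as an outlier.
    """
    bx, sx, by, sy, rsids = _arrays(insts)
    k = len(bx)
    if k < 3:
        raise SensitivityError("insufficient_instruments")
    ratios = by / bx
    # First-order start, then modified second-order reweighting.
    w = bx**2 / sy**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = bx**2 / (sy**2 + beta**2 * sx**2)
        new_beta = float(np.sum(w * ratios) / np.sum(w))
        if abs(new_beta - beta) < tol:
            beta = new_beta
            break
        beta = new_beta
    q_j = w * (ratios - beta) ** 2
    q = float(q_j.sum())
    se = float(1.0 / math.sqrt(np.sum(w)))
    p_j = stats.chi2.sf(q_j, 1)
    outliers = [rsids[i] for i in range(k) if p_j[i] < alpha]
    return RadialResult(beta, se, q, dict(zip(rsids, q_j.astype(float))), outliers, n_iter)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out weighted through-origin slopes, vectorized.

    by may be 2-D (n_sim, k); returns matching shape of per-SNP LOO slopes.
    """
    s_xy = np.sum(w * bx * by, axis=-1, keepdims=True)
    s_xx = np.sum(w * bx**2, axis=-1, keepdims=True)
    return (s_xy - w * bx * by) / (s_xx - w * bx**2)


def mr_presso(
    insts: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
    distortion_alpha: float = 0.05,
    ivw_mode: str = "multiplicative_random",
) -> PressoResult:
    """MR-PRESSO: global pleiotropy test, outlier test, distortion test.

    The observed statistic is the weighted leave-one-out residual sum of
    squares of the through-origin IVW regression; its null distribution is
    built from ``n_sim`` parametric replicates drawn under the no-pleiotropy
    model (p uses the rank-based +1 correction).  Per-SNP outliers are flagged
    by Bonferroni-corrected simulated residual p-values; the distortion test
    compares the all-SNP and outlier-removed estimates against random
    removals of the same size.  The corrected estimate is the IVW on
    non-outlier SNPs.
    """
    if n_sim < 100:
        raise SensitivityError("n_sim must be >= 100")
    kept = kept_instruments(list(insts))
    bx, sx, by, sy, rsids = _arrays(kept)
    k = len(bx)
    if k < 4:
        raise SensitivityError("insufficient_instruments_for_presso")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy**2

    beta_loo = _loo_slopes(bx, by[None, :], w)[0]
    resid_obs = w * (by - beta_loo * bx) ** 2
    rss_obs = float(resid_obs.sum())

    # Parametric replicates under the no-pleiotropy model: each SNP's outcome
    # effect drawn around its leave-one-out prediction, exposure effect around
    # its observed value.
    # Outcome effects are drawn around the LOO prediction at the *observed*
    # exposure effect while exposure effects are re-drawn with their own
    # noise, so simulated residuals carry the same error-in-X component as
    # the data.
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(beta_loo * bx, sy, size=(n_sim, k))
    beta_loo_sim = _loo_slopes(bx_sim, by_sim, w)
    resid_sim = w * (by_sim - beta_loo_sim * bx_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    outliers: list[str] = []
    if global_p < 0.05:
        # Raw empirical exceedance (no +1 correction), so an observed residual
        # beyond every simulated one yields p = 0 and survives Bonferroni.
        p_j = np.sum(resid_sim >= resid_obs[None, :], axis=0) / n_sim
        threshold = outlier_alpha / k  # Bonferroni
        outliers = [rsids[i] for i in range(k) if p_j[i] < threshold]

    corrected = None
    distortion_p: float | None = None
    if outliers and len(outliers) < k - 1:
        corrected_insts = [h for h in kept if h.rsid not in outliers]
        corrected = ivw(corrected_insts, mode=ivw_mode)
        beta_all = float(np.sum(w * bx * by) / np.sum(w * bx**2))
        d_obs = abs(beta_all - corrected.beta)
        n_out = len(outliers)
        d_null = np.empty(n_sim)
        for i in range(n_sim):
            drop = rng.choice(k, size=n_out, replace=False)
            mask = np.ones(k, dtype=bool)
            mask[drop] = False
            b_sub = float(
                np.sum(w[mask] * bx[mask] * by[mask]) / np.sum(w[mask] * bx[mask] ** 2)
            )
            d_null[i] = abs(beta_all - b_sub)
        distortion_p = float((1 + np.sum(d_null >= d_obs)) / (n_sim + 1))
    elif not outliers:
        corrected = ivw(kept, mode=ivw_mode)

    return PressoResult(rss_obs, global_p, outliers, distortion_p, corrected, n_sim)


def sensitivity_report(
    insts: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 0,
    radial_alpha: float = 0.05,
    ivw_mode: str = "multiplicative_random",
) -> dict:
    """Assemble the full diagnostic block as a JSON-serializable dict."""
    kept = kept_instruments(list(insts))
    report: dict = {"n_snp": len(kept)}
    if len(kept) >= 2:
        q = cochran_q(kept, "ivw")
        report["heterogeneity_ivw"] = {"q": q.q_stat, "df": q.df, "p": q.pval}
    if len(kept) >= 3:
        q = cochran_q(kept, "egger")
        report["heterogeneity_egger"] = {"q": q.q_stat, "df": q.df, "p": q.pval}
        b0, se0, p0 = egger_intercept_test(kept)
        report["egger_intercept"] = {"intercept": b0, "se": se0, "p": p0}
        rad = radial_mr(kept, alpha=radial_alpha)
        report["radial"] = {
            "beta": rad.beta,
            "q": rad.q_stat,
            "outliers": rad.outlier_rsids,
        }
    if len(kept) >= 4:
        pres = mr_presso(kept, n_sim=n_sim, seed=seed, ivw_mode=ivw_mode)
        report["presso"] = {
            "global_rss": pres.global_rss,
            "global_p": pres.global_p,
            "outliers": pres.outlier_rsids,
            "distortion_p": pres.distortion_p,
            "corrected_or": None if pres.corrected is None else pres.corrected.or_value,
        }
    return report
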