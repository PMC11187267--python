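"""Synthetic two-sample GWAS summary statistics with a known causal chain.

The generator emulates the data structure the MR pipeline consumes: per-SNP
exposure effects with sampling noise, an exposure -> mediator -> outcome
chain on the log-odds scale, optional balanced or directional pleiotropy on
a configurable SNP fraction, and standard errors derived from allele
frequency and sample size, se = 1/sqrt(2*maf*(1-maf)*n).

Exposure, mediator and outcome samples are non-overlapping by construction
(independent noise draws), matching the two-sample design.  Instruments are
generated without LD, consistent with post-clumping data.  Because the
mediator -> outcome leg is only identifiable from variants acting on the
mediator directly, the generator creates a second, independent set of
mediator-specific instruments (effects delta_j on the mediator, b2*delta_j
on the outcome) alongside the exposure instruments.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .summary_data import SummaryDataset, VariantAssociation

#: Ordered non-palindromic allele pairs (effect, other).
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters; defaults mirror the study's scale.

    65 instruments for an exposure GWAS of 807,553 individuals, a binary
    outcome GWAS of 342,499, and a quantitative mediator measured in a
    biobank-scale sample.  Effects are on the log-odds (outcome) or
    standardized-trait (exposure/mediator) scale.
    """

    n_snp: int = 65
    n_snp_mediator: int = 65
    n_exposure: int = 807_553
    n_mediator: int = 361_194
    n_outcome: int = 342_499
    theta_direct: float = 0.3
    b1: float = 0.2
    b2: float = 0.5
    pleiotropy_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    gamma_sd: float = 0.03
    delta_sd: float = 0.03
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_snp", "n_snp_mediator", "n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.pleiotropy_fraction <= 1):
            raise ValueError("pleiotropy_fraction must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.b1 * self.b2

    @property
    def true_proportion(self) -> float | None:
        if self.theta_total == 0:
            return None
        return self.b1 * self.b2 / self.theta_total


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta / se))
    return np.maximum(p, np.finfo(float).tiny)


def _records(rsids, alleles, mafs, betas, ses, n, chroms, positions):
    pvals = _pvals(betas, ses)
    return [
        VariantAssociation(
            rsid=rsids[j],
            effect_allele=alleles[j][0],
            other_allele=alleles[j][1],
            beta=float(betas[j]),
            se=float(ses[j]),
            pval=float(pvals[j]),
            n=int(n),
            eaf=float(mafs[j]),
            chrom=chroms[j],
            pos=int(positions[j]),
        )
        for j in range(len(rsids))
    ]


def simulate_chain(
    config: SimulationConfig,
) -> tuple[SummaryDataset, SummaryDataset, SummaryDataset, dict]:
    """Generate (exposure, mediator, outcome) datasets plus the truth record.

    Per exposure instrument j: maf_j ~ U(maf_range); true effect
    gamma_j = |N(0, gamma_sd^2)| (oriented positive); observed exposure effect ~ N(gamma_j,
    se_x,j^2); mediator truth b1*gamma_j; outcome truth
    (theta_direct + b1*b2)*gamma_j + alpha_j with alpha_j the pleiotropic
    offset on the configured fraction.  Mediator-specific instruments carry
    delta_j on the mediator and b2*delta_j on the outcome.  Positions are
    spaced widely on alternating chromosomes so clumping is a no-op.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    k, m = c.n_snp, c.n_snp_mediator
    total = k + m

    mafs = rng.uniform(c.maf_range[0], c.maf_range[1], total)
    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), total)
    alleles = [_ALLELE_PAIRS[i] for i in allele_idx]
    rsids = [f"rs{1_000_000 + j}" for j in range(k)] + [
        f"rs{2_000_000 + j}" for j in range(m)
    ]
    chroms = [str(1 + j % 22) for j in range(total)]
    positions = [1_000_000 + (j // 22) * 20_000_000 for j in range(total)]

    def se_for(n):
        return 1.0 / np.sqrt(2.0 * mafs * (1.0 - mafs) * n)

    se_x, se_m, se_y = se_for(c.n_exposure), se_for(c.n_mediator), se_for(c.n_outcome)

    # Effect alleles are oriented to the trait-increasing allele (the usual
    # convention for published instrument panels), so true effects are the
    # magnitudes of normal draws; directional pleiotropy is then defined
    # relative to that orientation.
    gamma = np.abs(rng.normal(0.0, c.gamma_sd, k))
    delta = np.abs(rng.normal(0.0, c.delta_sd, m))

    alpha = np.zeros(k)
    n_pleio = int(round(c.pleiotropy_fraction * k))
    pleio_idx = rng.choice(k, size=n_pleio, replace=False) if n_pleio else np.array([], dtype=int)
    if n_pleio:
        alpha[pleio_idx] = rng.normal(c.pleiotropy_mean, c.pleiotropy_sd, n_pleio)

    true_x = np.concatenate([gamma, np.zeros(m)])
    true_m = np.concatenate([c.b1 * gamma, delta])
    true_y = np.concatenate([c.theta_total * gamma + alpha, c.b2 * delta])

    beta_x = rng.normal(true_x, se_x)
    beta_m = rng.normal(true_m, se_m)
    beta_y = rng.normal(true_y, se_y)

    exposure = SummaryDataset(
        "exposure",
        "binary",
        _records(rsids[:k], alleles[:k], mafs[:k], beta_x[:k], se_x[:k], c.n_exposure, chroms[:k], positions[:k]),
        provenance="simulated",
    )
    mediator = SummaryDataset(
        "mediator",
        "quantitative",
        _records(rsids, alleles, mafs, beta_m, se_m, c.n_mediator, chroms, positions),
        provenance="simulated",
    )
    outcome = SummaryDataset(
        "outcome",
        "binary",
        _records(rsids, alleles, mafs, beta_y, se_y, c.n_outcome, chroms, positions),
        provenance="simulated",
    )
    truth = {
        "config": asdict(c),
        "gamma": gamma.tolist(),
        "delta": delta.tolist(),
        "alpha": alpha.tolist(),
        "pleiotropic_rsids": [rsids[i] for i in sorted(pleio_idx.tolist())],
        "theta_total": c.theta_total,
        "true_proportion": c.true_proportion,
    }
    return exposure, mediator, outcome, truth


def simulate_pair(
    theta: float, seed: int = 0, **overrides
) -> tuple[SummaryDataset, SummaryDataset, dict]:
    """Exposure/outcome pair with total causal effect ``theta`` (no mediator)."""
    cfg = SimulationConfig(theta_direct=theta, b1=0.0, b2=0.0, seed=seed,
                           n_snp_mediator=1, **overrides)
    exposure, _, outcome, truth = simulate_chain(cfg)
    return exposure, outcome.subset(exposure.rsids), truth


def plant_outliers(dataset: SummaryDataset, rsids, shift: float) -> SummaryDataset:
    """Shift the outcome effect of the named SNPs by ``shift``; all else untouched."""
    from dataclasses import replace

    records = []
    targets = set(rsids)
    for rec in dataset:
        if rec.rsid in targets:
            targets.discard(rec.rsid)
            records.append(replace(rec, beta=rec.beta + shift))
        else:
            records.append(rec)
    if targets:
        raise KeyError(f"unknown rsid(s): {sorted(targets)}")
    return SummaryDataset(dataset.trait_name, dataset.trait_type, records, dataset.provenance)


def calibrate_gamma_sd(
    target_median_f: float,
    n: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_draws: int = 100_000,
) -> float:
    """Effect-size spread giving a requested median per-SNP F statistic.

    Uses F_j ~ (gamma_j / se_j)^2 = gamma_j^2 * 2*maf_j*(1-maf_j)*n and
    inverts the Monte Carlo median of the unit-spread multiplier (internal
    fixed stream, so the helper is deterministic).
    """
    rng = np.random.default_rng(12345)
    z2 = rng.standard_normal(n_draws) ** 2
    maf = rng.uniform(maf_range[0], maf_range[1], n_draws)
    multiplier = float(np.median(z2 * 2.0 * maf * (1.0 - maf) * n))
    return float(np.sqrt(target_median_f / multiplier))
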