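"""Config-driven orchestration of the full MR study.

Runs, per direction (forward / reverse): instrument selection ->
harmonization -> all five estimators -> the sensitivity suite ->
(optionally) mediation, and writes the estimate table, the
heterogeneity/pleiotropy table, the mediation table, leave-one-out and
funnel tables, minimal plots, and a cumulative exclusion ledger.
Identical config + seed produce byte-identical report tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .estimators import estimate_all
from .harmonization import DEFAULT_AF_WINDOW, harmonize_pair, kept_instruments
from .instruments import ClumpParams, LDTable, select_instruments
from .mediation import run_mediation
from .sensitivity import funnel_data, leave_one_out, sensitivity_report
from .summary_data import ExclusionLedger, SummaryDataset, read_summary_table, write_summary_table
from .synthetic import SimulationConfig, simulate_chain

logger = logging.getLogger("mrmediate")


class PipelineError(RuntimeError):
    pass


@dataclass
class StudyConfig:
    """Study-level settings; see ``StudyConfig.from_yaml`` for the file form.

    Datasets are either loaded from TSV paths (``datasets``: mapping of role
    -> {path, column_map, trait_name, trait_type}) or generated
    (``simulate``: SimulationConfig fields).  The forward direction uses
    exposure -> outcome; the reverse direction requires its own explicit
    dataset assignment (``reverse_exposure`` / ``reverse_outcome`` roles or a
    ``reverse_simulate`` block), since instruments must be selected for the
    trait acting as exposure.
    """

    output_dir: str = "mr_study_out"
    direction: str = "forward"  # forward | reverse | both
    seed: int = 0
    selection: ClumpParams = field(default_factory=ClumpParams)
    f_min: float = 10.0
    af_window: tuple[float, float] = DEFAULT_AF_WINDOW
    ivw_mode: str = "multiplicative_random"
    n_boot: int = 1000
    n_sim: int = 1000
    radial_alpha: float = 0.05
    mediation: bool = False
    plots: bool = False
    alpha: float = 0.05
    simulate: SimulationConfig | None = None
    reverse_simulate: SimulationConfig | None = None
    datasets: dict = field(default_factory=dict)
    ld_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        raw = dict(raw)
        if "selection" in raw:
            raw["selection"] = ClumpParams(**raw["selection"])
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            sim.setdefault("seed", raw.get("seed", 0))
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            raw["simulate"] = SimulationConfig(**sim)
        if "reverse_simulate" in raw and raw["reverse_simulate"] is not None:
            sim = dict(raw["reverse_simulate"])
            sim.setdefault("seed", raw.get("seed", 0) + 1)
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            raw["reverse_simulate"] = SimulationConfig(**sim)
        if "af_window" in raw:
            raw["af_window"] = tuple(raw["af_window"])
        return cls(**raw)


def _load_dataset(spec: dict) -> SummaryDataset:
    ds, ledger = read_summary_table(
        spec["path"],
        column_map=spec.get("column_map"),
        trait_name=spec.get("trait_name", "trait"),
        trait_type=spec.get("trait_type", "binary"),
    )
    if len(ledger):
        logger.warning("%s: %d rows rejected on read", spec["path"], len(ledger))
    return ds


def estimates_frame(estimates) -> pd.DataFrame:
    rows = [
        {
            "method": e.method,
            "n_snp": e.n_snp,
            "beta": e.beta,
            "se": e.se,
            "or": e.or_value,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "pval": e.pval,
            "intercept": e.intercept,
            "intercept_p": e.intercept_p,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)


def exclusion_summary(ledger: ExclusionLedger, n_start: int) -> pd.DataFrame:
    """Per-stage, per-reason removal accounting with surviving counts.

    Warning-only ledger entries (p-value clamps, missing-LD notes) do not
    remove records and are not counted as removals.  Conservation
    (start = removed + remaining) is enforced.
    """
    warning_reasons = {"pval_clamped"}
    df = ledger.to_frame()
    removals = df[
        ~df["reason"].isin(warning_reasons) & ~df["reason"].str.startswith("missing_ld_pair")
    ]
    rows = []
    remaining = n_start
    base_reason = removals["reason"].str.split(":").str[0]
    keys = list(dict.fromkeys(zip(removals["stage"], base_reason)))  # first-seen order
    for stage, reason in keys:
        n_removed = int(((removals["stage"] == stage) & (base_reason == reason)).sum())
        remaining -= n_removed
        rows.append({"stage": stage, "reason": reason, "removed": n_removed,
                     "remaining": remaining})
    out = pd.DataFrame(rows, columns=["stage", "reason", "removed", "remaining"])
    total_removed = int(out["removed"].sum()) if len(out) else 0
    if n_start - total_removed != remaining:
        raise PipelineError("exclusion accounting does not conserve records")
    return out


def _write_plots(insts, estimates, outdir: Path, tag: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .estimators import _arrays, wald_ratios

    bx, _, by, sy, _ = _arrays(insts)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(bx, by, yerr=sy, fmt="o", ms=3, lw=0.5, alpha=0.7)
    for e in estimates:
        if e.method in ("ivw", "egger"):
            icpt = e.intercept or 0.0
            xs = [0, bx.max()]
            ax.plot(xs, [icpt, icpt + e.beta * xs[1]], label=e.method)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / f"scatter_{tag}.png", dpi=100)
    plt.close(fig)

    ratios, ses = wald_ratios(bx, by, sy)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ratios, 1.0 / ses, s=8)
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel("precision (1/SE)")
    fig.tight_layout()
    fig.savefig(outdir / f"funnel_{tag}.png", dpi=100)
    plt.close(fig)


def _run_direction(
    tag: str,
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    config: StudyConfig,
    ld: LDTable | None,
    outdir: Path,
) -> dict:
    t0 = time.time()
    n_start = len(exposure)
    selected, ledger = select_instruments(
        exposure, ld=ld, params=config.selection, f_min=config.f_min
    )
    insts, led2 = harmonize_pair(selected, outcome, config.af_window)
    ledger.extend(led2)
    kept = kept_instruments(insts)
    if not kept:
        raise PipelineError(f"{tag}: no instruments survived selection/harmonization")

    estimates = estimate_all(
        kept, ivw_mode=config.ivw_mode, n_boot=config.n_boot, seed=config.seed
    )
    est_df = estimates_frame(estimates)
    est_df.insert(0, "direction", tag)
    est_df.to_csv(outdir / f"estimates_{tag}.tsv", sep="\t", index=False)

    report = sensitivity_report(
        kept,
        n_sim=config.n_sim,
        seed=config.seed,
        radial_alpha=config.radial_alpha,
        ivw_mode=config.ivw_mode,
    )
    with open(outdir / f"sensitivity_{tag}.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    if len(kept) >= 3:
        leave_one_out(kept, ivw_mode=config.ivw_mode).to_csv(
            outdir / f"leave_one_out_{tag}.tsv", sep="\t", index=False
        )
    funnel_df, refs = funnel_data(kept)
    funnel_df.to_csv(outdir / f"funnel_{tag}.tsv", sep="\t", index=False)

    ledger.write(outdir / f"exclusions_{tag}.tsv")
    exclusion_summary(ledger, n_start).to_csv(
        outdir / f"exclusion_summary_{tag}.tsv", sep="\t", index=False
    )
    harmonized_df = pd.DataFrame(
        [
            {
                "rsid": h.rsid,
                "beta_exp": h.beta_exp,
                "se_exp": h.se_exp,
                "beta_out": h.beta_out,
                "se_out": h.se_out,
                "status": h.status,
                "reason": h.reason,
            }
            for h in insts
        ]
    )
    harmonized_df.to_csv(outdir / f"harmonized_{tag}.tsv", sep="\t", index=False)

    if config.plots:
        _write_plots(kept, estimates, outdir, tag)

    logger.info("direction %s done in %.2fs (%d instruments)", tag, time.time() - t0, len(kept))
    return {"estimates": est_df, "sensitivity": report, "n_instruments": len(kept)}


def run_study(config: StudyConfig) -> dict:
    """Execute the configured study and write the report bundle.

    Returns a dict with per-direction results, mediation results, and the
    output directory path.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ld = LDTable.from_tsv(config.ld_path) if config.ld_path else None
    bundle: dict = {"output_dir": str(outdir)}

    mediator_ds: SummaryDataset | None = None
    if config.simulate is not None:
        exposure, mediator_ds, outcome, truth = simulate_chain(config.simulate)
        with open(outdir / "truth_forward.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
        write_summary_table(exposure, outdir / "exposure.tsv")
        write_summary_table(outcome, outdir / "outcome.tsv")
    elif "exposure" in config.datasets and "outcome" in config.datasets:
        exposure = _load_dataset(config.datasets["exposure"])
        outcome = _load_dataset(config.datasets["outcome"])
        if "mediator" in config.datasets:
            mediator_ds = _load_dataset(config.datasets["mediator"])
    else:
        raise PipelineError("config must provide either simulate or exposure/outcome datasets")

    if config.direction in ("forward", "both"):
        bundle["forward"] = _run_direction("forward", exposure, outcome, config, ld, outdir)

    if config.direction in ("reverse", "both"):
        if config.reverse_simulate is not None:
            rev_exposure, _, rev_outcome, rtruth = simulate_chain(config.reverse_simulate)
            rev_outcome = rev_outcome.subset(rev_exposure.rsids)
            with open(outdir / "truth_reverse.json", "w") as fh:
                json.dump(rtruth, fh, indent=2, sort_keys=True)
        elif "reverse_exposure" in config.datasets and "reverse_outcome" in config.datasets:
            rev_exposure = _load_dataset(config.datasets["reverse_exposure"])
            rev_outcome = _load_dataset(config.datasets["reverse_outcome"])
        else:
            raise PipelineError(
                "reverse direction requires reverse_simulate or explicit reverse datasets"
            )
        bundle["reverse"] = _run_direction("reverse", rev_exposure, rev_outcome, config, ld, outdir)

    if config.mediation:
        if mediator_ds is None:
            raise PipelineError("mediation enabled but no mediator dataset available")
        results, med_ledger = run_mediation(
            exposure,
            [mediator_ds],
            outcome,
            params=config.selection,
            f_min=config.f_min,
            af_window=config.af_window,
            ivw_mode=config.ivw_mode,
        )
        med_df = pd.DataFrame(
            [
                {
                    "mediator": r.mediator_name,
                    "proportion_pct": r.proportion_pct,
                    "ci_low_pct": 100 * r.ci_low,
                    "ci_high_pct": 100 * r.ci_high,
                    "pval": r.pval,
                    "indirect": r.indirect,
                    "total": r.total,
                    "inconsistent": r.inconsistent,
                }
                for r in results
            ]
        )
        med_df.to_csv(outdir / "mediation.tsv", sep="\t", index=False)
        bundle["mediation"] = results

    return bundle
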