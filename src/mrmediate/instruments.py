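"""Instrument selection: significance filtering, LD clumping, and the
F-statistic weak-instrument screen.

The selection funnel mirrors standard two-sample MR practice: keep
genome-wide-significant SNPs (p < 5e-8), greedily prune linkage-disequilibrium
partners (r^2 < 0.001 within a 10,000 kb window, most significant SNP kept),
and drop instruments with F <= 10, where

    F = (R^2 / (1 - R^2)) * ((n - k - 1) / k)

with R^2 the exposure variance explained, n the GWAS sample size and k the
number of instruments (k = 1 for a per-SNP F).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .summary_data import ExclusionLedger, SummaryDataset

import pandas as pd


class InstrumentError(ValueError):
    pass


@dataclass(frozen=True)
class ClumpParams:
    """Clumping thresholds: significance, LD r^2, and physical window."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise InstrumentError("p_threshold must lie in (0, 1)")
        if not (0 <= self.r2_threshold <= 1):
            raise InstrumentError("r2_threshold must lie in [0, 1]")
        if self.window_kb <= 0:
            raise InstrumentError("window_kb must be positive")


@dataclass(frozen=True)
class InstrumentStrength:
    rsid: str
    r2: float
    f_stat: float
    n: int
    k: int


def filter_significant(
    dataset: SummaryDataset, p_threshold: float = 5e-8
) -> tuple[SummaryDataset, ExclusionLedger]:
    """Retain records with p < ``p_threshold`` (strict); ledger the rest."""
    ledger = ExclusionLedger()
    keep = []
    for rec in dataset:
        if rec.pval < p_threshold:
            keep.append(rec.rsid)
        else:
            ledger.add(rec.rsid, "significance", "not_genome_wide_significant")
    return dataset.subset(keep), ledger


class LDTable:
    """Symmetric pairwise r^2 lookups; unlisted pairs default to 0."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | Iterable[tuple[str, str, float]] = ()):
        self._r2: dict[frozenset, float] = {}
        items = pairs.items() if isinstance(pairs, Mapping) else ((a_b[0:2], a_b[2]) for a_b in pairs)
        for key, r2 in items:
            a, b = key
            if a == b:
                if r2 != 1.0:
                    raise InstrumentError(f"diagonal r2 for {a} must be 1")
                continue
            fkey = frozenset((a, b))
            if fkey in self._r2 and self._r2[fkey] != float(r2):
                raise InstrumentError(f"asymmetric LD entries for pair ({a}, {b})")
            self._r2[fkey] = float(r2)

    @classmethod
    def from_tsv(cls, path) -> "LDTable":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        return cls(list(zip(df["rsid_a"], df["rsid_b"], df["r2"].astype(float))))

    def r2(self, a: str, b: str) -> float | None:
        """Pairwise r^2, or None when the pair is unlisted."""
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)))


def _within_window(rec_a, rec_b, window_kb: float) -> bool:
    # Missing positions are treated as inside the window, so the LD table
    # (not physical distance) decides; different chromosomes never co-window.
    if rec_a.chrom is None or rec_b.chrom is None or rec_a.pos is None or rec_b.pos is None:
        return True
    if rec_a.chrom != rec_b.chrom:
        return False
    return abs(rec_a.pos - rec_b.pos) <= window_kb * 1000


def ld_clump(
    dataset: SummaryDataset,
    ld: LDTable | None = None,
    params: ClumpParams = ClumpParams(),
) -> tuple[SummaryDataset, ExclusionLedger]:
    """Greedy LD clumping in ascending p-value order (rsid tie-break).

    A SNP is pruned when its r^2 with any already-kept SNP inside the window
    exceeds ``params.r2_threshold``; the ledger names the index SNP
    responsible.  Pairs missing from the LD table are treated as r^2 = 0 with
    a ``missing_ld_pair`` warning when they fall inside the window.
    """
    ld = ld or LDTable()
    ledger = ExclusionLedger()
    ordered = sorted(dataset, key=lambda r: (r.pval, r.rsid))
    kept = []
    for rec in ordered:
        pruned_by = None
        for index in kept:
            if not _within_window(rec, index, params.window_kb):
                continue
            r2 = ld.r2(rec.rsid, index.rsid)
            if r2 is None:
                ledger.add(rec.rsid, "clump", f"missing_ld_pair:{index.rsid}")
                continue
            if r2 > params.r2_threshold:
                pruned_by = index.rsid
                break
        if pruned_by is None:
            kept.append(rec)
        else:
            ledger.add(rec.rsid, "clump", f"ld_pruned:{pruned_by}")
    return dataset.subset([r.rsid for r in kept]), ledger


def variance_explained(rec) -> float:
    """Per-SNP exposure variance explained: 2*eaf*(1-eaf)*beta^2.

    Assumes a standardized (unit-variance) exposure; the usual summary-data
    approximation when per-SNP R^2 is not published.
    """
    if rec.eaf is None:
        raise InstrumentError(f"cannot_compute_r2: {rec.rsid} has no eaf")
    return 2.0 * rec.eaf * (1.0 - rec.eaf) * rec.beta**2


def f_statistic(r2: float, n: int, k: int) -> float:
    if not (0 <= r2 < 1):
        raise InstrumentError("r2 must lie in [0, 1)")
    if k < 1:
        raise InstrumentError("k must be >= 1")
    return (r2 / (1.0 - r2)) * ((n - k - 1) / k)


def compute_f_statistics(dataset: SummaryDataset, k: int | None = None) -> list[InstrumentStrength]:
    """Per-SNP instrument strength (k = 1), plus an optional set-level entry.

    When ``k`` is given, a final entry with rsid ``"__set__"`` carries the
    set-level F computed from the summed per-SNP variance explained.
    """
    out = []
    total_r2 = 0.0
    for rec in dataset:
        r2 = variance_explained(rec)
        total_r2 += r2
        out.append(InstrumentStrength(rec.rsid, r2, f_statistic(r2, rec.n, 1), rec.n, 1))
    if k is not None and len(out) > 0:
        n = max(rec.n for rec in dataset)
        out.append(InstrumentStrength("__set__", total_r2, f_statistic(total_r2, n, k), n, k))
    return out


def filter_weak_instruments(
    dataset: SummaryDataset,
    strengths: Iterable[InstrumentStrength] | None = None,
    f_min: float = 10.0,
) -> tuple[SummaryDataset, ExclusionLedger]:
    """Retain SNPs with per-SNP F strictly greater than ``f_min``."""
    if strengths is None:
        strengths = compute_f_statistics(dataset)
    ledger = ExclusionLedger()
    keep = []
    for s in strengths:
        if s.rsid == "__set__":
            continue
        if s.f_stat > f_min:
            keep.append(s.rsid)
        else:
            ledger.add(s.rsid, "instrument_strength", "weak_instrument")
    return dataset.subset(keep), ledger


def select_instruments(
    dataset: SummaryDataset,
    ld: LDTable | None = None,
    params: ClumpParams = ClumpParams(),
    f_min: float = 10.0,
) -> tuple[SummaryDataset, ExclusionLedger]:
    """Full selection funnel: significance -> LD clump -> weak-instrument filter."""
    sig, ledger = filter_significant(dataset, params.p_threshold)
    clumped, led2 = ld_clump(sig, ld, params)
    ledger.extend(led2)
    missing_eaf = [r.rsid for r in clumped if r.eaf is None]
    for rsid in missing_eaf:
        ledger.add(rsid, "instrument_strength", "cannot_compute_r2")
    with_eaf = clumped.subset([r.rsid for r in clumped if r.eaf is not None])
    strong, led3 = filter_weak_instruments(with_eaf, f_min=f_min)
    ledger.extend(led3)
    return strong, ledger
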