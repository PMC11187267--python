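"""GWAS summary-statistic tables: validated in-memory containers and TSV I/O.

A summary dataset holds one record per SNP (rsID, alleles, effect-allele
frequency, effect size, standard error, p-value, sample size).  Binary traits
carry effects on the log-odds scale; quantitative traits in trait units.
Malformed rows are never silently dropped: every rejection lands in an
exclusion ledger with a machine-readable reason code.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: Canonical column names of the on-disk TSV dialect.
CANONICAL_COLUMNS = [
    "SNP",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "samplesize",
    "chr",
    "pos",
]

MANDATORY_COLUMNS = ["SNP", "effect_allele", "other_allele", "beta", "se", "pval", "samplesize"]

#: Smallest positive double; p-values of exactly zero are clamped here.
_MIN_PVAL = sys.float_info.min


class SummaryDataError(ValueError):
    """Format or validation failure in a summary-statistic table."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    eaf: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise SummaryDataError(f"{self.rsid}: alleles must be single A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise SummaryDataError(f"{self.rsid}: identical alleles")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise SummaryDataError(f"{self.rsid}: se must be finite and > 0")
        if not (0 < self.pval <= 1):
            raise SummaryDataError(f"{self.rsid}: pval must lie in (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise SummaryDataError(f"{self.rsid}: eaf must lie in (0, 1)")
        if self.n <= 0:
            raise SummaryDataError(f"{self.rsid}: sample size must be positive")


@dataclass
class ExclusionRecord:
    rsid: str
    stage: str
    reason: str


class ExclusionLedger:
    """Audit trail of every record removed (or warned about) at any stage."""

    def __init__(self, records: Iterable[ExclusionRecord] | None = None) -> None:
        self.records: list[ExclusionRecord] = list(records or [])

    def add(self, rsid: str, stage: str, reason: str) -> None:
        self.records.append(ExclusionRecord(rsid, stage, reason))

    def extend(self, other: "ExclusionLedger") -> None:
        self.records.extend(other.records)

    def reasons(self) -> list[str]:
        return [r.reason for r in self.records]

    def count(self, reason: str | None = None, stage: str | None = None) -> int:
        return sum(
            1
            for r in self.records
            if (reason is None or r.reason == reason) and (stage is None or r.stage == stage)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.rsid, r.stage, r.reason) for r in self.records],
            columns=["rsid", "stage", "reason"],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ExclusionRecord]:
        return iter(self.records)


class SummaryDataset:
    """A named trait's GWAS summary statistics, keyed by rsID.

    Parameters
    ----------
    trait_name:
        Human-readable trait label, e.g. ``"depression"``.
    trait_type:
        ``"binary"`` (effects are log-odds) or ``"quantitative"``.
    records:
        Variant associations; rsIDs must be unique.
    provenance:
        Free-text source label carried through reports.
    """

    def __init__(
        self,
        trait_name: str,
        trait_type: str,
        records: Iterable[VariantAssociation] = (),
        provenance: str = "",
    ) -> None:
        if trait_type not in ("binary", "quantitative"):
            raise SummaryDataError(f"unknown trait_type {trait_type!r}")
        self.trait_name = trait_name
        self.trait_type = trait_type
        self.provenance = provenance
        self._records: dict[str, VariantAssociation] = {}
        for rec in records:
            if rec.rsid in self._records:
                raise SummaryDataError(f"duplicate rsid {rec.rsid}")
            self._records[rec.rsid] = rec

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self._records.values())

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._records

    def __getitem__(self, rsid: str) -> VariantAssociation:
        return self._records[rsid]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SummaryDataset):
            return NotImplemented
        return (
            self.trait_name == other.trait_name
            and self.trait_type == other.trait_type
            and self._records == other._records
        )

    @property
    def rsids(self) -> list[str]:
        return list(self._records)

    def subset(self, rsids: Iterable[str]) -> "SummaryDataset":
        keep = [self._records[r] for r in rsids if r in self._records]
        return SummaryDataset(self.trait_name, self.trait_type, keep, self.provenance)

    def with_record(self, rec: VariantAssociation) -> "SummaryDataset":
        recs = dict(self._records)
        recs[rec.rsid] = rec
        return SummaryDataset(self.trait_name, self.trait_type, recs.values(), self.provenance)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "SNP": r.rsid,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "samplesize": r.n,
                "chr": r.chrom,
                "pos": r.pos,
            }
            for r in self
        ]
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "NA" or value == "":
        return None
    return float(value)


def read_summary_table(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str = "trait",
    trait_type: str = "binary",
    provenance: str = "",
) -> tuple[SummaryDataset, ExclusionLedger]:
    """Read a delimited summary-statistic table into a validated dataset.

    ``column_map`` maps canonical names (``SNP``, ``effect_allele``,
    ``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``, ``samplesize``,
    ``chr``, ``pos``) to the names actually present in the file, so tables
    from different GWAS repositories can be adapted without rewriting them.

    Malformed rows are rejected with per-row reason codes in the returned
    exclusion ledger; a p-value of exactly 0 is clamped to the smallest
    positive double with a ``pval_clamped`` warning rather than rejected.
    A duplicated rsID is a hard validation error (the table is ambiguous).
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)

    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in df.columns:
            rename[source] = canonical
    df = df.rename(columns=rename)

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryDataError(f"missing mandatory column(s): {', '.join(missing)}")

    seen: set[str] = set()
    ledger = ExclusionLedger()
    records: list[VariantAssociation] = []
    for _, row in df.iterrows():
        rsid = str(row["SNP"])
        if rsid in seen:
            raise SummaryDataError(f"duplicate rsid {rsid}")
        seen.add(rsid)
        try:
            ea = str(row["effect_allele"]).upper()
            oa = str(row["other_allele"]).upper()
            if len(ea) != 1 or len(oa) != 1 or ea not in VALID_ALLELES or oa not in VALID_ALLELES:
                ledger.add(rsid, "read", "invalid_allele")
                continue
            if ea == oa:
                ledger.add(rsid, "read", "identical_alleles")
                continue
            se = float(row["se"])
            if not (se > 0 and math.isfinite(se)):
                ledger.add(rsid, "read", "nonpositive_se")
                continue
            pval = float(row["pval"])
            if pval == 0.0:
                pval = _MIN_PVAL
                ledger.add(rsid, "read", "pval_clamped")
            if not (0 < pval <= 1):
                ledger.add(rsid, "read", "invalid_pval")
                continue
            eaf = _parse_optional_float(row.get("eaf"))
            if eaf is not None and not (0 < eaf < 1):
                ledger.add(rsid, "read", "invalid_eaf")
                continue
            n = int(float(row["samplesize"]))
            if n <= 0:
                ledger.add(rsid, "read", "nonpositive_samplesize")
                continue
            chrom_raw = row.get("chr")
            chrom = None if chrom_raw is None or pd.isna(chrom_raw) or chrom_raw in ("", "NA") else str(chrom_raw)
            pos_f = _parse_optional_float(row.get("pos"))
            pos = None if pos_f is None else int(pos_f)
            records.append(
                VariantAssociation(
                    rsid=rsid,
                    effect_allele=ea,
                    other_allele=oa,
                    beta=float(row["beta"]),
                    se=se,
                    pval=pval,
                    n=n,
                    eaf=eaf,
                    chrom=chrom,
                    pos=pos,
                )
            )
        except (ValueError, TypeError):
            ledger.add(rsid, "read", "unparseable_row")

    return SummaryDataset(trait_name, trait_type, records, provenance or str(path)), ledger


def write_summary_table(dataset: SummaryDataset, path) -> str:
    """Write a dataset as TSV; missing optional values are encoded ``NA``.

    Floats are written with Python's shortest round-trip representation, so
    ``read_summary_table(write_summary_table(d))`` reproduces every field
    bit-identically.
    """
    lines = ["\t".join(CANONICAL_COLUMNS)]
    for r in dataset:
        fields = [
            r.rsid,
            r.effect_allele,
            r.other_allele,
            "NA" if r.eaf is None else repr(r.eaf),
            repr(r.beta),
            repr(r.se),
            repr(r.pval),
            str(r.n),
            "NA" if r.chrom is None else str(r.chrom),
            "NA" if r.pos is None else str(r.pos),
        ]
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)
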