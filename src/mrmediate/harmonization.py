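"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR requires the per-SNP exposure and outcome effects to refer to
the same effect allele on the same strand.  Per SNP this module resolves:
identical alleles (kept as-is), swapped alleles (outcome effect negated,
frequency complemented), strand flips (complement, then match), and
palindromic A/T and C/G pairs, which are strand-ambiguous and can only be
oriented through allele frequency — SNPs whose frequency is intermediate
(near 0.5) are excluded as unresolvable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .summary_data import ExclusionLedger, SummaryDataset

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default ambiguity window for palindromic SNP allele frequencies.
DEFAULT_AF_WINDOW = (0.42, 0.58)


def classify_palindromic(ea: str, oa: str) -> bool:
    """True exactly for the strand-ambiguous pairs {A,T} and {C,G}."""
    return _COMPLEMENT[ea] == oa


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP's aligned exposure/outcome effects, or its exclusion record."""

    rsid: str
    beta_exp: float | None = None
    se_exp: float | None = None
    beta_out: float | None = None
    se_out: float | None = None
    eaf_exp: float | None = None
    eaf_out: float | None = None
    status: str = "kept"  # kept | excluded
    reason: str = "none"  # none | not_in_outcome | palindromic_intermediate_af | allele_mismatch

    @property
    def kept(self) -> bool:
        return self.status == "kept"


def _excluded(rsid: str, reason: str) -> HarmonizedInstrument:
    return HarmonizedInstrument(rsid=rsid, status="excluded", reason=reason)


def _complement_of(eaf: float | None) -> float | None:
    return None if eaf is None else 1.0 - eaf


def harmonize_pair(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    af_window: tuple[float, float] = DEFAULT_AF_WINDOW,
) -> tuple[list[HarmonizedInstrument], ExclusionLedger]:
    """Align each exposure SNP with its outcome record.

    Resolution order per SNP: absent from outcome -> excluded
    ``not_in_outcome``; same alleles -> kept unchanged; swapped alleles ->
    outcome beta negated and eaf complemented; strand-complement
    (non-palindromic) -> complement then re-match; palindromic with either
    eaf inside ``af_window`` (or missing) -> excluded
    ``palindromic_intermediate_af``; palindromic outside the window ->
    oriented so both frequencies agree on the minor allele; anything else ->
    excluded ``allele_mismatch``.
    """
    lo, hi = af_window
    ledger = ExclusionLedger()
    out: list[HarmonizedInstrument] = []
    for exp in exposure:
        rsid = exp.rsid
        if rsid not in outcome:
            rec = _excluded(rsid, "not_in_outcome")
            ledger.add(rsid, "harmonization", rec.reason)
            out.append(rec)
            continue
        o = outcome[rsid]
        ea, oa = exp.effect_allele, exp.other_allele
        beta_out, eaf_out = o.beta, o.eaf

        if classify_palindromic(ea, oa):
            if not classify_palindromic(o.effect_allele, o.other_allele) or {
                o.effect_allele,
                o.other_allele,
            } != {ea, oa}:
                rec = _excluded(rsid, "allele_mismatch")
                ledger.add(rsid, "harmonization", rec.reason)
                out.append(rec)
                continue
            if exp.eaf is None or o.eaf is None:
                rec = _excluded(rsid, "palindromic_intermediate_af")
                ledger.add(rsid, "harmonization", rec.reason)
                out.append(rec)
                continue
            if lo <= exp.eaf <= hi or lo <= o.eaf <= hi:
                rec = _excluded(rsid, "palindromic_intermediate_af")
                ledger.add(rsid, "harmonization", rec.reason)
                out.append(rec)
                continue
            # Nominal label alignment first (a palindromic swap is
            # indistinguishable from a strand flip), then orient by frequency.
            if o.effect_allele != ea:
                beta_out, eaf_out = -beta_out, _complement_of(eaf_out)
            if (exp.eaf < 0.5) != (eaf_out < 0.5):
                beta_out, eaf_out = -beta_out, _complement_of(eaf_out)
        else:
            o_ea, o_oa = o.effect_allele, o.other_allele
            if {o_ea, o_oa} != {ea, oa}:
                o_ea, o_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
            if (o_ea, o_oa) == (ea, oa):
                pass
            elif (o_ea, o_oa) == (oa, ea):
                beta_out, eaf_out = -beta_out, _complement_of(eaf_out)
            else:
                rec = _excluded(rsid, "allele_mismatch")
                ledger.add(rsid, "harmonization", rec.reason)
                out.append(rec)
                continue

        out.append(
            HarmonizedInstrument(
                rsid=rsid,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=o.se,
                eaf_exp=exp.eaf,
                eaf_out=eaf_out,
            )
        )
    return out, ledger


def kept_instruments(insts: list[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    return [h for h in insts if h.kept]
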