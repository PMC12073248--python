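"""Library-driven annotation of screened features.

Candidate identities are assigned by exact-mass search against a compound
library (theoretical adduct m/z from the formula, |ppm| within tolerance),
optionally backed by MS/MS fragment agreement and retention-time plausibility.
Identifications remain tentative; instead of a hidden accept/reject threshold
the report carries an evidence tier: ``mass``, ``mass+fragments``, or
``mass+fragments+rt``.  Isobaric compounds are all reported — there is no
automatic winner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .feature_io import CompoundRecord
from .formula import MassAssignment, adduct_mz, dbe, monoisotopic_mass, ppm_error, resolve_adduct
from .screen import BinderCall

__all__ = [
    "AnnotationCandidate",
    "annotate_mz",
    "match_fragments",
    "annotate_binders",
]


@dataclass(frozen=True)
class AnnotationCandidate:
    compound: CompoundRecord
    adduct: str
    assignment: MassAssignment
    fragments_matched: int = 0
    fragments_expected: int = 0
    rt_delta: Optional[float] = None

    @property
    def tier(self) -> str:
        if self.fragments_matched > 0:
            if self.rt_delta is not None:
                return "mass+fragments+rt"
            return "mass+fragments"
        return "mass"


def annotate_mz(
    mz: float,
    polarity: str,
    library: Sequence[CompoundRecord],
    tol_ppm: float = 10.0,
) -> list[AnnotationCandidate]:
    """Rank library compounds by |ppm| against an observed m/z.

    Only adducts of matching polarity are considered.  The ranking chain is
    deterministic and total: |ppm| ascending, fragment support descending
    (zero at this stage), then compound name.
    """
    candidates: list[AnnotationCandidate] = []
    for record in library:
        for adduct_name in record.adducts:
            spec = resolve_adduct(adduct_name)
            if spec.polarity != polarity:
                continue
            theoretical = adduct_mz(monoisotopic_mass(record.formula), spec)
            err = ppm_error(theoretical, mz)
            if abs(err) <= tol_ppm:
                assignment = MassAssignment(
                    theoretical_mz=theoretical,
                    experimental_mz=mz,
                    error_ppm=err,
                    dbe=dbe(record.formula),
                )
                candidates.append(
                    AnnotationCandidate(
                        compound=record,
                        adduct=spec.name,
                        assignment=assignment,
                        fragments_expected=len(record.diagnostic_fragments),
                    )
                )
    candidates.sort(key=_rank_key)
    return candidates


def _rank_key(c: AnnotationCandidate) -> tuple:
    return (abs(c.assignment.error_ppm), -c.fragments_matched, c.compound.name)


def match_fragments(
    observed: Sequence[float],
    expected: Sequence[float],
    tol_mz: float = 0.01,
) -> tuple[int, list[tuple[float, float]]]:
    """Greedy one-to-one fragment pairing by smallest absolute m/z difference.

    Returns the matched count and the pairing.  An observed peak can satisfy
    at most one expected fragment and vice versa.
    """
    if tol_mz <= 0:
        raise ValueError("tol_mz must be positive")
    pairs_by_distance = sorted(
        ((abs(o - e), oi, ei) for oi, o in enumerate(observed) for ei, e in enumerate(expected)),
        key=lambda t: t,
    )
    used_obs: set[int] = set()
    used_exp: set[int] = set()
    pairing: list[tuple[float, float]] = []
    for distance, oi, ei in pairs_by_distance:
        if distance > tol_mz:
            break
        if oi in used_obs or ei in used_exp:
            continue
        used_obs.add(oi)
        used_exp.add(ei)
        pairing.append((observed[oi], expected[ei]))
    return len(pairing), pairing


def annotate_binders(
    calls: Sequence[BinderCall],
    library: Sequence[CompoundRecord],
    tol_ppm: float = 10.0,
    fragment_tol_mz: float = 0.01,
    observed_fragments: Optional[dict[int, Sequence[float]]] = None,
) -> pd.DataFrame:
    """Annotated binder report, one row per (call, candidate).

    Unannotated calls are retained with compound "unknown" rather than
    dropped.  When ``observed_fragments`` maps a call index to measured MS/MS
    fragments, fragment support and the evidence tier are filled in.
    """
    rows = []
    for idx, call in enumerate(calls):
        candidates = annotate_mz(call.matched.consensus_mz, call.matched.polarity, library, tol_ppm)
        observed = list((observed_fragments or {}).get(idx, ()))
        enriched: list[AnnotationCandidate] = []
        for cand in candidates:
            matched_n = 0
            if observed and cand.compound.diagnostic_fragments:
                matched_n, _ = match_fragments(
                    observed, cand.compound.diagnostic_fragments, fragment_tol_mz
                )
            rt_delta = None
            if cand.compound.reference_rt is not None:
                rt_delta = call.matched.consensus_rt - cand.compound.reference_rt
            enriched.append(
                AnnotationCandidate(
                    compound=cand.compound,
                    adduct=cand.adduct,
                    assignment=cand.assignment,
                    fragments_matched=matched_n,
                    fragments_expected=cand.fragments_expected,
                    rt_delta=rt_delta,
                )
            )
        enriched.sort(key=_rank_key)
        if not enriched:
            rows.append(
                {
                    "call_index": idx,
                    "mz": call.matched.consensus_mz,
                    "rt": call.matched.consensus_rt,
                    "polarity": call.matched.polarity,
                    "decision": call.decision,
                    "log2fc": call.log2fc,
                    "q_value": call.q_value,
                    "compound": "unknown",
                    "formula": None,
                    "adduct": None,
                    "theoretical_mz": None,
                    "experimental_mz": call.matched.consensus_mz,
                    "error_ppm": None,
                    "dbe": None,
                    "fragments_matched": 0,
                    "fragments_expected": 0,
                    "rt_delta": None,
                    "tier": "none",
                    "rank": 0,
                }
            )
            continue
        for rank, cand in enumerate(enriched, start=1):
            rows.append(
                {
                    "call_index": idx,
                    "mz": call.matched.consensus_mz,
                    "rt": call.matched.consensus_rt,
                    "polarity": call.matched.polarity,
                    "decision": call.decision,
                    "log2fc": call.log2fc,
                    "q_value": call.q_value,
                    "compound": cand.compound.name,
                    "formula": str(cand.compound.formula),
                    "adduct": cand.adduct,
                    "theoretical_mz": cand.assignment.theoretical_mz,
                    "experimental_mz": cand.assignment.experimental_mz,
                    "error_ppm": cand.assignment.error_ppm,
                    "dbe": cand.assignment.dbe,
                    "fragments_matched": cand.fragments_matched,
                    "fragments_expected": cand.fragments_expected,
                    "rt_delta": cand.rt_delta,
                    "tier": cand.tier,
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows)
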