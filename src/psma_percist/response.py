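"""PERCIST-style response classification at lesion, patient and biochemical level.

Lesion level (SUVpeak): complete tracer resolution -> iCR; change <= -30% ->
iPR; change >= +30% -> iPD; otherwise iSD.  Patient level uses TL-PSMA with
the same +/-30% boundaries; the appearance of any new lesion is sufficient
for iPD, and a patient-level complete response is not defined.  Biochemical
(PSA) response follows the prostate-cancer working-group definitions:
reduction of more than 50% -> bPR, increase of at least 25% -> bPD,
everything between -> bSD.  Objective response means iCR or iPR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .quant import ScanQuant

IMAGING_CATEGORIES = ("iCR", "iPR", "iSD", "iPD")
BIOCHEMICAL_CATEGORIES = ("bPR", "bSD", "bPD")

RESPONDER_CATEGORIES = frozenset({"iCR", "iPR"})


@dataclass(frozen=True)
class LesionPair:
    """One lesion tracked across the two timepoints."""

    lesion_id: object
    suv_peak_baseline: float
    suv_peak_followup: float
    matched: bool = True
    new_lesion: bool = False
    site: str = "unknown"

    def __post_init__(self) -> None:
        if self.suv_peak_baseline < 0 or self.suv_peak_followup < 0:
            raise ValueError("SUV values must be non-negative")
        if self.matched and self.new_lesion:
            raise ValueError("a pair cannot be both matched and new")


def percent_change(pre: float, post: float) -> float:
    """100 * (post - pre) / pre; ``pre`` must be positive."""
    if pre <= 0:
        raise ValueError("baseline value must be positive")
    return 100.0 * (post - pre) / pre


def classify_lesion(pair: LesionPair, threshold_pct: float = 30.0) -> str:
    """Lesion-level imaging category from the SUVpeak pair.

    Follow-up of exactly zero (uptake resolved below threshold) is iCR; the
    +/-30% boundaries are inclusive.  New lesions carry no baseline and are
    not classified at the lesion level.
    """
    if pair.new_lesion:
        raise ValueError("new lesions are not classified at the lesion level")
    if pair.suv_peak_baseline <= 0:
        raise ValueError("baseline SUVpeak must be positive")
    if pair.suv_peak_followup == 0:
        return "iCR"
    change = percent_change(pair.suv_peak_baseline, pair.suv_peak_followup)
    if change <= -threshold_pct:
        return "iPR"
    if change >= threshold_pct:
        return "iPD"
    return "iSD"


def classify_patient(
    tl_pre: float,
    tl_post: float,
    any_new_lesion: bool = False,
    threshold_pct: float = 30.0,
) -> str:
    """Patient-level imaging category from TL-PSMA change.

    Any new lesion is sufficient for iPD (it takes precedence over a
    TL-PSMA reduction); otherwise a >=30% reduction is iPR and a >=30%
    increase iPD.  Patient-level iCR is not emitted.
    """
    if tl_pre <= 0:
        raise ValueError("baseline TL-PSMA must be positive")
    if any_new_lesion:
        return "iPD"
    change = percent_change(tl_pre, tl_post)
    if change <= -threshold_pct:
        return "iPR"
    if change >= threshold_pct:
        return "iPD"
    return "iSD"


def classify_biochemical(
    psa_pre: float,
    psa_post: float,
    reduction_pct: float = 50.0,
    increase_pct: float = 25.0,
) -> str:
    """Biochemical category: change < -50% -> bPR; >= +25% -> bPD; else bSD.

    Both boundaries follow the working-group wording: a reduction of exactly
    50% is still bSD, an increase of exactly 25% is already bPD.
    """
    if psa_pre <= 0:
        raise ValueError("baseline PSA must be positive")
    change = percent_change(psa_pre, psa_post)
    if change < -reduction_pct:
        return "bPR"
    if change >= increase_pct:
        return "bPD"
    return "bSD"


def is_objective_response(category: str) -> bool:
    return category in RESPONDER_CATEGORIES


# ---------------------------------------------------------------------------
# Lesion matching across timepoints
# ---------------------------------------------------------------------------


def match_lesions(
    baseline: ScanQuant,
    followup: ScanQuant,
    id_map: dict | None = None,
    max_distance_mm: float = 15.0,
    require_same_site: bool = True,
) -> list[LesionPair]:
    """Pair baseline and follow-up lesions.

    With an explicit ``id_map`` (baseline id -> follow-up id) the mapping is
    used as-is; otherwise greedy nearest-centroid matching within
    ``max_distance_mm`` (and, by default, the same site) is applied.
    Unmatched baseline lesions are reported with follow-up SUVpeak 0
    (resolved); unmatched follow-up lesions are flagged as new.
    """
    b_lesions = {l.lesion_id: l for l in baseline.lesions}
    f_lesions = {l.lesion_id: l for l in followup.lesions}

    if id_map is not None:
        targets = [v for v in id_map.values() if v is not None]
        if len(targets) != len(set(targets)) or len(id_map) != len(set(id_map)):
            raise ValueError("duplicate ids in id_map")
        assignment = {
            b: f for b, f in id_map.items() if f is not None and f in f_lesions
        }
    else:
        candidates = []
        for b in baseline.lesions:
            for f in followup.lesions:
                if require_same_site and b.site != f.site:
                    continue
                dist = math.dist(b.centroid, f.centroid)
                if dist <= max_distance_mm:
                    candidates.append((dist, b.lesion_id, f.lesion_id))
        candidates.sort()
        assignment = {}
        used_f = set()
        for _dist, b_id, f_id in candidates:
            if b_id in assignment or f_id in used_f:
                continue
            assignment[b_id] = f_id
            used_f.add(f_id)

    pairs: list[LesionPair] = []
    for b_id, b in b_lesions.items():
        f_id = assignment.get(b_id)
        if f_id is not None:
            pairs.append(
                LesionPair(
                    lesion_id=b_id,
                    suv_peak_baseline=b.suv_peak,
                    suv_peak_followup=f_lesions[f_id].suv_peak,
                    matched=True,
                    site=b.site,
                )
            )
        else:
            pairs.append(
                LesionPair(
                    lesion_id=b_id,
                    suv_peak_baseline=b.suv_peak,
                    suv_peak_followup=0.0,
                    matched=False,
                    site=b.site,
                )
            )
    matched_f = set(assignment.values())
    for f_id, f in f_lesions.items():
        if f_id not in matched_f:
            pairs.append(
                LesionPair(
                    lesion_id=f_id,
                    suv_peak_baseline=0.0,
                    suv_peak_followup=f.suv_peak,
                    matched=False,
                    new_lesion=True,
                    site=f.site,
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# Table-level helpers (pipeline surface)
# ---------------------------------------------------------------------------


def classify_lesion_table(
    lesions: pd.DataFrame, threshold_pct: float = 30.0
) -> pd.DataFrame:
    """Add ``category``/``responder`` columns from suv_peak_t0/suv_peak_t1."""
    out = lesions.copy()
    out["category"] = [
        classify_lesion(
            LesionPair(lesion_id=i, suv_peak_baseline=pre, suv_peak_followup=post),
            threshold_pct,
        )
        for i, (pre, post) in enumerate(zip(out["suv_peak_t0"], out["suv_peak_t1"]))
    ]
    out["responder"] = out["category"].map(is_objective_response)
    return out


def classify_patient_table(
    patients: pd.DataFrame,
    threshold_pct: float = 30.0,
    psa_reduction_pct: float = 50.0,
    psa_increase_pct: float = 25.0,
) -> pd.DataFrame:
    """Add imaging and biochemical response columns to a patient table."""
    out = patients.copy()
    out["imaging_response"] = [
        classify_patient(pre, post, bool(new), threshold_pct)
        for pre, post, new in zip(
            out["tl_psma_t0"], out["tl_psma_t1"], out["new_lesions"]
        )
    ]
    out["imaging_responder"] = out["imaging_response"].map(is_objective_response)
    out["biochemical_response"] = [
        classify_biochemical(pre, post, psa_reduction_pct, psa_increase_pct)
        for pre, post in zip(out["psa_t0"], out["psa_t1"])
    ]
    out["biochemical_responder"] = out["biochemical_response"] == "bPR"
    out["tl_psma_change_pct"] = [
        percent_change(pre, post)
        for pre, post in zip(out["tl_psma_t0"], out["tl_psma_t1"])
    ]
    return out
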