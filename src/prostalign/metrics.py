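"""Registration-variability statistics for multi-rater validation studies.

There is no objective ground truth for prostate MRI-CT registration on
clinical images, so accuracy is measured pragmatically against expert
raters. For each case the MRI prostate centroid is mapped through every
registration into CT coordinates and the following quantities are derived
(distances in mm, Euclidean):

* ``P_avg`` — consensus position: the mean of the manual rater positions;
* ``D_PPro`` — distance of the automated (unadjusted) registration from the
  consensus;
* ``D_intra`` — per-rater distance between the round-1 and round-2
  repetitions of the same case with the same workflow;
* ``D_inter`` — the maximum rater distance from the consensus;
* acceptability — the automated result is acceptable when ``D_PPro`` falls
  within the observed intra-/inter-rater variability (ties count as
  acceptable).

Per-axis adjustment vectors quantify how far (and in which direction:
left-right, anterior-posterior, superior-inferior) raters move an
automated registration they were given as a starting point. Cohorts are
summarized by median and interquartile range (linear-interpolation
percentiles). The System Usability Scale questionnaire is scored 0-100
with the conventional above-average boundary of 68.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, MissingRoundError, ValidationError
from .geometry import RigidTransform

__all__ = [
    "RaterEntry",
    "CaseRegistrations",
    "VariabilityReport",
    "rater_position",
    "consensus_position",
    "d_ppro",
    "d_intra",
    "d_inter",
    "acceptability",
    "adjustment_vector",
    "sus_score",
    "classify_sus",
    "summarize",
    "evaluate_case",
    "evaluate_cohort",
    "simulate_rater_study",
]

SUS_ABOVE_AVERAGE = 68.0
AXIS_NAMES = ("LR", "AP", "SI")


@dataclass(frozen=True)
class RaterEntry:
    rater_id: str
    round: int                      # 1 or 2
    mode: str                       # "manual" or "assisted"
    transform: RigidTransform       # MRI world -> CT world

    def __post_init__(self):
        if self.round not in (1, 2):
            raise ValidationError(f"round must be 1 or 2, got {self.round}")
        if self.mode not in ("manual", "assisted"):
            raise ValidationError(f"mode must be 'manual' or 'assisted', got {self.mode!r}")


@dataclass
class CaseRegistrations:
    """All registrations of one case: rater entries plus the automated result."""

    case_id: str
    mri_prostate_centroid: np.ndarray
    entries: List[RaterEntry] = field(default_factory=list)
    auto_transform: Optional[RigidTransform] = None

    def __post_init__(self):
        self.mri_prostate_centroid = np.asarray(self.mri_prostate_centroid, dtype=float)
        if self.mri_prostate_centroid.shape != (3,):
            raise ValidationError("mri_prostate_centroid must be a 3-vector (mm)")

    def manual_entries(self) -> List[RaterEntry]:
        return [e for e in self.entries if e.mode == "manual"]

    def raters(self) -> List[str]:
        return sorted({e.rater_id for e in self.entries})


@dataclass
class VariabilityReport:
    case_id: str
    p_avg: np.ndarray
    d_ppro: Optional[float]
    d_intra: Dict[str, float]
    d_inter: float
    acceptable_vs_intra: Optional[bool]
    acceptable_vs_inter: Optional[bool]
    n_consensus: int


def rater_position(case: CaseRegistrations, entry: RaterEntry) -> np.ndarray:
    """MRI prostate centroid mapped through the entry's transform (CT mm)."""
    return entry.transform.apply(case.mri_prostate_centroid)


def consensus_position(case: CaseRegistrations) -> np.ndarray:
    """Mean of manual rater positions (the consensus ``P_avg``).

    Only manual registrations feed the consensus; for the translation-only
    transforms used here this equals the position under the component-wise
    mean of the translations.
    """
    manual = case.manual_entries()
    if len(manual) < 2:
        raise InsufficientDataError(
            f"case {case.case_id}: need >= 2 manual registrations for a consensus, got {len(manual)}"
        )
    positions = np.array([rater_position(case, e) for e in manual])
    return positions.mean(axis=0)


def d_ppro(case: CaseRegistrations) -> float:
    """Distance of the unadjusted automated registration from the consensus."""
    if case.auto_transform is None:
        raise ValidationError(f"case {case.case_id} has no automated registration")
    auto_pos = case.auto_transform.apply(case.mri_prostate_centroid)
    return float(np.linalg.norm(auto_pos - consensus_position(case)))


def d_intra(case: CaseRegistrations, rater_id: str, mode: str = "manual") -> float:
    """Round-1 to round-2 distance for one rater (same workflow mode)."""
    rounds = {}
    for e in case.entries:
        if e.rater_id == rater_id and e.mode == mode:
            rounds[e.round] = e
    if 1 not in rounds or 2 not in rounds:
        raise MissingRoundError(
            f"case {case.case_id}, rater {rater_id}: missing a {mode} registration in "
            f"round {1 if 1 not in rounds else 2} (case switched modes between rounds?)"
        )
    p1 = rater_position(case, rounds[1])
    p2 = rater_position(case, rounds[2])
    return float(np.linalg.norm(p1 - p2))


def d_inter(case: CaseRegistrations) -> float:
    """Maximum manual-rater distance from the consensus position."""
    p_avg = consensus_position(case)
    dists = [
        float(np.linalg.norm(rater_position(case, e) - p_avg))
        for e in case.manual_entries()
    ]
    return max(dists)


def acceptability(case: CaseRegistrations) -> Tuple[Optional[bool], bool]:
    """(within intra-rater variability, within inter-rater variability).

    The automated result is compared per case against the smallest observed
    intra-rater distance and against the inter-rater spread; equality counts
    as acceptable ("falls within the range"). The intra flag is None when no
    rater completed both rounds in the same mode.
    """
    d = d_ppro(case)
    intra_vals = []
    for rater in case.raters():
        try:
            intra_vals.append(d_intra(case, rater))
        except MissingRoundError:
            continue
    vs_intra = (d <= min(intra_vals)) if intra_vals else None
    vs_inter = d <= d_inter(case)
    return vs_intra, vs_inter


def adjustment_vector(
    auto: RigidTransform, final: RigidTransform, mri_centroid
) -> Tuple[np.ndarray, float]:
    """Signed per-axis (LR, AP, SI) displacement a rater applied to the
    automated result, measured at the prostate centroid, plus its magnitude."""
    c = np.asarray(mri_centroid, dtype=float)
    delta = final.apply(c) - auto.apply(c)
    return delta, float(np.linalg.norm(delta))


def classify_sus(score: float) -> str:
    """Above-average rule: strictly greater than the conventional 68 boundary."""
    return "above average" if score > SUS_ABOVE_AVERAGE else "not above average"


def sus_score(responses: Sequence[int]) -> Tuple[float, str]:
    """Standard System Usability Scale score and its classification.

    Ten Likert items in 1..5; odd items contribute ``response - 1``, even
    items ``5 - response``; the sum is scaled by 2.5 to 0-100. Scores
    strictly above 68 are classified "above average".
    """
    responses = list(responses)
    if len(responses) != 10:
        raise ValidationError(f"SUS needs exactly 10 responses, got {len(responses)}")
    total = 0.0
    for i, r in enumerate(responses, start=1):
        if not (1 <= r <= 5):
            raise ValidationError(f"SUS response {i} out of range 1..5: {r}")
        total += (r - 1) if i % 2 == 1 else (5 - r)
    score = total * 2.5
    return score, classify_sus(score)


def summarize(values: Sequence[float]) -> Dict[str, float]:
    """Median and IQR (25th/75th percentiles, linear interpolation)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValidationError("cannot summarize an empty list")
    q25, med, q75 = np.percentile(vals, [25.0, 50.0, 75.0])
    return {
        "median": float(med),
        "iqr_low": float(q25),
        "iqr_high": float(q75),
        "n": int(vals.size),
        "percentile_convention": "linear interpolation",
    }


def evaluate_case(case: CaseRegistrations) -> VariabilityReport:
    p_avg = consensus_position(case)
    intra = {}
    for rater in case.raters():
        try:
            intra[rater] = d_intra(case, rater)
        except MissingRoundError:
            continue
    dp = d_ppro(case) if case.auto_transform is not None else None
    vs_intra, vs_inter = acceptability(case) if case.auto_transform is not None else (None, None)
    return VariabilityReport(
        case_id=case.case_id,
        p_avg=p_avg,
        d_ppro=dp,
        d_intra=intra,
        d_inter=d_inter(case),
        acceptable_vs_intra=vs_intra,
        acceptable_vs_inter=vs_inter,
        n_consensus=len(case.manual_entries()),
    )


def evaluate_cohort(cases: Sequence[CaseRegistrations]) -> pd.DataFrame:
    """Per-case metric table for a cohort (one row per case)."""
    rows = []
    for case in cases:
        rep = evaluate_case(case)
        rows.append(
            {
                "case_id": rep.case_id,
                "n_consensus": rep.n_consensus,
                "d_ppro_mm": rep.d_ppro,
                "d_inter_mm": rep.d_inter,
                "d_intra_min_mm": min(rep.d_intra.values()) if rep.d_intra else np.nan,
                "d_intra_median_mm": float(np.median(list(rep.d_intra.values()))) if rep.d_intra else np.nan,
                "acceptable_vs_intra": rep.acceptable_vs_intra,
                "acceptable_vs_inter": rep.acceptable_vs_inter,
            }
        )
    return pd.DataFrame(rows)


def simulate_rater_study(
    n_cases: int,
    n_raters: int = 3,
    sigma: float = 1.5,
    seed: int = 0,
    auto_sigma: float = 0.0,
) -> List[CaseRegistrations]:
    """Emulate a rater study: truth + per-axis Gaussian jitter.

    Each case has a true MRI->CT translation; every rater produces a
    registration in each of two rounds whose position errs from truth by
    independent N(0, sigma^2) per axis. The automated transform errs by
    N(0, auto_sigma^2) per axis (exact when ``auto_sigma`` is 0). Used to
    check that the metric suite recovers the sampling distributions these
    jitters imply.
    """
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        centroid = rng.uniform(80.0, 320.0, size=3)
        truth = rng.uniform(-15.0, 15.0, size=3)
        entries = []
        for r in range(n_raters):
            for rnd in (1, 2):
                jitter = rng.normal(0.0, sigma, size=3)
                entries.append(
                    RaterEntry(
                        rater_id=f"R{r + 1}",
                        round=rnd,
                        mode="manual",
                        transform=RigidTransform.from_translation(truth + jitter),
                    )
                )
        auto_err = rng.normal(0.0, auto_sigma, size=3) if auto_sigma > 0 else np.zeros(3)
        cases.append(
            CaseRegistrations(
                case_id=f"case{i:04d}",
                mri_prostate_centroid=centroid,
                entries=entries,
                auto_transform=RigidTransform.from_translation(truth + auto_err),
            )
        )
    return cases
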