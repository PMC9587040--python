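"""Dataset construction: exclusions, estimated BMI, classifications.

Builds the "Analysis table" from raw report bundles the way a
disproportionality study constructs its denominator: reports with missing
or unclear sex, age, height or weight are excluded; height and weight
arrive as 10-unit bands, so a continuous estimated BMI (eBMI) is computed
from each band's intermediate value; eBMI outliers are trimmed by the
boxplot rule; the remaining cases carry an event flag for the target
MedDRA preferred-term code.  A separate "time-to-onset table" restricts to
event cases with fully dated drug-start and event-onset records.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .jader_io import OUTCOMES, CaseBundle

logger = logging.getLogger("srs_signal")

#: Quantile rule used everywhere (boxplot bounds, onset medians/IQRs):
#: linear interpolation between order statistics at positions (n+1)p.
QUANTILE_METHOD = "weibull"

EBMI_UNDERWEIGHT_CUT = 18.5   # kg/m^2, eBMI < cut → underweight
EBMI_OBESE_CUT = 25.0         # kg/m^2, eBMI >= cut → obese

_BAND_RE = re.compile(r"^\s*(\d+)\s*[-‒–]\s*(\d+)\s*$")


def quantile(values, p, method: str = QUANTILE_METHOD) -> float:
    """Quantile under the configured rule (shared by all modules)."""
    return float(np.quantile(np.asarray(values, dtype=float), p, method=method))


# --------------------------------------------------------------------------
# Band arithmetic and eBMI
# --------------------------------------------------------------------------

def parse_band(band: str) -> tuple[int, int]:
    """Parse a 10-unit range label like ``"160-169"`` into ``(160, 169)``.

    The youngest age band is labelled ``"<10"`` and parses as ``(0, 9)``.
    """
    if (band or "").strip() == "<10":
        return 0, 9
    m = _BAND_RE.match(band or "")
    if not m:
        raise ValueError(f"unparseable band label: {band!r}")
    lo, hi = int(m.group(1)), int(m.group(2))
    if hi - lo != 9:
        raise ValueError(f"band {band!r} is not a 10-unit range")
    return lo, hi


def intermediate_value(band: str) -> float:
    """Intermediate value of a 10-unit band: lower bound + 5.

    A height band of 160‒169 cm maps to 165 cm and a weight band of 50‒59
    kg to 55 kg, the representative values from which eBMI is computed.
    """
    lo, _ = parse_band(band)
    return float(lo + 5)


def compute_ebmi(height_band: str, weight_band: str) -> float:
    """Estimated BMI from banded height (cm) and weight (kg), in kg/m².

    eBMI = intermediate weight / (intermediate height in m)², reported to
    one decimal (the resolution the banded inputs support); e.g. bands
    160‒169 cm and 50‒59 kg give 55 / 1.65² = 20.2 kg/m².
    """
    h_m = intermediate_value(height_band) / 100.0
    w_kg = intermediate_value(weight_band)
    return round(w_kg / (h_m * h_m), 1)


def classify_ebmi(ebmi: float) -> str:
    """Three-class body type: underweight < 18.5 ≤ normal < 25.0 ≤ obese."""
    if ebmi < EBMI_UNDERWEIGHT_CUT:
        return "underweight"
    if ebmi < EBMI_OBESE_CUT:
        return "normal"
    return "obese"


def ebmi_outlier_bounds(values: Iterable[float],
                        method: str = QUANTILE_METHOD) -> tuple[float, float]:
    """Boxplot outlier bounds: (Q1 − 1.5·IQR, Q3 + 1.5·IQR).

    Requires at least four values; quartiles follow the configured
    quantile rule.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4:
        raise ValueError(f"need >= 4 values for outlier bounds, got {arr.size}")
    q1 = quantile(arr, 0.25, method)
    q3 = quantile(arr, 0.75, method)
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def age_band_ge60(age_band: str) -> bool:
    """Elderly stratum flag: band lower bound ≥ 60."""
    lo, _ = parse_band(age_band)
    return lo >= 60


# --------------------------------------------------------------------------
# Analysis table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisCase:
    """One cleaned report, the unit of every downstream analysis."""
    case_id: str
    sex: str                      # "male" | "female"
    age_band: str
    age_ge60: bool
    ebmi: float                   # kg/m^2
    ebmi_class: str               # underweight | normal | obese
    exposed_drugs: frozenset[str]
    event: bool
    outcome: str | None


@dataclass
class FlowchartCounts:
    """Per-stage accounting of the dataset-construction flow."""
    n_input: int = 0
    n_excluded_missing: int = 0
    n_complete: int = 0           # n_input − n_excluded_missing
    n_excluded_outlier: int = 0
    n_analysis: int = 0           # n_complete − n_excluded_outlier
    n_event: int = 0
    n_tto: int = 0

    def to_rows(self) -> list[tuple[str, int]]:
        return [
            ("reports_input", self.n_input),
            ("excluded_missing_demographics", self.n_excluded_missing),
            ("complete_demographics", self.n_complete),
            ("excluded_ebmi_outlier", self.n_excluded_outlier),
            ("analysis_table", self.n_analysis),
            ("event_cases", self.n_event),
            ("time_to_onset_cases", self.n_tto),
        ]


def _demo_complete(bundle: CaseBundle) -> bool:
    d = bundle.demo
    if d.sex not in ("male", "female"):
        return False
    for band in (d.age_band, d.height_band, d.weight_band):
        if band is None:
            return False
        try:
            parse_band(band)
        except ValueError:
            return False
    return True


def build_analysis_table(
    bundles: Sequence[CaseBundle],
    target_pt_code: str,
    quantile_method: str = QUANTILE_METHOD,
    drug_roles: Sequence[str] | None = None,
) -> tuple[list[AnalysisCase], FlowchartCounts]:
    """Apply the exclusion flow and return the Analysis table.

    Steps, in order: (1) exclude reports with missing/unclear sex, age,
    height or weight; (2) compute eBMI for the remainder; (3) compute
    boxplot outlier bounds on the pooled eBMI distribution and exclude
    values outside them; (4) classify eBMI and the ≥60 age stratum and
    flag the target event.  Every exclusion is counted.

    ``drug_roles`` optionally restricts the exposure set to given roles
    (default: all roles count as exposure).
    """
    counts = FlowchartCounts(n_input=len(bundles))
    complete: list[tuple[CaseBundle, float]] = []
    for bundle in bundles:
        if not _demo_complete(bundle):
            counts.n_excluded_missing += 1
            continue
        ebmi = compute_ebmi(bundle.demo.height_band, bundle.demo.weight_band)
        complete.append((bundle, ebmi))
    counts.n_complete = len(complete)

    kept = complete
    if len(complete) >= 4:
        low, high = ebmi_outlier_bounds([e for _, e in complete], quantile_method)
        kept = [(b, e) for b, e in complete if low <= e <= high]
        counts.n_excluded_outlier = len(complete) - len(kept)
        if counts.n_excluded_outlier:
            logger.info("excluded %d eBMI outliers outside (%.1f, %.1f)",
                        counts.n_excluded_outlier, low, high)

    cases: list[AnalysisCase] = []
    for bundle, ebmi in kept:
        target_rows = [r for r in bundle.reactions
                       if r.pt_code == target_pt_code]
        event = len(target_rows) > 0
        outcome = None
        for r in target_rows:
            if r.outcome is not None:
                outcome = r.outcome
                break
        if drug_roles is None:
            exposed = frozenset(d.drug_name for d in bundle.drugs)
        else:
            roles = set(drug_roles)
            exposed = frozenset(d.drug_name for d in bundle.drugs
                                if d.role in roles)
        cases.append(AnalysisCase(
            case_id=bundle.case_id,
            sex=bundle.demo.sex,
            age_band=bundle.demo.age_band,
            age_ge60=age_band_ge60(bundle.demo.age_band),
            ebmi=ebmi,
            ebmi_class=classify_ebmi(ebmi),
            exposed_drugs=exposed,
            event=event,
            outcome=outcome,
        ))
    counts.n_analysis = len(cases)
    counts.n_event = sum(c.event for c in cases)
    logger.info("analysis table: %d input, %d excluded missing, %d excluded "
                "outlier, %d retained, %d event cases",
                counts.n_input, counts.n_excluded_missing,
                counts.n_excluded_outlier, counts.n_analysis, counts.n_event)
    return cases, counts


# --------------------------------------------------------------------------
# Time-to-onset table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OnsetRecord:
    """Shortest fully-dated drug-start → event-onset duration, in days."""
    case_id: str
    drug_name: str
    duration_days: float     # > 0; same-day onsets carry 0.5
    start_date: str
    onset_date: str


def build_tto_table(
    bundles: Sequence[CaseBundle],
    event_case_ids: Iterable[str],
    target_pt_code: str,
) -> tuple[list[OnsetRecord], int]:
    """Durations from drug start to event onset for fully dated records.

    For each event case the earliest fully dated onset of the target event
    is paired with every fully dated drug-start record; per (case, drug)
    only the shortest duration is kept.  Negative durations (onset before
    start) are data errors: dropped and counted in the second return
    value.  Zero-day durations map to 0.5 days so same-day onsets stay in
    the strictly positive lifetime domain.
    """
    event_ids = set(event_case_ids)
    by_id = {b.case_id: b for b in bundles}
    records: list[OnsetRecord] = []
    n_negative = 0
    for cid in sorted(event_ids):
        bundle = by_id.get(cid)
        if bundle is None:
            continue
        onsets = [(r.onset, r.onset_date) for r in bundle.reactions
                  if r.pt_code == target_pt_code and r.onset is not None]
        if not onsets:
            continue
        onset, onset_raw = min(onsets)
        best: dict[str, tuple[float, str]] = {}
        for drug in bundle.drugs:
            start = drug.start
            if start is None:
                continue
            days = float((onset - start).days)
            if days < 0:
                n_negative += 1
                continue
            if days == 0.0:
                days = 0.5
            prev = best.get(drug.drug_name)
            if prev is None or days < prev[0]:
                best[drug.drug_name] = (days, drug.start_date)
        for name in sorted(best):
            days, start_raw = best[name]
            records.append(OnsetRecord(cid, name, days, start_raw, onset_raw))
    if n_negative:
        logger.warning("dropped %d negative drug-start→onset durations",
                       n_negative)
    return records, n_negative


# --------------------------------------------------------------------------
# Drugs of interest and outcomes
# --------------------------------------------------------------------------

#: Frequency strata for the drugs-of-interest table, by event-case count.
FREQUENCY_STRATA = (
    (">100", lambda n: n > 100),
    ("20-100", lambda n: 20 <= n <= 100),
    ("10-19", lambda n: 10 <= n <= 19),
    ("5-9", lambda n: 5 <= n <= 9),
)


def frequency_stratum(n: int) -> str:
    for label, rule in FREQUENCY_STRATA:
        if rule(n):
            return label
    raise ValueError(f"count {n} below the drugs-of-interest threshold")


def drugs_of_interest(
    analysis_cases: Sequence[AnalysisCase],
    min_cases: int = 5,
) -> "pd.DataFrame":
    """Drugs administered in at least ``min_cases`` event cases.

    Returns a frame with columns drug, n_cases, stratum, sorted by
    descending count then drug name; counts are distinct event cases
    exposed to the drug.
    """
    import pandas as pd
    counts: Counter[str] = Counter()
    for case in analysis_cases:
        if case.event:
            counts.update(case.exposed_drugs)
    rows = [(drug, n, frequency_stratum(n))
            for drug, n in counts.items() if n >= min_cases]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["drug", "n_cases", "stratum"])


def tabulate_outcomes(
    analysis_cases: Sequence[AnalysisCase],
) -> "OrderedDict[str, int]":
    """Event-case counts per clinical outcome category (missing excluded)."""
    counts: "OrderedDict[str, int]" = OrderedDict((o, 0) for o in OUTCOMES)
    for case in analysis_cases:
        if case.event and case.outcome is not None:
            counts[case.outcome] += 1
    return counts
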