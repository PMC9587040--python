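"""Reporting-odds-ratio disproportionality screen.

For each drug of interest the analysis table is partitioned into the
classic two-by-two layout — a: event & exposed, b: event & unexposed,
c: non-event & exposed, d: non-event & unexposed — and the reporting odds
ratio ROR = ad/bc is computed with a Woolf (log-normal) 95% confidence
interval, exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)).  A drug is
signal-positive when the lower confidence bound exceeds 1.  No
multiplicity adjustment is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .cohort import AnalysisCase
from .jader_io import fmt2

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # event & drug
    b: int  # event & no drug
    c: int  # no event & drug
    d: int  # no event & no drug

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RorResult:
    drug_name: str
    table: ContingencyTable
    ror: float | None
    ci_low: float | None
    ci_high: float | None
    signal: bool
    defined: bool


def make_table(analysis_cases: Sequence[AnalysisCase],
               drug_name: str) -> ContingencyTable:
    """Two-by-two event-by-exposure counts over the analysis table."""
    a = b = c = d = 0
    for case in analysis_cases:
        exposed = drug_name in case.exposed_drugs
        if case.event:
            a += exposed
            b += not exposed
        else:
            c += exposed
            d += not exposed
    return ContingencyTable(a, b, c, d)


def ror(table: ContingencyTable, drug_name: str = "",
        haldane: bool = False) -> RorResult:
    """Reporting odds ratio with Woolf 95% CI and the signal flag.

    A zero cell leaves the estimate undefined unless ``haldane`` enables
    the Haldane–Anscombe +0.5 correction on every cell.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        if not haldane:
            return RorResult(drug_name, table, None, None, None,
                             signal=False, defined=False)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    estimate = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_ror = math.log(estimate)
    ci_low = math.exp(log_ror - Z95 * se)
    ci_high = math.exp(log_ror + Z95 * se)
    return RorResult(drug_name, table, estimate, ci_low, ci_high,
                     signal=ci_low > 1.0, defined=True)


def screen(analysis_cases: Sequence[AnalysisCase],
           drugs: Iterable[str], haldane: bool = False) -> list[RorResult]:
    """One crude ROR per drug, sorted by descending event-exposed count."""
    results = [ror(make_table(analysis_cases, name), name, haldane)
               for name in drugs]
    results.sort(key=lambda r: (-r.table.a, r.drug_name))
    return results


def screen_to_frame(results: Sequence[RorResult]) -> pd.DataFrame:
    """Report-ready frame (odds ratios and bounds rendered to 2 decimals)."""
    rows = []
    for r in results:
        t = r.table
        rows.append({
            "drug": r.drug_name, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": fmt2(r.ror), "ci_low": fmt2(r.ci_low),
            "ci_high": fmt2(r.ci_high),
            "signal": str(bool(r.signal)).lower(),
            "defined": str(bool(r.defined)).lower(),
        })
    return pd.DataFrame(rows, columns=["drug", "a", "b", "c", "d", "ror",
                                       "ci_low", "ci_high", "signal",
                                       "defined"])
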