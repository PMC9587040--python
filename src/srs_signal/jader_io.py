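"""Reading, validating and joining spontaneous-reporting-system tables.

The expected layout mirrors the Japanese Adverse Drug Event Report (JADER)
database: four CSV tables — DEMO (per-report demographics with banded
age/height/weight), DRUG (per-report drug records), REAC (per-report adverse
events coded by MedDRA preferred-term code) and HIST (medical history) —
linked by a report identifier.  The canonical schema here uses English
column names and tokens; :data:`COLUMN_ALIASES` and :data:`TOKEN_ALIASES`
document the mapping from the raw Japanese distribution so a real extract
can be ingested after header translation.

All downstream analysis consumes :class:`CaseBundle` objects, one per DEMO
row, carrying that report's drug and reaction records.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("srs_signal")

# --------------------------------------------------------------------------
# Canonical schema
# --------------------------------------------------------------------------

DEMO_COLUMNS = ["case_id", "sex", "age_band", "height_band", "weight_band"]
DRUG_COLUMNS = ["case_id", "drug_name", "role", "start_date", "end_date"]
REAC_COLUMNS = ["case_id", "pt_code", "pt_name", "onset_date", "outcome"]
HIST_COLUMNS = ["case_id", "history_term"]

SEXES = ("male", "female")
DRUG_ROLES = ("suspected", "concomitant", "interacting", "unknown")
OUTCOMES = ("Uncertain", "Recovered", "Improved", "Unimproved",
            "WithSequelae", "Death")

#: Header translation for the raw JADER distribution (extend as needed).
COLUMN_ALIASES: Mapping[str, str] = {
    "識別番号": "case_id",
    "性別": "sex",
    "年齢": "age_band",
    "身長": "height_band",
    "体重": "weight_band",
    "医薬品（一般名）": "drug_name",
    "医薬品の関与": "role",
    "投与開始日": "start_date",
    "投与終了日": "end_date",
    "有害事象": "pt_name",
    "有害事象発現日": "onset_date",
    "転帰": "outcome",
    "原疾患等": "history_term",
}

#: Value-token translation for the raw distribution.
TOKEN_ALIASES: Mapping[str, str] = {
    "男性": "male",
    "女性": "female",
    "不明": "",          # "unknown" → missing
    "被疑薬": "suspected",
    "併用薬": "concomitant",
    "相互作用": "interacting",
    "回復": "Recovered",
    "軽快": "Improved",
    "未回復": "Unimproved",
    "後遺症あり": "WithSequelae",
    "死亡": "Death",
}


class SchemaError(ValueError):
    """A table header does not match the documented schema."""


class IntegrityError(ValueError):
    """A structural invariant of the tables is violated."""


# --------------------------------------------------------------------------
# Record types
# --------------------------------------------------------------------------

def parse_date(raw: str | None) -> tuple[_dt.date | None, bool]:
    """Parse an 8-digit ``YYYYMMDD`` date string.

    Returns ``(date, partial)``.  Six-digit ``YYYYMM`` (or other short)
    forms are retained by callers as raw strings but flagged partial and
    return ``(None, True)``; empty/missing values return ``(None, False)``.
    """
    if raw is None:
        return None, False
    raw = str(raw).strip()
    if not raw or raw.lower() == "nan":
        return None, False
    if len(raw) == 8 and raw.isdigit():
        try:
            return _dt.date(int(raw[:4]), int(raw[4:6]), int(raw[6:])), False
        except ValueError:
            return None, True
    return None, True


@dataclass(frozen=True)
class DemoRecord:
    case_id: str
    sex: str | None            # "male" / "female" / None
    age_band: str | None       # decade label "60-69" or None
    height_band: str | None    # 10-cm band "160-169" or None
    weight_band: str | None    # 10-kg band "50-59" or None


@dataclass(frozen=True)
class DrugRecord:
    case_id: str
    drug_name: str
    role: str                  # one of DRUG_ROLES
    start_date: str            # raw string, possibly partial/empty
    end_date: str

    @property
    def start(self) -> _dt.date | None:
        """Fully parsed start date, or None for missing/partial values."""
        return parse_date(self.start_date)[0]

    @property
    def start_is_partial(self) -> bool:
        return parse_date(self.start_date)[1]


@dataclass(frozen=True)
class ReacRecord:
    case_id: str
    pt_code: str
    pt_name: str
    onset_date: str            # raw string, possibly partial/empty
    outcome: str | None        # one of OUTCOMES or None

    @property
    def onset(self) -> _dt.date | None:
        return parse_date(self.onset_date)[0]


@dataclass
class CaseBundle:
    """One spontaneous report: demographics plus its drug and event rows."""
    demo: DemoRecord
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: list[ReacRecord] = field(default_factory=list)

    @property
    def case_id(self) -> str:
        return self.demo.case_id


@dataclass
class ReadReport:
    """Row accounting for one ingestion pass."""
    n_demo: int = 0
    n_drug: int = 0
    n_reac: int = 0
    n_hist: int = 0
    orphan_drug_rows: int = 0
    orphan_reac_rows: int = 0
    warnings: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------

def _read_csv(path: str | Path, expected: Sequence[str], table: str) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    got = list(frame.columns)
    if got != list(expected):
        missing = [c for c in expected if c not in got]
        extra = [c for c in got if c not in expected]
        offending = (missing or extra or ["<column order>"])[0]
        raise SchemaError(
            f"{table} header mismatch at column {offending!r}: "
            f"expected {list(expected)}, got {got}"
        )
    return frame


def _clean(value: str) -> str | None:
    value = value.strip()
    return value if value else None


def read_tables(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    hist_path: str | Path,
) -> tuple[list[CaseBundle], ReadReport]:
    """Read the four tables and join them into one bundle per DEMO report.

    DRUG/REAC rows whose case_id does not appear in DEMO are counted in the
    returned :class:`ReadReport` rather than silently dropped.  HIST is
    parsed for schema validation only and never attached (the linkage is
    not used by any analysis stage).
    """
    demo = _read_csv(demo_path, DEMO_COLUMNS, "DEMO")
    drug = _read_csv(drug_path, DRUG_COLUMNS, "DRUG")
    reac = _read_csv(reac_path, REAC_COLUMNS, "REAC")
    hist = _read_csv(hist_path, HIST_COLUMNS, "HIST")

    report = ReadReport(n_demo=len(demo), n_drug=len(drug),
                        n_reac=len(reac), n_hist=len(hist))

    if demo["case_id"].duplicated().any():
        dup = demo.loc[demo["case_id"].duplicated(), "case_id"].iloc[0]
        raise IntegrityError(f"duplicate DEMO case_id {dup!r}")
    if (demo["case_id"].str.strip() == "").any():
        raise IntegrityError("empty DEMO case_id")

    bundles: dict[str, CaseBundle] = {}
    for row in demo.itertuples(index=False):
        sex = _clean(row.sex)
        if sex is not None and sex not in SEXES:
            sex = None
        bundles[row.case_id] = CaseBundle(DemoRecord(
            case_id=row.case_id,
            sex=sex,
            age_band=_clean(row.age_band),
            height_band=_clean(row.height_band),
            weight_band=_clean(row.weight_band),
        ))

    if len(drug) == 0:
        report.warnings.append("DRUG table is empty")
        logger.warning("DRUG table is empty")
    for row in drug.itertuples(index=False):
        bundle = bundles.get(row.case_id)
        if bundle is None:
            report.orphan_drug_rows += 1
            continue
        role = row.role.strip() if row.role.strip() in DRUG_ROLES else "unknown"
        bundle.drugs.append(DrugRecord(
            case_id=row.case_id, drug_name=row.drug_name.strip(),
            role=role, start_date=row.start_date.strip(),
            end_date=row.end_date.strip(),
        ))

    for row in reac.itertuples(index=False):
        bundle = bundles.get(row.case_id)
        if bundle is None:
            report.orphan_reac_rows += 1
            continue
        outcome = _clean(row.outcome)
        if outcome is not None and outcome not in OUTCOMES:
            outcome = None
        bundle.reactions.append(ReacRecord(
            case_id=row.case_id, pt_code=row.pt_code.strip(),
            pt_name=row.pt_name.strip(),
            onset_date=row.onset_date.strip(), outcome=outcome,
        ))

    if report.orphan_drug_rows or report.orphan_reac_rows:
        logger.warning("orphan rows: %d DRUG, %d REAC",
                       report.orphan_drug_rows, report.orphan_reac_rows)
    return list(bundles.values()), report


def bundles_from_frames(
    demo: pd.DataFrame, drug: pd.DataFrame, reac: pd.DataFrame
) -> list[CaseBundle]:
    """Build bundles directly from in-memory canonical-schema frames.

    Fast path used by the pipeline when the tables come straight from the
    simulator; applies the same joining rules as :func:`read_tables` but
    assumes validated schema and unique case ids.
    """
    bundles: dict[str, CaseBundle] = {}
    for row in demo.itertuples(index=False):
        bundles[row.case_id] = CaseBundle(DemoRecord(
            case_id=row.case_id, sex=_clean(str(row.sex)),
            age_band=_clean(str(row.age_band)),
            height_band=_clean(str(row.height_band)),
            weight_band=_clean(str(row.weight_band)),
        ))
    for row in drug.itertuples(index=False):
        bundle = bundles.get(row.case_id)
        if bundle is not None:
            bundle.drugs.append(DrugRecord(
                row.case_id, str(row.drug_name), str(row.role),
                str(row.start_date), str(row.end_date)))
    for row in reac.itertuples(index=False):
        bundle = bundles.get(row.case_id)
        if bundle is not None:
            outcome = _clean(str(row.outcome))
            bundle.reactions.append(ReacRecord(
                row.case_id, str(row.pt_code), str(row.pt_name),
                str(row.onset_date),
                outcome if outcome in OUTCOMES else None))
    return list(bundles.values())


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------

# Report rounding: odds ratios and CI bounds to 2 decimals, eBMI and days
# to 1 decimal (the precision the report tables carry).

def fmt2(x) -> str:
    return "" if x is None or (isinstance(x, float) and x != x) else f"{float(x):.2f}"


def fmt1(x) -> str:
    return "" if x is None or (isinstance(x, float) and x != x) else f"{float(x):.1f}"


REPORT_FILES = (
    "flowchart.tsv", "drug_groups.tsv", "ror_screen.tsv",
    "tto_summary.tsv", "regression_all.tsv", "regression_by_sex.tsv",
)


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV deterministically (fixed column order, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_report_tables(results: Mapping[str, pd.DataFrame],
                        out_dir: str | Path) -> list[Path]:
    """Write every pipeline output table as a byte-stable TSV.

    ``results`` maps output stem ("flowchart", "ror_screen", ...) to an
    already-formatted DataFrame; formatting (column order, rounding) is the
    producing module's responsibility so that writing is a pure dump.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for stem, frame in results.items():
        path = out / f"{stem}.tsv"
        write_tsv(frame, path)
        written.append(path)
    return written


def write_input_tables(tables: Mapping[str, pd.DataFrame],
                       out_dir: str | Path) -> list[Path]:
    """Write DEMO/DRUG/REAC/HIST frames as canonical-schema CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in ("demo", "drug", "reac", "hist"):
        path = out / f"{name}.csv"
        tables[name].to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    return written
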