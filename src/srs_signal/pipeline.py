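"""End-to-end orchestration: tables → cohort → screen → onset → model.

One :func:`run` executes every stage in dataset-construction order on
either a directory of report tables or a simulated registry, writes the
report TSVs plus a JSON manifest (config echo, seed, stage timings,
exclusion counts), and is deterministic for a fixed config and seed.
:func:`run_stages` is the in-memory core used by tests and replicate
studies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort, disproportionality, regression, time_to_onset
from .jader_io import (CaseBundle, bundles_from_frames, read_tables,
                       write_input_tables, write_report_tables)
from .synthetic_data import SimulationConfig, simulate

logger = logging.getLogger("srs_signal")


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Either ``input_dir`` (canonical-schema CSV tables) or ``simulation``
    must be provided; a ``seed`` given here overrides the simulation
    config's own seed so one integer governs the whole run.
    """
    input_dir: str | None = None
    simulation: SimulationConfig | None = None
    target_pt_code: str = "10056979"
    min_drug_cases: int = 5
    min_tto_cases: int = 10
    quantile_rule: str = cohort.QUANTILE_METHOD
    haldane_correction: bool = False
    alpha_enter: float = 0.05
    alpha_remove: float = 0.05
    excluded_candidates: frozenset[str] = regression.DEFAULT_EXCLUDED
    subset_drugs: tuple[str, ...] | None = None
    drug_roles: tuple[str, ...] | None = None
    seed: int | None = None
    output_dir: str = "out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim_raw = dict(raw["simulation"])
            if "drug_catalog" in sim_raw:
                sim_raw["drug_catalog"] = [tuple(x)
                                           for x in sim_raw["drug_catalog"]]
            if "onset_models" in sim_raw:
                sim_raw["onset_models"] = {
                    k: tuple(v) for k, v in sim_raw["onset_models"].items()}
            raw["simulation"] = SimulationConfig(**sim_raw)
        if "excluded_candidates" in raw:
            raw["excluded_candidates"] = frozenset(raw["excluded_candidates"])
        if raw.get("subset_drugs") is not None:
            raw["subset_drugs"] = tuple(raw["subset_drugs"])
        if raw.get("drug_roles") is not None:
            raw["drug_roles"] = tuple(raw["drug_roles"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """All stage outputs of one run, in memory."""
    analysis_cases: list
    flowchart: cohort.FlowchartCounts
    drug_groups: pd.DataFrame
    outcomes: Mapping[str, int]
    ror_results: list
    onset_records: list
    n_negative_durations: int
    weibull_fits: list
    main_fit: regression.LogisticFit | None
    main_design: pd.DataFrame | None
    main_outcome: np.ndarray | None
    sex_fits: Mapping[str, regression.LogisticFit]
    sex_frames: Mapping[str, tuple[pd.DataFrame, np.ndarray]]
    subset_drugs: tuple[str, ...]

    def report_tables(self) -> dict[str, pd.DataFrame]:
        """Report-ready TSV frames keyed by output stem."""
        flow = pd.DataFrame(self.flowchart.to_rows(),
                            columns=["stage", "count"])
        outcomes = pd.DataFrame(list(self.outcomes.items()),
                                columns=["outcome", "n"])
        tables = {
            "flowchart": flow,
            "outcomes": outcomes,
            "drug_groups": self.drug_groups,
            "ror_screen": disproportionality.screen_to_frame(self.ror_results),
            "tto_summary": time_to_onset.profile_to_frame(self.weibull_fits),
        }
        if self.main_fit is not None:
            tables["regression_all"] = regression.fit_to_frame(
                self.main_fit, self.main_design, self.main_outcome,
                "all", regression.FORCED_TERMS)
        else:
            tables["regression_all"] = regression.fit_to_frame(
                regression.LogisticFit([], np.array([]), np.array([]),
                                       np.array([]), np.empty((0, 2)),
                                       np.array([]), 0.0, [], None, [],
                                       True, 0),
                pd.DataFrame(), np.array([]), "all", ())
        sex_rows = []
        for sex in ("female", "male"):
            if sex in self.sex_fits:
                design, y = self.sex_frames[sex]
                sex_rows.append(regression.fit_to_frame(
                    self.sex_fits[sex], design, y, sex, ()))
        tables["regression_by_sex"] = (
            pd.concat(sex_rows, ignore_index=True) if sex_rows
            else regression.fit_to_frame(
                regression.LogisticFit([], np.array([]), np.array([]),
                                       np.array([]), np.empty((0, 2)),
                                       np.array([]), 0.0, [], None, [],
                                       True, 0),
                pd.DataFrame(), np.array([]), "none", ()))
        return tables


def run_stages(bundles: Sequence[CaseBundle],
               config: RunConfig) -> PipelineResult:
    """Execute cohort → screen → regression → time-to-onset in memory."""
    cases, flow = cohort.build_analysis_table(
        bundles, config.target_pt_code,
        quantile_method=config.quantile_rule,
        drug_roles=config.drug_roles)
    drug_groups = cohort.drugs_of_interest(cases, config.min_drug_cases)
    outcomes = cohort.tabulate_outcomes(cases)
    doi = list(drug_groups["drug"])

    ror_results = disproportionality.screen(cases, doi,
                                            config.haldane_correction)

    main_fit = None
    design = None
    y = None
    selected: list[str] = []
    if cases and any(c.event for c in cases):
        design, y = regression.build_design(cases, doi)
        spec = regression.ModelSpec(
            candidate_terms=tuple(doi),
            alpha_enter=config.alpha_enter,
            alpha_remove=config.alpha_remove,
            excluded_candidates=config.excluded_candidates)
        main_fit = regression.stepwise_select(spec, design, y)
        selected = main_fit.selected_drugs

    # by-sex subset models with fixed terms: the configured drugs, or the
    # two stepwise-selected drugs most frequent among event cases
    if config.subset_drugs is not None:
        subset_drugs = tuple(config.subset_drugs)
    else:
        by_count = {r.drug_name: r.table.a for r in ror_results}
        subset_drugs = tuple(sorted(
            selected, key=lambda d: (-by_count.get(d, 0), d))[:2])
    sex_fits: dict[str, regression.LogisticFit] = {}
    sex_frames: dict[str, tuple[pd.DataFrame, np.ndarray]] = {}
    if subset_drugs:
        try:
            sex_fits = regression.subset_by_sex(cases, subset_drugs)
            for sex in ("female", "male"):
                subset = [c for c in cases if c.sex == sex]
                d, yy = regression.build_design(subset, subset_drugs)
                cols = (["age_ge60", "ebmi_obese", "ebmi_underweight"]
                        + list(subset_drugs))
                sex_frames[sex] = (d[cols], yy)
        except (ValueError, regression.SeparationError) as exc:
            logger.warning("by-sex subset models skipped: %s", exc)
            sex_fits, sex_frames = {}, {}

    event_ids = [c.case_id for c in cases if c.event]
    onset_records, n_negative = cohort.build_tto_table(
        bundles, event_ids, config.target_pt_code)
    flow.n_tto = len({r.case_id for r in onset_records})
    # per-drug onset profiling restricted to model-selected drugs
    selected_records = [r for r in onset_records if r.drug_name in selected]
    fits = time_to_onset.tto_profile(selected_records, config.min_tto_cases)

    return PipelineResult(
        analysis_cases=cases, flowchart=flow, drug_groups=drug_groups,
        outcomes=outcomes, ror_results=ror_results,
        onset_records=onset_records, n_negative_durations=n_negative,
        weibull_fits=fits, main_fit=main_fit, main_design=design,
        main_outcome=y, sex_fits=sex_fits, sex_frames=sex_frames,
        subset_drugs=subset_drugs)


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    if config.simulation is not None:
        echo["simulation"] = config.simulation.to_dict()
    echo["excluded_candidates"] = sorted(config.excluded_candidates)
    if echo.get("subset_drugs") is not None:
        echo["subset_drugs"] = list(echo["subset_drugs"])
    if echo.get("drug_roles") is not None:
        echo["drug_roles"] = list(echo["drug_roles"])
    return echo


def run(config: RunConfig) -> PipelineResult:
    """Full run with file outputs and a JSON manifest.

    Any stage error aborts with the stage name; outputs written before
    the failure are preserved.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "load"
    try:
        t0 = time.perf_counter()
        if config.input_dir is not None:
            base = Path(config.input_dir)
            bundles, read_report = read_tables(
                base / "demo.csv", base / "drug.csv",
                base / "reac.csv", base / "hist.csv")
        elif config.simulation is not None:
            sim = config.simulation
            if config.seed is not None:
                sim = dataclasses.replace(sim, seed=config.seed)
            tables, _truth = simulate(sim)
            bundles = bundles_from_frames(tables["demo"], tables["drug"],
                                          tables["reac"])
            write_input_tables(tables, out_dir / "inputs")
            read_report = None
        else:
            raise ValueError("RunConfig needs input_dir or simulation")
        timings[stage] = time.perf_counter() - t0

        stage = "analysis"
        t0 = time.perf_counter()
        result = run_stages(bundles, config)
        timings[stage] = time.perf_counter() - t0

        stage = "write"
        t0 = time.perf_counter()
        write_report_tables(result.report_tables(), out_dir)
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": _config_echo(config),
        "seed": config.seed if config.seed is not None else (
            config.simulation.seed if config.simulation else None),
        "outputs": sorted(p.name for p in out_dir.glob("*.tsv")),
        "flowchart": dict(result.flowchart.to_rows()),
        "n_negative_durations": result.n_negative_durations,
        "selected_drugs": (result.main_fit.selected_drugs
                           if result.main_fit else []),
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
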