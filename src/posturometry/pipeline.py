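"""End-to-end study orchestration: simulate -> extract -> evaluate -> report.

Three designs mirror the evaluation protocol for a screening instrument:

* ``reliability`` — two occasions per subject; per endpoint a Wilcoxon
  signed-rank test for systematic occasion differences, ICC(3,1) with
  95% CI and band, SEM, and MDC;
* ``construct_validity`` — one motion, two devices; Wilcoxon, Spearman
  with band, ICC, and Bland-Altman fixed/proportional bias;
* ``discriminative`` — patient vs control groups; Mann-Whitney U with
  group medians and IQRs.

Every report carries all 18 endpoints (explicitly marked missing when
not estimable), the missingness table, a config echo and the seed, so a
report reproduces itself exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .kinematics import FilterSpec, InvalidConfigError
from .psychometrics import (
    DegenerateDataError,
    PairedMeasurements,
    evaluate_agreement,
    evaluate_reliability,
    mann_whitney_u,
    normality_report,
)
from .synthetic import (
    SimulationConfig,
    StudyData,
    simulate_clinical_dataset,
    simulate_reliability_dataset,
    simulate_validity_dataset,
)
from .variables import VARIABLE_NAMES, variable

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_reliability",
    "run_validity",
    "run_discriminative",
    "run_study",
    "render_report",
]

log = logging.getLogger("posturometry")

_DESIGNS = ("reliability", "construct_validity", "discriminative")


@dataclass
class StudyConfig:
    """Everything one study run needs: design, generator, analysis knobs."""

    design: Literal["reliability", "construct_validity", "discriminative"]
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    percentile: float = 95.0
    alpha: float = 0.05
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.design not in _DESIGNS:
            raise InvalidConfigError(
                f"design must be one of {_DESIGNS}, got {self.design!r}")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 <= self.percentile <= 100.0:
            raise InvalidConfigError("percentile must lie in [0, 100]")


@dataclass
class StudyReport:
    """One study's per-endpoint statistics plus reproducibility metadata."""

    design: str
    table: pd.DataFrame
    missingness: pd.DataFrame
    config: dict
    seed: int
    n_comparisons: int
    version: str = __version__

    def to_json_dict(self) -> dict:
        tbl = self.table.where(pd.notna(self.table), None)
        miss = self.missingness.where(pd.notna(self.missingness), None)
        return {
            "design": self.design,
            "seed": self.seed,
            "version": self.version,
            "n_comparisons": self.n_comparisons,
            "config": self.config,
            "table": tbl.to_dict(orient="records"),
            "missingness": miss.to_dict(orient="records"),
        }


def _config_echo(config: StudyConfig) -> dict:
    d = dataclasses.asdict(config)

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, tuple):
            return [clean(v) for v in x]
        return x

    return clean(d)


def _paired_values(data: StudyData, name: str, keys_a, keys_b
                   ) -> PairedMeasurements:
    """Per-subject (A, B) pairs for one endpoint across two session keys."""
    rows = []
    for p in data.cohort:
        a = data.panel(p.subject_id, *keys_a)[name]
        b = data.panel(p.subject_id, *keys_b)[name]
        rows.append((a, b))
    return PairedMeasurements(np.array(rows, dtype=float),
                              variable_name=name, units=variable(name).unit)


def _missingness(data: StudyData) -> pd.DataFrame:
    rows = []
    for name in VARIABLE_NAMES:
        n_missing, reasons = 0, set()
        for s in data.sessions:
            if s.panel is None:
                continue
            if not math.isfinite(s.panel[name]):
                n_missing += 1
                reasons.add(s.panel.missing.get(name, "not finite"))
        rows.append({"variable": name, "n_missing": n_missing,
                     "reasons": "; ".join(sorted(reasons))})
    return pd.DataFrame(rows)


def _medians(values: np.ndarray) -> tuple[float, float, float, float]:
    """median, IQR, and the 5th/95th percentiles of the finite values."""
    v = values[np.isfinite(values)]
    if v.size == 0:
        return math.nan, math.nan, math.nan, math.nan
    q5, q25, q75, q95 = np.percentile(v, [5, 25, 75, 95])
    return float(np.median(v)), float(q75 - q25), float(q5), float(q95)


def run_reliability(config: StudyConfig) -> StudyReport:
    """Test-retest study: occasion 1 vs occasion 2 on the low-fidelity device."""
    data = simulate_reliability_dataset(config.simulation)
    log.info("reliability: seed=%d n=%d granularity=%s",
             config.simulation.master_seed, len(data.cohort),
             config.simulation.granularity)
    rows = []
    for name in VARIABLE_NAMES:
        paired = _paired_values(data, name, (1, "kinect_like"), (2, "kinect_like"))
        row = {"variable": name, "units": variable(name).unit,
               "n": paired.n, "n_excluded": paired.n_excluded}
        m1 = _medians(paired.a)
        m2 = _medians(paired.b)
        row.update(median_t1=m1[0], iqr_t1=m1[1], p5_t1=m1[2], p95_t1=m1[3],
                   median_t2=m2[0], iqr_t2=m2[1], p5_t2=m2[2], p95_t2=m2[3])
        try:
            res = evaluate_reliability(paired)
            row.update(p_systematic=res.p_systematic, icc=res.icc,
                       icc_ci_low=res.icc_ci[0], icc_ci_high=res.icc_ci[1],
                       icc_band=res.icc_band, sem=res.sem, mdc=res.mdc,
                       degenerate=res.degenerate)
            if paired.n >= 3:
                row["normality_ks_p"] = normality_report(paired.a)["ks_p"]
        except DegenerateDataError as e:
            row.update(estimable=False, reason=str(e))
        rows.append(row)
    table = pd.DataFrame(rows)
    return StudyReport("reliability", table, _missingness(data),
                       _config_echo(config), config.simulation.master_seed,
                       n_comparisons=len(VARIABLE_NAMES))


def run_validity(config: StudyConfig) -> StudyReport:
    """Device-agreement study: low-fidelity device vs laboratory reference."""
    data = simulate_validity_dataset(config.simulation)
    log.info("validity: seed=%d n=%d granularity=%s",
             config.simulation.master_seed, len(data.cohort),
             config.simulation.granularity)
    rows = []
    for name in VARIABLE_NAMES:
        paired = _paired_values(data, name, (1, "kinect_like"),
                                (1, "mocap_forceplate"))
        row = {"variable": name, "units": variable(name).unit,
               "n": paired.n, "n_excluded": paired.n_excluded}
        mk = _medians(paired.a)
        mr = _medians(paired.b)
        row.update(median_kinect=mk[0], iqr_kinect=mk[1],
                   median_reference=mr[0], iqr_reference=mr[1])
        try:
            res = evaluate_agreement(paired)
            row.update(p_systematic=res.p_systematic,
                       rho=res.rho, rho_p=res.rho_p, rho_band=res.rho_band,
                       icc=res.icc, icc_ci_low=res.icc_ci[0],
                       icc_ci_high=res.icc_ci[1],
                       bias=res.bias, loa_low=res.loa[0], loa_high=res.loa[1],
                       prop_slope=res.prop_slope, prop_p=res.prop_p,
                       degenerate=res.degenerate)
        except DegenerateDataError as e:
            row.update(estimable=False, reason=str(e))
        rows.append(row)
    table = pd.DataFrame(rows)
    return StudyReport("construct_validity", table, _missingness(data),
                       _config_echo(config), config.simulation.master_seed,
                       n_comparisons=len(VARIABLE_NAMES))


def run_discriminative(config: StudyConfig) -> StudyReport:
    """Two-group clinical study: patients vs healthy controls, one occasion."""
    data = simulate_clinical_dataset(config.simulation)
    groups = {p.subject_id: p.group for p in data.cohort}
    log.info("discriminative: seed=%d n_lbp=%d n_controls=%d",
             config.simulation.master_seed, config.simulation.n_lbp,
             config.simulation.n_controls)
    rows = []
    for name in VARIABLE_NAMES:
        a, b = [], []
        for s in data.sessions:
            (a if groups[s.subject] == "lbp" else b).append(s.panel[name])
        a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
        row = {"variable": name, "units": variable(name).unit}
        try:
            cmp = mann_whitney_u(a, b, variable_name=name,
                                 units=variable(name).unit)
            row.update(n_lbp=cmp.n_a, n_controls=cmp.n_b,
                       median_lbp=cmp.median_a, iqr_lbp=cmp.iqr_a,
                       median_controls=cmp.median_b, iqr_controls=cmp.iqr_b,
                       p=cmp.p, significant=bool(cmp.p < config.alpha))
        except ValueError as e:
            row.update(estimable=False, reason=str(e))
        rows.append(row)
    table = pd.DataFrame(rows)
    return StudyReport("discriminative", table, _missingness(data),
                       _config_echo(config), config.simulation.master_seed,
                       n_comparisons=len(VARIABLE_NAMES))


_RUNNERS = {
    "reliability": run_reliability,
    "construct_validity": run_validity,
    "discriminative": run_discriminative,
}


def run_study(config: StudyConfig) -> StudyReport:
    """Dispatch one study run by its design."""
    return _RUNNERS[config.design](config)


def render_report(report: StudyReport, out_dir, formats=("csv", "json"),
                  stem: str | None = None) -> list[Path]:
    """Write a report to disk as CSV (table + missingness) and/or JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = stem or report.design
    written = []
    if "csv" in formats:
        p = out / f"{stem}_table.csv"
        report.table.to_csv(p, index=False)
        written.append(p)
        m = out / f"{stem}_missingness.csv"
        report.missingness.to_csv(m, index=False)
        written.append(m)
    if "json" in formats:
        p = out / f"{stem}_report.json"
        p.write_text(json.dumps(report.to_json_dict(), indent=2,
                                default=_json_default))
        written.append(p)
    for p in written:
        log.info("wrote %s", p)
    return written


def _json_default(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.bool_):
        return bool(x)
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def load_report_schema() -> dict:
    """The versioned JSON schema the rendered JSON report conforms to."""
    path = Path(__file__).with_name("report_schema.json")
    return json.loads(path.read_text())
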