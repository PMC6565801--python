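"""Study orchestration: cardiac-output scenarios, slices, postures.

The steady-state flow model has no heartbeat, so the two halves of cardiac
output act through different knobs: stroke volume changes the pulmonary
trunk flow rate (CO = HR x SV), while heart rate changes the inversion time
(TI is 80% of the R-R interval).  Four scenarios span the design: varying
SV at fixed HR, varying HR at fixed SV, constant CO with HR/SV traded off,
and varying both.  Each scenario row is solved, imaged slice by slice, swept
over thresholds, and summarized (median/mean ASL, COV, gradient, optimal
threshold, histogram).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .asl import InversionProfile, MRParams, SlicePlane, simulate_slice
from .geometry import VascularNetwork
from .hemodynamics import (
    BloodProperties,
    BoundaryConditions,
    DistensionParams,
    GravityState,
    SheetParams,
    solve_flow,
)
from .thresholding import cov, gravitational_gradient, threshold_sweep

log = logging.getLogger(__name__)

#: scenario label -> rows of (SV L/beat, HR BPM, CO L/min)
SCENARIO_TABLE: dict[str, list[tuple[float, float, float]]] = {
    "varying_SV": [(0.066, 60, 4), (0.083, 60, 5), (0.100, 60, 6), (0.133, 60, 8)],
    "varying_HR": [(0.083, 48, 4), (0.083, 60, 5), (0.083, 72, 6), (0.083, 96, 8)],
    "constant_CO": [(0.104, 48, 5), (0.083, 60, 5), (0.069, 72, 5), (0.052, 96, 5)],
    "varying_HR_and_SV": [(0.050, 80, 4), (0.058, 86, 5), (0.067, 90, 6), (0.083, 96, 8)],
}


def ti_from_hr(hr_bpm: float) -> int:
    """Inversion time in ms: 80% of the R-R interval, rounded to 1 ms."""
    if hr_bpm <= 0:
        raise ValueError("heart rate must be positive")
    return int(round(0.8 * 60000.0 / hr_bpm))


def sv_from_co_hr(co_l_min: float, hr_bpm: float) -> float:
    """Stroke volume SV = CO / HR in L/beat, rounded to three decimals for
    reporting (matching the scenario table's printed precision)."""
    if co_l_min <= 0 or hr_bpm <= 0:
        raise ValueError("CO and HR must be positive")
    return round(co_l_min / hr_bpm, 3)


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario: label, (SV, HR, CO) rows, posture, slices, seed."""

    label: str
    rows: tuple[tuple[float, float, float], ...]
    posture: str = "supine"
    slice_indices: tuple[int, ...] = (1, 2, 3, 4, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        for sv, hr, co in self.rows:
            if abs(sv * hr - co) > 0.05 * co + 1e-9:
                raise ValueError(
                    f"{self.label}: SV {sv} x HR {hr} != CO {co} beyond rounding"
                )

    def ti_ms(self, row: int) -> int:
        return ti_from_hr(self.rows[row][1])


def default_scenarios(posture: str = "supine",
                      slice_indices: tuple[int, ...] = (1, 2, 3, 4, 5),
                      seed: int = 0) -> list[ScenarioSpec]:
    return [
        ScenarioSpec(label=label, rows=tuple(rows), posture=posture,
                     slice_indices=slice_indices, seed=seed)
        for label, rows in SCENARIO_TABLE.items()
    ]


@dataclass(frozen=True)
class HistogramSpec:
    """ASL-rate histogram: fixed bin width, range taken from the data."""

    bin_width: float = 1.0  # mL/min/cm^3

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")

    def compute(self, rates: np.ndarray) -> pd.DataFrame:
        if rates.size == 0:
            return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
        lo = np.floor(rates.min() / self.bin_width) * self.bin_width
        hi = np.ceil(rates.max() / self.bin_width) * self.bin_width
        if hi <= lo:
            hi = lo + self.bin_width
        edges = np.arange(lo, hi + 0.5 * self.bin_width, self.bin_width)
        counts, _ = np.histogram(rates, bins=edges)
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )


@dataclass
class RunReport:
    """Per (scenario row x slice) result records plus provenance."""

    records: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {"provenance": self.provenance, "records": self.records}
        path.write_text(json.dumps(payload, indent=2, default=str))
        return path


@dataclass(frozen=True)
class StudyConfig:
    """Everything run_scenario needs beyond the scenario itself."""

    blood: BloodProperties = BloodProperties()
    dist: DistensionParams = DistensionParams()
    sheet: SheetParams = SheetParams()
    mr: MRParams = MRParams()
    profile: InversionProfile = InversionProfile()
    hist: HistogramSpec = HistogramSpec()
    left_atrial_pressure_mmhg: float = 5.0
    quantum_mm: float = 1.0
    n_bins: int = 10


def _config_hash(spec: ScenarioSpec, config: StudyConfig) -> str:
    blob = json.dumps([asdict(spec), repr(config)], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_scenario(
    network: VascularNetwork,
    spec: ScenarioSpec,
    config: StudyConfig = StudyConfig(),
    out_dir: str | Path | None = None,
    solve_cache: dict | None = None,
) -> RunReport:
    """Execute one scenario: solve each row's CO, image each slice at the
    row's TI, sweep thresholds, and summarize.

    A failed stage marks that row's record as failed and the remaining rows
    still run.  ``solve_cache`` (keyed by (CO, posture)) lets callers share
    flow solutions across scenarios that revisit the same cardiac output.
    """
    from . import __version__

    gravity = GravityState.for_posture(spec.posture)
    up_sign = 1 if spec.posture == "supine" else -1
    domain = network.domain
    if domain is None:
        raise ValueError("network carries no domain; cannot place slices")
    slices = {
        s.index: s for s in SlicePlane.default_slices(domain)
    }
    report = RunReport(
        provenance={
            "scenario": spec.label,
            "posture": spec.posture,
            "seed": spec.seed,
            "config_hash": _config_hash(spec, config),
            "version": __version__,
        }
    )
    cache = solve_cache if solve_cache is not None else {}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for row_idx, (sv, hr, co) in enumerate(spec.rows):
        ti = ti_from_hr(hr)
        mr = MRParams(
            b0_t=config.mr.b0_t, t1_ms=config.mr.t1_ms, t2_ms=config.mr.t2_ms,
            te_ms=config.mr.te_ms, ti_ms=float(ti), m0b=config.mr.m0b,
        )
        key = (round(co, 6), spec.posture)
        try:
            if key not in cache:
                bc = BoundaryConditions(
                    cardiac_output_l_min=co,
                    left_atrial_pressure_mmhg=config.left_atrial_pressure_mmhg,
                )
                cache[key] = solve_flow(
                    network, bc, config.blood, gravity, config.dist, config.sheet
                )
            solution = cache[key]
        except Exception as exc:  # solver failure: mark every slice row failed
            log.error("row %d (CO=%.1f) solve failed: %s", row_idx, co, exc)
            for s_idx in spec.slice_indices:
                report.records.append(
                    {"scenario": spec.label, "row": row_idx, "sv": sv, "hr": hr,
                     "co": co, "ti_ms": ti, "slice": s_idx,
                     "posture": spec.posture, "failed": True,
                     "failure_stage": "solve", "error": str(exc)}
                )
            continue

        for s_idx in spec.slice_indices:
            rec = {
                "scenario": spec.label, "row": row_idx, "sv": sv, "hr": hr,
                "co": co, "ti_ms": ti, "slice": s_idx, "posture": spec.posture,
                "failed": False,
            }
            try:
                grid = simulate_slice(
                    network, solution, slices[s_idx], mr, config.profile,
                    domain, config.quantum_mm,
                )
                sweep = threshold_sweep(grid, up_sign=up_sign,
                                        n_bins=config.n_bins)
                rates = grid.rate()[grid.mask]
                rec.update(
                    total_signal=float(grid.total[grid.mask].sum()),
                    median_asl=float(np.median(rates)),
                    mean_asl=float(np.mean(rates)),
                    cov=cov(grid),
                    gradient=gravitational_gradient(grid, up_sign,
                                                    n_bins=config.n_bins),
                    optimal_x=sweep.optimal_x,
                )
                if out_dir is not None:
                    tag = f"{spec.label}_row{row_idx}_slice{s_idx}_{spec.posture}"
                    sweep_path = out_dir / f"sweep_{tag}.csv"
                    sweep.table.to_csv(sweep_path, index=False)
                    hist_path = out_dir / f"hist_{tag}.csv"
                    config.hist.compute(rates).to_csv(hist_path, index=False)
                    rec["sweep_table"] = str(sweep_path)
                    rec["histogram_table"] = str(hist_path)
            except Exception as exc:
                log.error("row %d slice %d failed: %s", row_idx, s_idx, exc)
                rec.update(failed=True, failure_stage="image", error=str(exc))
            report.records.append(rec)
    return report


def posture_comparison(report_supine: RunReport, report_prone: RunReport) -> dict:
    """Paired per-slice comparison of COV and gradient between postures.

    Pairs matched on (scenario, row, slice); differences are supine minus
    prone.  A paired two-sided t-test is used (the test choice is a package
    design decision); with fewer than 2 pairs, or zero variance of the
    differences, the test is skipped and only the mean difference reported.
    """
    def keyed(report: RunReport) -> dict:
        return {
            (r["scenario"], r["row"], r["slice"]): r
            for r in report.records
            if not r.get("failed")
        }

    sup, pro = keyed(report_supine), keyed(report_prone)
    keys = sorted(set(sup) & set(pro))
    out: dict = {"n_pairs": len(keys)}
    for metric in ("cov", "gradient"):
        a = np.array([sup[k][metric] for k in keys])
        b = np.array([pro[k][metric] for k in keys])
        diff = a - b
        entry = {
            "mean_difference": float(diff.mean()) if len(keys) else float("nan"),
            "direction": "supine>prone" if len(keys) and diff.mean() > 0
            else ("prone>supine" if len(keys) and diff.mean() < 0 else "no difference"),
        }
        if len(keys) < 2:
            entry["p_value"] = None
            entry["note"] = "fewer than 2 paired slices; test skipped"
            log.warning("posture comparison: %s", entry["note"])
        elif np.allclose(diff, diff[0]) and np.ptp(diff) == 0 and diff[0] == 0:
            entry["p_value"] = None
            entry["note"] = "no difference"
        else:
            t, p = stats.ttest_rel(a, b)
            entry["t_statistic"] = float(t)
            entry["p_value"] = float(p)
        out[metric] = entry
    return out
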