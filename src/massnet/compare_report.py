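"""Scenario-vs-control direction classification and group statistics.

Each perturbation scenario is compared with the control batch on three
composite outcomes:

* ``neuronal_activity`` — direction of the whole-brain mean pyramidal spike
  density (higher / lower / unchanged);
* ``total_power`` — direction of the absolute broadband (0.5-48 Hz) power;
* ``oscillatory_behavior`` — slower / faster / unchanged / mixed, a composite
  over relative theta power, peak frequency, and the fast (alpha2+beta)
  relative power that captures global oscillatory slowing even when some
  faster-band power rises.

"Unchanged" tolerances default to twice the pooled across-iteration standard
error of each measure, so labels reflect batch dispersion rather than a fixed
magnitude; Monte-Carlo model output is deliberately not significance-tested.
The reference direction table used for concordance scoring is embedded below;
the contrast-1A oscillatory label is accepted either way because the source
reports it inconsistently (text: slower peak; table: faster).

Group-level statistics on per-subject values (the human-data arm) use Welch's
unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .network_sim import SCENARIO_ORDER
from .spectral import SpectralSummary

__all__ = [
    "TABLE_REFERENCE_DIRECTIONS",
    "OSCILLATORY_AMBIGUOUS",
    "DirectionSummary",
    "DirectionTolerances",
    "classify_direction",
    "summarize_all_scenarios",
    "concordance",
    "welch_ttest",
    "report_grid",
]

#: reference direction labels for the twelve perturbation scenarios
#: (rows: neuronal activity, oscillatory behavior, total power)
TABLE_REFERENCE_DIRECTIONS: dict[str, dict[str, str]] = {
    "1A_ad": {"neuronal_activity": "higher", "oscillatory_behavior": "slower", "total_power": "higher"},
    "1B_ad": {"neuronal_activity": "lower", "oscillatory_behavior": "slower", "total_power": "higher"},
    "1C_ad": {"neuronal_activity": "higher", "oscillatory_behavior": "slower", "total_power": "higher"},
    "2A_ad": {"neuronal_activity": "higher", "oscillatory_behavior": "slower", "total_power": "higher"},
    "2B_ad": {"neuronal_activity": "higher", "oscillatory_behavior": "faster", "total_power": "higher"},
    "2C_ad": {"neuronal_activity": "higher", "oscillatory_behavior": "slower", "total_power": "higher"},
    "1A_contrast": {"neuronal_activity": "lower", "oscillatory_behavior": "faster", "total_power": "lower"},
    "1B_contrast": {"neuronal_activity": "higher", "oscillatory_behavior": "faster", "total_power": "lower"},
    "1C_contrast": {"neuronal_activity": "lower", "oscillatory_behavior": "faster", "total_power": "lower"},
    "2A_contrast": {"neuronal_activity": "lower", "oscillatory_behavior": "faster", "total_power": "lower"},
    "2B_contrast": {"neuronal_activity": "lower", "oscillatory_behavior": "slower", "total_power": "lower"},
    "2C_contrast": {"neuronal_activity": "lower", "oscillatory_behavior": "faster", "total_power": "lower"},
}

#: scenarios whose oscillatory label is reported inconsistently at the source
#: and therefore scored as concordant either way
OSCILLATORY_AMBIGUOUS = frozenset({"1A_contrast"})


@dataclass(frozen=True)
class DirectionTolerances:
    """Explicit unchanged-band half-widths per measure; None = 2x pooled SE."""

    theta: float | None = None
    peak_frequency: float | None = None
    fast_power: float | None = None
    spike_density: float | None = None
    total_power: float | None = None
    se_multiplier: float = 2.0


@dataclass(frozen=True)
class DirectionSummary:
    """Directional comparison of one scenario batch against control."""

    scenario: str
    neuronal_activity: str
    oscillatory_behavior: str
    total_power: str
    deltas: dict[str, float]
    tolerances: dict[str, float]
    n_iterations: tuple[int, int]


def _pooled_se(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size))


def _column(summary: SpectralSummary, name: str) -> np.ndarray:
    if name not in summary.per_iteration:
        raise ValueError(f"batch summary lacks measure {name!r}")
    return summary.per_iteration[name].to_numpy(dtype=float)


def _sign_label(delta: float, tol: float, pos: str, neg: str) -> str:
    if delta > tol:
        return pos
    if delta < -tol:
        return neg
    return "unchanged"


def classify_direction(
    scenario_summary: SpectralSummary,
    control_summary: SpectralSummary,
    scenario_name: str = "scenario",
    tolerances: DirectionTolerances | None = None,
) -> DirectionSummary:
    """Label a scenario batch against the control batch.

    Both batches need >= 2 iterations unless every tolerance is given
    explicitly.  The oscillatory rule, in order: theta up with peak not up
    -> slower; theta up with peak up -> mixed; theta down -> faster; theta
    unchanged -> faster if fast (alpha2+beta) power rose, slower if the peak
    dropped, else unchanged.
    """
    tol_spec = tolerances or DirectionTolerances()
    explicit = all(
        getattr(tol_spec, f) is not None
        for f in ("theta", "peak_frequency", "fast_power", "spike_density", "total_power")
    )
    if not explicit and (scenario_summary.n_iterations < 2 or control_summary.n_iterations < 2):
        raise ValueError("need >= 2 iterations per batch for SE-based tolerances")

    def measure_pair(name: str) -> tuple[np.ndarray, np.ndarray]:
        return _column(scenario_summary, name), _column(control_summary, name)

    theta_s, theta_c = measure_pair("theta")
    fast_s = _column(scenario_summary, "alpha2") + _column(scenario_summary, "beta")
    fast_c = _column(control_summary, "alpha2") + _column(control_summary, "beta")
    peak_s, peak_c = measure_pair("peak_frequency")
    tp_s, tp_c = measure_pair("total_power")
    has_density = "mean_spike_density" in scenario_summary.per_iteration
    if has_density:
        sd_s, sd_c = measure_pair("mean_spike_density")

    def tol(name: str, a: np.ndarray, b: np.ndarray) -> float:
        explicit_value = getattr(tol_spec, name)
        if explicit_value is not None:
            return float(explicit_value)
        return tol_spec.se_multiplier * _pooled_se(a, b)

    tol_theta = tol("theta", theta_s, theta_c)
    tol_peak = tol("peak_frequency", peak_s, peak_c)
    tol_fast = tol("fast_power", fast_s, fast_c)
    tol_tp = tol("total_power", tp_s, tp_c)
    d_theta = float(theta_s.mean() - theta_c.mean())
    d_peak = float(peak_s.mean() - peak_c.mean())
    d_fast = float(fast_s.mean() - fast_c.mean())
    d_tp = float(tp_s.mean() - tp_c.mean())

    if d_theta > tol_theta:
        oscillatory = "mixed" if d_peak > tol_peak else "slower"
    elif d_theta < -tol_theta:
        oscillatory = "faster"
    elif d_fast > tol_fast:
        oscillatory = "faster"
    elif d_peak < -tol_peak:
        oscillatory = "slower"
    else:
        oscillatory = "unchanged"

    deltas = {"theta": d_theta, "peak_frequency": d_peak, "fast_power": d_fast,
              "total_power": d_tp}
    tols = {"theta": tol_theta, "peak_frequency": tol_peak, "fast_power": tol_fast,
            "total_power": tol_tp}
    if has_density:
        tol_sd = tol("spike_density", sd_s, sd_c)
        d_sd = float(sd_s.mean() - sd_c.mean())
        activity = _sign_label(d_sd, tol_sd, "higher", "lower")
        deltas["spike_density"] = d_sd
        tols["spike_density"] = tol_sd
    else:
        activity = "unchanged"
    return DirectionSummary(
        scenario=scenario_name,
        neuronal_activity=activity,
        oscillatory_behavior=oscillatory,
        total_power=_sign_label(d_tp, tol_tp, "higher", "lower"),
        deltas=deltas,
        tolerances=tols,
        n_iterations=(scenario_summary.n_iterations, control_summary.n_iterations),
    )


def summarize_all_scenarios(
    batches: Mapping[str, SpectralSummary],
    tolerances: DirectionTolerances | None = None,
) -> list[DirectionSummary]:
    """Classify every non-control scenario batch against the control batch.

    ``batches`` maps scenario names (including "control") to batch summaries.
    Scenarios beyond the control are reported in canonical order first, then
    any extras; a mapping holding only the control yields an empty list.
    """
    if "control" not in batches:
        raise ValueError("batches must include a 'control' entry")
    control = batches["control"]
    names = [n for n in SCENARIO_ORDER if n in batches]
    names += [n for n in batches if n not in names and n != "control"]
    return [
        classify_direction(batches[name], control, name, tolerances) for name in names
    ]


def concordance(rows: Sequence[DirectionSummary]) -> dict:
    """Score direction labels against the embedded reference table.

    Returns per-outcome matched counts over the scenarios present, with the
    ambiguous contrast-1A oscillatory label always counted as a match.
    """
    out: dict[str, dict] = {}
    for outcome in ("neuronal_activity", "oscillatory_behavior", "total_power"):
        matches, mismatches = 0, []
        total = 0
        for row in rows:
            expected = TABLE_REFERENCE_DIRECTIONS.get(row.scenario)
            if expected is None:
                continue
            total += 1
            got = getattr(row, "total_power" if outcome == "total_power" else outcome)
            if outcome == "oscillatory_behavior" and row.scenario in OSCILLATORY_AMBIGUOUS:
                matches += 1
                continue
            if got == expected[outcome]:
                matches += 1
            else:
                mismatches.append(f"{row.scenario}: {got} != {expected[outcome]}")
        out[outcome] = {"matched": matches, "of": total, "mismatches": mismatches}
    return out


class WelchResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float


def welch_ttest(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Two-sided independent-samples t-test not assuming equal variance.

    Returns (t, Welch-Satterthwaite df, p).  Two groups with zero variance
    and equal means return t=0, p=1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups contain non-finite values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0)
        return WelchResult(np.inf if a.mean() > b.mean() else -np.inf,
                           float(a.size + b.size - 2), 0.0)
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def report_grid(rows: Sequence[DirectionSummary]) -> str:
    """Plain-text direction grid, one scenario per column."""
    if not rows:
        return "(no scenarios)"
    names = [r.scenario for r in rows]
    width = max(len(n) for n in names) + 2
    lines = ["".ljust(22) + "".join(n.ljust(width) for n in names)]
    for attr, label in [
        ("neuronal_activity", "Neuronal activity"),
        ("oscillatory_behavior", "Oscillatory behavior"),
        ("total_power", "Total power"),
    ]:
        lines.append(
            label.ljust(22) + "".join(getattr(r, attr).ljust(width) for r in rows)
        )
    return "\n".join(lines)


def rows_to_frame(rows: Sequence[DirectionSummary]) -> pd.DataFrame:
    """Tabular form of a direction report (one row per scenario)."""
    records = []
    for r in rows:
        rec = {
            "scenario": r.scenario,
            "neuronal_activity": r.neuronal_activity,
            "oscillatory_behavior": r.oscillatory_behavior,
            "total_power": r.total_power,
        }
        rec.update({f"delta_{k}": v for k, v in r.deltas.items()})
        records.append(rec)
    return pd.DataFrame(records)
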