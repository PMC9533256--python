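"""Probe design sweeps and inverse design lookups.

The validated bioheat model is exercised over a grid of probe surface
temperatures (0-40 degC) and tip lengths (0.5x / 1x / 2x the standard
25 mm) at a fixed cooling time (default one hour).  Each cell stores the
VOTC summary; inverse lookups invert the monotone volume-vs-temperature
curve to find the surface temperature that achieves a target cooled volume,
and length-effect reports compare maxima across probe lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .exceptions import MonotonicityError, SolverError
from .properties import BloodProperties, TissueProperties
from .solver import PennesSolver, ProbeSpec, SimulationDomain, SolverOptions
from .votc import THRESHOLDS, VOTCSummary, votc_summary

STANDARD_LENGTHS = (12.5, 25.0, 50.0)   # mm: 0.5x, 1x, 2x tip lengths
TEMPERATURE_RANGE = (0.0, 40.0)         # degC, assessed surface temperatures


@dataclass
class SweepResult:
    """VOTC summaries over a (surface temperature, tip length) grid."""

    temperatures: np.ndarray
    lengths: np.ndarray
    cooling_time: float
    cells: dict[tuple[float, float], VOTCSummary] = dc_field(default_factory=dict)
    failures: list[tuple[float, float, str]] = dc_field(default_factory=list)

    def cell(self, temperature: float, length: float) -> VOTCSummary:
        return self.cells[(float(temperature), float(length))]

    def series(self, length: float, stratum: str = "mild",
               quantity: str = "volume") -> tuple[np.ndarray, np.ndarray]:
        """(temperatures, values) for one probe length, skipping failed cells."""
        temps, vals = [], []
        for t in self.temperatures:
            key = (float(t), float(length))
            if key not in self.cells:
                continue
            s = self.cells[key]
            v = (s.volumes_cm3[stratum] if quantity == "volume"
                 else s.areas_mm2[stratum])
            temps.append(float(t))
            vals.append(v)
        return np.asarray(temps), np.asarray(vals)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (t, length), s in sorted(self.cells.items()):
            for row in s.to_rows():
                rows.append({"surface_temperature_C": t, "tip_length_mm": length,
                             **row})
        return pd.DataFrame(rows)


def run_sweep(temperatures, lengths=STANDARD_LENGTHS, cooling_time: float = 3600.0,
              domain: SimulationDomain | None = None,
              tissue: TissueProperties | None = None,
              blood: BloodProperties | None = None,
              probe_template: ProbeSpec | None = None,
              options: SolverOptions | None = None,
              progress: bool = False) -> SweepResult:
    """One transient solve per (surface temperature, length) cell.

    Cells are independent pure functions of their parameters; a solver
    failure flags the cell and the sweep continues.
    """
    temperatures = np.atleast_1d(np.asarray(temperatures, dtype=float))
    lengths = np.atleast_1d(np.asarray(lengths, dtype=float))
    lo, hi = TEMPERATURE_RANGE
    if np.any((temperatures < lo) | (temperatures > hi)):
        warnings.warn(f"surface temperatures outside the assessed range "
                      f"[{lo}, {hi}] degC", stacklevel=2)
    template = probe_template or ProbeSpec()
    result = SweepResult(temperatures=temperatures, lengths=lengths,
                         cooling_time=cooling_time)
    for length in lengths:
        for ts in temperatures:
            probe = replace(template, surface_temperature=float(ts),
                            tip_length=float(length))
            try:
                solver = PennesSolver(domain, probe, tissue, blood, options)
                fld = solver.solve_transient([cooling_time])[0]
                result.cells[(float(ts), float(length))] = votc_summary(fld)
            except SolverError as exc:  # flag and continue
                result.failures.append((float(ts), float(length), str(exc)))
            if progress:
                print(f"  sweep cell Ts={ts:g} degC, L={length:g} mm done",
                      flush=True)
    return result


def required_surface_temperature(sweep: SweepResult, target_volume: float,
                                 stratum: str = "mild",
                                 length: float = 25.0) -> float | None:
    """Surface temperature achieving ``target_volume`` cm^3 of the given
    stratum, by monotone (PCHIP) inversion of the sweep curve.

    Returns None when the target is unreachable even at the coldest simulated
    temperature.  Raises MonotonicityError if the sweep data are not
    non-increasing in temperature (which indicates a solver problem).
    """
    temps, vols = sweep.series(length, stratum, "volume")
    if temps.size < 4:
        raise ValueError("need at least 4 temperature points for inversion")
    if np.any(np.diff(vols) > 1e-6 * max(1.0, vols.max())):
        raise MonotonicityError("cooled volume increases with surface "
                                "temperature; check the sweep solves")
    if target_volume > vols[0]:
        return None  # infeasible even at the coldest temperature
    if target_volume < vols[-1]:
        return float(temps[-1])
    # restrict to the strictly decreasing part (trailing zeros break PCHIP)
    keep = np.concatenate([[True], np.diff(vols) < 0])
    interp = PchipInterpolator(temps[keep], vols[keep])
    return float(brentq(lambda t: interp(t) - target_volume,
                        temps[keep][0], temps[keep][-1], xtol=1e-4))


def length_effect_report(sweep: SweepResult,
                         reference_length: float = 25.0) -> pd.DataFrame:
    """Percent change of maximum cooled area/volume vs the reference length.

    The maximum over the swept temperature grid occurs at the coldest
    temperature.  Returns a DataFrame with one row per (stratum, length):
    max_area_mm2, max_volume_cm3 and their percent change relative to the
    reference length.
    """
    lengths = [float(x) for x in sweep.lengths]
    if reference_length not in lengths:
        raise ValueError(f"reference length {reference_length} not in sweep")
    rows = []
    for stratum in THRESHOLDS:
        maxima = {}
        for length in lengths:
            ta, areas = sweep.series(length, stratum, "area")
            tv, vols = sweep.series(length, stratum, "volume")
            if areas.size == 0:
                raise ValueError(f"no successful cells for length {length}")
            maxima[length] = (areas.max(), vols.max())
        ref_a, ref_v = maxima[reference_length]
        for length in lengths:
            a, v = maxima[length]
            rows.append({
                "stratum": stratum, "tip_length_mm": length,
                "max_area_mm2": a, "max_volume_cm3": v,
                "area_change_pct": 100.0 * (a - ref_a) / ref_a if ref_a else 0.0,
                "volume_change_pct": 100.0 * (v - ref_v) / ref_v if ref_v else 0.0,
            })
    return pd.DataFrame(rows)
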