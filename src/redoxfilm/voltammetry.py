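"""Simulation and analysis of cyclic voltammetry (CV) and chronoamperometry
(CA) on enzyme-loaded redox films.

CVs are generated by driving the transient film solver with a triangular
electrode-potential program; CAs with a piecewise-constant one.  The
analysis functions (mediator E0 extraction, normalization by the maximal
positive current, plateau detection, zero-crossing location) operate on any
:class:`Trace`, simulated or synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .potentials import PotentialValue
from .film_model import (
    BoundaryConditions,
    FilmParameters,
    SpeciesProfile,
    solve_steady_state,
    solve_transient,
)

__all__ = [
    "Trace",
    "PlateauResult",
    "simulate_cv",
    "simulate_ca",
    "extract_mediator_e0",
    "normalize_by_max_positive",
    "plateau_current",
    "zero_crossing_potential",
    "split_sweeps",
    "write_trace",
    "read_trace",
]


@dataclass
class Trace:
    """A time/potential/current series with metadata.

    ``kind`` is "CV" or "CA"; potentials are in V vs SHE; the current is in
    A m^-2 unless ``normalized`` is set.
    """

    time: np.ndarray
    potential: np.ndarray
    current: np.ndarray
    kind: str = "CV"
    pH: float | None = None
    temperature: float | None = None
    scan_rate: float | None = None
    gas_feed: str = ""
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.potential = np.asarray(self.potential, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if not (self.time.size == self.potential.size == self.current.size):
            raise ValueError("time, potential and current must have equal length")
        if self.time.size < 2:
            raise ValueError("a trace needs at least two samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.kind not in ("CV", "CA"):
            raise ValueError("kind must be 'CV' or 'CA'")


def _triangle_program(e_start: float, e_vertex: float, scan_rate: float,
                      cycles: int):
    """Piecewise-linear E(t) for ``cycles`` triangular sweeps."""
    half = abs(e_vertex - e_start) / scan_rate
    sign = 1.0 if e_vertex > e_start else -1.0
    period = 2.0 * half

    def program(t: float) -> float:
        tau = t % period
        if tau <= half:
            return e_start + sign * scan_rate * tau
        return e_vertex - sign * scan_rate * (tau - half)

    return program, half, period


def simulate_cv(
    params: FilmParameters,
    e_start: float,
    e_vertex: float,
    scan_rate: float,
    cycles: int = 1,
    bc: BoundaryConditions | None = None,
    n_nodes: int = 80,
    samples_per_sweep: int = 240,
    initial: SpeciesProfile | None = None,
    rtol: float = 1.0e-6,
    atol: float = 1.0e-9,
) -> Trace:
    """Cyclic voltammogram of the film between ``e_start`` and ``e_vertex``.

    Potentials in V vs SHE, scan rate in V/s.  The film starts from the
    anaerobic steady state at ``e_start`` unless ``initial`` is given.
    Each linear sweep is integrated as its own segment so the vertices are
    honored exactly.
    """
    if scan_rate <= 0:
        raise ValueError("scan_rate must be positive")
    if e_vertex == e_start:
        raise ValueError("e_vertex must differ from e_start")
    if bc is None:
        bc = BoundaryConditions(
            PotentialValue(e_start, "SHE"), bulk_h2=0.78, bulk_o2=0.0
        )
    program, half, period = _triangle_program(e_start, e_vertex, scan_rate, cycles)

    if initial is None:
        bc0 = replace(bc, electrode_potential=PotentialValue(e_start, "SHE"))
        initial, _ = solve_steady_state(params, bc0, n_nodes=n_nodes)

    times: list[np.ndarray] = []
    pots: list[np.ndarray] = []
    curs: list[np.ndarray] = []
    state = initial
    for seg in range(2 * cycles):
        t0 = seg * half
        local = np.linspace(0.0, half, samples_per_sweep + 1)
        seg_program = lambda t, t0=t0: program(t0 + t)
        res = solve_transient(
            params,
            bc,
            t_end=half,
            snapshots=local,
            initial=state,
            potential_program=seg_program,
            n_nodes=n_nodes,
            rtol=rtol,
            atol=atol,
        )
        state = res.profiles[-1]
        sl = slice(0, None) if seg == 0 else slice(1, None)
        times.append(res.times[sl] + t0)
        pots.append(res.potential[sl])
        curs.append(res.current[sl])
    return Trace(
        time=np.concatenate(times),
        potential=np.concatenate(pots),
        current=np.concatenate(curs),
        kind="CV",
        pH=params.pH,
        temperature=params.temperature,
        scan_rate=scan_rate,
        gas_feed=f"H2 {bc.bulk_h2} mol/m3, O2 {bc.bulk_o2} mol/m3",
    )


def simulate_ca(
    params: FilmParameters,
    steps: Sequence[tuple[float, float]],
    bc: BoundaryConditions | None = None,
    n_nodes: int = 80,
    samples_per_step: int = 120,
    initial: SpeciesProfile | None = None,
    rtol: float = 1.0e-6,
    atol: float = 1.0e-9,
) -> Trace:
    """Chronoamperometry: ``steps`` is a list of (E vs SHE, duration s).

    The film starts from the anaerobic steady state at the first step
    potential unless ``initial`` is given.
    """
    if not steps:
        raise ValueError("at least one potential step is required")
    for _, dur in steps:
        if dur <= 0:
            raise ValueError("step durations must be positive")
    if bc is None:
        bc = BoundaryConditions(
            PotentialValue(steps[0][0], "SHE"), bulk_h2=0.78, bulk_o2=0.0
        )
    if initial is None:
        bc0 = replace(bc, electrode_potential=PotentialValue(steps[0][0], "SHE"))
        initial, _ = solve_steady_state(params, bc0, n_nodes=n_nodes)

    times: list[np.ndarray] = []
    pots: list[np.ndarray] = []
    curs: list[np.ndarray] = []
    state = initial
    t_offset = 0.0
    for k, (e_step, dur) in enumerate(steps):
        local = np.linspace(0.0, dur, samples_per_step + 1)
        res = solve_transient(
            params,
            bc,
            t_end=dur,
            snapshots=local,
            initial=state,
            potential_program=lambda t, e=e_step: e,
            n_nodes=n_nodes,
            rtol=rtol,
            atol=atol,
        )
        state = res.profiles[-1]
        sl = slice(0, None) if k == 0 else slice(1, None)
        # shift the first sample slightly so time stays strictly increasing
        tt = res.times[sl] + t_offset
        if k > 0:
            tt = tt.copy()
        times.append(tt)
        pots.append(res.potential[sl])
        curs.append(res.current[sl])
        t_offset += dur
    return Trace(
        time=np.concatenate(times),
        potential=np.concatenate(pots),
        current=np.concatenate(curs),
        kind="CA",
        pH=params.pH,
        temperature=params.temperature,
        gas_feed=f"H2 {bc.bulk_h2} mol/m3, O2 {bc.bulk_o2} mol/m3",
    )


# ---------------------------------------------------------------------------
# Trace analysis
# ---------------------------------------------------------------------------


def split_sweeps(trace: Trace) -> list[np.ndarray]:
    """Index arrays of the monotone potential sweeps of a CV."""
    dE = np.sign(np.diff(trace.potential))
    # treat zeros (plateaus at the vertex sample) as the previous direction
    for i in range(1, dE.size):
        if dE[i] == 0:
            dE[i] = dE[i - 1]
    breaks = np.nonzero(np.diff(dE))[0] + 1
    pieces = np.split(np.arange(trace.potential.size), breaks + 1)
    return [p for p in pieces if p.size >= 2]


def extract_mediator_e0(
    trace: Trace, smooth_window: int = 11, smooth_order: int = 2
) -> float:
    """Mediator midpoint potential (E_pa + E_pc)/2 from a non-catalytic CV.

    Currents are smoothed (Savitzky-Golay) before peak picking; each sweep
    direction must contain an interior extremum, otherwise an extraction
    error is raised.  Ties are broken toward the extremum nearest the sweep
    midpoint.  The estimate is invariant to positive rescaling of the
    current.
    """
    sweeps = split_sweeps(trace)
    if len(sweeps) < 2:
        raise ValueError("need at least one anodic and one cathodic sweep")
    current = trace.current
    if current.size > smooth_window and smooth_window > smooth_order + 1:
        current = savgol_filter(current, smooth_window, smooth_order)

    def interior_extremum(idx: np.ndarray, anodic: bool) -> float | None:
        seg = current[idx]
        k = int(np.argmax(seg)) if anodic else int(np.argmin(seg))
        if k == 0 or k == seg.size - 1:
            return None
        # tie-break toward the sweep midpoint
        best = seg[k]
        ties = np.nonzero(seg == best)[0]
        if ties.size > 1:
            mid = seg.size / 2.0
            k = int(ties[np.argmin(np.abs(ties - mid))])
            if k == 0 or k == seg.size - 1:
                return None
        return float(trace.potential[idx[k]])

    e_pa = e_pc = None
    for idx in sweeps:
        anodic = trace.potential[idx[-1]] > trace.potential[idx[0]]
        found = interior_extremum(idx, anodic)
        if found is None:
            continue
        if anodic and e_pa is None:
            e_pa = found
        elif not anodic and e_pc is None:
            e_pc = found
    if e_pa is None or e_pc is None:
        raise ValueError("could not locate one peak per sweep direction")
    return 0.5 * (e_pa + e_pc)


def normalize_by_max_positive(trace: Trace) -> Trace:
    """Divide all currents by the maximal positive current (idempotent)."""
    top = float(np.max(trace.current))
    if top <= 0:
        raise ValueError("trace has no positive current to normalize by")
    return Trace(
        time=trace.time.copy(),
        potential=trace.potential.copy(),
        current=trace.current / top,
        kind=trace.kind,
        pH=trace.pH,
        temperature=trace.temperature,
        scan_rate=trace.scan_rate,
        gas_feed=trace.gas_feed,
        normalized=True,
        meta=dict(trace.meta),
    )


@dataclass(frozen=True)
class PlateauResult:
    """Median forward-sweep current over a window and its relative spread."""

    current: float
    spread: float
    is_plateau: bool


def plateau_current(
    trace: Trace,
    window: tuple[float, float],
    spread_threshold: float = 0.05,
) -> PlateauResult:
    """Median forward-scan current over a potential window (V vs SHE).

    The forward scan is the first monotone sweep; the relative spread is
    (max - min)/|median| over the window, and a plateau is asserted when
    the spread is below ``spread_threshold``.
    """
    lo, hi = sorted(window)
    if trace.kind == "CV":
        idx = split_sweeps(trace)[0]
    else:
        idx = np.arange(trace.potential.size)
    e = trace.potential[idx]
    i = trace.current[idx]
    sel = (e >= lo) & (e <= hi)
    if not np.any(sel):
        raise ValueError("window does not overlap the scanned potential range")
    vals = i[sel]
    med = float(np.median(vals))
    if med == 0:
        spread = np.inf
    else:
        spread = float((np.max(vals) - np.min(vals)) / abs(med))
    return PlateauResult(current=med, spread=spread, is_plateau=spread < spread_threshold)


def zero_crossing_potential(trace: Trace) -> float:
    """Potential of zero catalytic current of an anaerobic catalytic CV.

    Linear interpolation of the sign change on the forward and on the
    return sweep; the two are averaged, which cancels the (antisymmetric)
    pseudocapacitive charging contribution to first order.
    """
    crossings = []
    for idx in split_sweeps(trace)[:2]:
        i = trace.current[idx]
        e = trace.potential[idx]
        s = np.sign(i)
        flips = np.nonzero(np.diff(s) != 0)[0]
        if flips.size == 0:
            continue
        k = flips[0]
        if i[k + 1] == i[k]:
            crossings.append(float(e[k]))
        else:
            frac = -i[k] / (i[k + 1] - i[k])
            crossings.append(float(e[k] + frac * (e[k + 1] - e[k])))
    if not crossings:
        raise ValueError("no zero crossing found")
    return float(np.mean(crossings))


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------


def write_trace(trace: Trace, path) -> None:
    """Write a trace as CSV with '#'-prefixed metadata header lines."""
    import pandas as pd

    meta = {
        "kind": trace.kind,
        "pH": trace.pH,
        "temperature_K": trace.temperature,
        "scan_rate_V_s": trace.scan_rate,
        "gas_feed": trace.gas_feed,
        "normalized": trace.normalized,
    }
    meta.update(trace.meta)
    unit = "normalized" if trace.normalized else "A_m2"
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "potential_V_SHE": trace.potential,
            f"current_{unit}": trace.current,
        }
    )
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def read_trace(path) -> Trace:
    """Read a trace CSV written by :func:`write_trace`."""
    import pandas as pd

    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    cur_col = [c for c in df.columns if c.startswith("current")][0]

    def _opt_float(key):
        val = meta.get(key, "None")
        return None if val in ("None", "") else float(val)

    return Trace(
        time=df["time_s"].to_numpy(),
        potential=df["potential_V_SHE"].to_numpy(),
        current=df[cur_col].to_numpy(),
        kind=meta.get("kind", "CV"),
        pH=_opt_float("pH"),
        temperature=_opt_float("temperature_K"),
        scan_rate=_opt_float("scan_rate_V_s"),
        gas_feed=meta.get("gas_feed", ""),
        normalized=meta.get("normalized", "False") == "True",
    )
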