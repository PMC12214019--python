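"""Synthetic two-channel intensity traces from latent CTMC state paths.

Converts a :class:`~strandex.kinetics.StatePath` into camera frames with
the optical artifacts the analysis has to cope with: donor leakage into
the acceptor channel, shot and read noise, per-dye photobleaching, the
background step when labeled competitor flows in, alternating-laser
excitation blocks, and time-weighted averaging of states that change
mid-frame (camera integration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kinetics import ExperimentCondition, KineticScheme, StatePath, gillespie_simulate, molecule_rng
from .optics import GREEN, RED, ExcitationPattern, OpticsModel

__all__ = [
    "MoleculeTrace",
    "synthesize_trace",
    "synthesize_ensemble",
    "simulate_molecule_path",
]


@dataclass
class MoleculeTrace:
    """Per-frame donor/acceptor counts for one molecule.

    ``time_s`` holds frame start times; ``excitation`` the per-frame laser
    label (G/R/dark).  ``truth`` optionally keeps the latent state path
    the trace was generated from (never used by the analysis).
    """

    time_s: np.ndarray
    excitation: np.ndarray
    I_D: np.ndarray
    I_A: np.ndarray
    frame_time: float
    molecule_id: int = 0
    truth: StatePath | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if not (len(self.excitation) == len(self.I_D) == len(self.I_A) == n):
            raise ValueError("trace arrays must have equal length")
        if (np.asarray(self.I_D) < 0).any() or (np.asarray(self.I_A) < 0).any():
            raise ValueError("counts must be >= 0 after clipping")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    def green_mask(self) -> np.ndarray:
        return np.asarray(self.excitation) == GREEN

    def red_mask(self) -> np.ndarray:
        return np.asarray(self.excitation) == RED


def _piecewise_frame_means(
    breaks: np.ndarray, values: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Mean of a piecewise-constant function over each [edge_i, edge_i+1).

    ``values[i]`` applies on [breaks[i], breaks[i+1]); the cumulative
    integral is piecewise linear so linear interpolation at the edges is
    exact.
    """
    cum = np.concatenate([[0.0], np.cumsum(values * np.diff(breaks))])
    at_edges = np.interp(edges, breaks, cum)
    return np.diff(at_edges) / np.diff(edges)


def synthesize_trace(
    path: StatePath,
    scheme: KineticScheme,
    optics: OpticsModel,
    pattern: ExcitationPattern,
    seed,
    *,
    t_start: float = 0.0,
    duration: float | None = None,
    flow_start: float | None = None,
    molecule_id: int = 0,
) -> MoleculeTrace:
    """Render the state path into camera frames on [t_start, t_start+duration).

    Per green-excited frame the expected donor signal is
    n_donors*total_intensity*(1-E) (integrated over state occupancy within
    the frame) plus background and, after ``flow_start``, the flow
    background step; the expected acceptor signal is
    n_donors*total_intensity*E plus ``leakage`` times the recorded donor
    channel.  Red frames report direct acceptor excitation (used for
    donor-only exclusion), dark frames background only.  A second donor
    during a labeled ternary intermediate doubles the sensitized acceptor
    signal (the pre-transfer Cy5 boost).  Photobleaching times are drawn
    per dye; a bleached donor removes one donor's contribution, a
    bleached acceptor leaves donors unquenched.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if duration is None:
        duration = path.horizon - t_start
    if duration <= 0:
        raise ValueError("requested duration is empty")
    if path.horizon < t_start + duration - 1e-9:
        raise ValueError("state path horizon does not cover the requested window")
    dt = pattern.frame_time
    n_frames = int(math.ceil(duration / dt - 1e-9))
    edges = t_start + dt * np.arange(n_frames + 1)
    frame_times = edges[:-1]
    labels = pattern.labels(n_frames)

    t_bleach_d = (
        rng.exponential(1.0 / optics.bleach_rate_donor)
        if optics.bleach_rate_donor > 0
        else np.inf
    )
    t_bleach_a = (
        rng.exponential(1.0 / optics.bleach_rate_acceptor)
        if optics.bleach_rate_acceptor > 0
        else np.inf
    )
    t_flow = flow_start if flow_start is not None else np.inf

    t_end = edges[-1]
    extra = [t for t in (t_bleach_d, t_bleach_a, t_flow) if 0.0 < t < t_end]
    breaks = np.unique(np.concatenate([path.times, extra, [t_end + dt]]))
    # per-segment emission rates (in units of total_intensity)
    fret = scheme.fret_by_index()
    donors = scheme.donors_by_index()
    acceptor = scheme.acceptor_by_index()
    seg_d = np.empty(breaks.size - 1)
    seg_a = np.empty(breaks.size - 1)
    seg_red = np.empty(breaks.size - 1)
    seg_flow = np.empty(breaks.size - 1)
    for i, b in enumerate(breaks[:-1]):
        s = path.state_at(b)
        n_d = donors[s] - (0 if b < t_bleach_d else 1)
        n_d = max(n_d, 0.0)
        acc_alive = acceptor[s] and b < t_bleach_a
        e = fret[s]
        if acc_alive:
            seg_d[i] = n_d * (1.0 - e)
            seg_a[i] = n_d * e
        else:
            seg_d[i] = n_d
            seg_a[i] = 0.0
        seg_red[i] = 1.0 if acc_alive else 0.0
        seg_flow[i] = 1.0 if b >= t_flow else 0.0

    d_mean = _piecewise_frame_means(breaks, seg_d, edges)
    a_mean = _piecewise_frame_means(breaks, seg_a, edges)
    red_mean = _piecewise_frame_means(breaks, seg_red, edges)
    flow_mean = _piecewise_frame_means(breaks, seg_flow, edges)

    total = optics.total_intensity
    exp_d = np.full(n_frames, optics.background_green)
    exp_a = np.full(n_frames, optics.background_red)
    green = labels == GREEN
    red = labels == RED
    exp_d[green] = (
        total * d_mean[green]
        + optics.background_green
        + optics.flow_background_step * flow_mean[green]
    )
    exp_a[green] = total * a_mean[green] + optics.leakage * exp_d[green] + optics.background_red
    exp_a[red] = total * red_mean[red] + optics.background_red

    if optics.shot_noise:
        i_d = rng.poisson(exp_d).astype(float)
        i_a = rng.poisson(exp_a).astype(float)
    else:
        i_d = exp_d.copy()
        i_a = exp_a.copy()
    if optics.read_noise_sd > 0:
        i_d = i_d + rng.normal(0.0, optics.read_noise_sd, n_frames)
        i_a = i_a + rng.normal(0.0, optics.read_noise_sd, n_frames)
    np.clip(i_d, 0.0, None, out=i_d)
    np.clip(i_a, 0.0, None, out=i_a)

    meta = {"flow_start": flow_start, "t_start": t_start}
    return MoleculeTrace(
        frame_times, labels, i_d, i_a, dt, molecule_id=molecule_id, truth=path, meta=meta
    )


def simulate_molecule_path(
    scheme: KineticScheme, horizon: float, flow_start: float, rng
) -> StatePath:
    """Latent path with the kinetics starting only at ``flow_start``.

    Before the competitor/protein flow the molecule sits in the scheme's
    initial state.
    """
    if flow_start >= horizon:
        i0 = scheme.index(scheme.initial_state)
        return StatePath(np.array([0.0]), np.array([i0]), scheme.state_names, horizon)
    p = gillespie_simulate(scheme, horizon - flow_start, rng)
    if flow_start > 0:
        p = p.shifted(flow_start, scheme.index(scheme.initial_state))
    return p


def synthesize_ensemble(
    condition: ExperimentCondition,
    scheme: KineticScheme,
    optics: OpticsModel,
    pattern: ExcitationPattern,
    *,
    horizon: float = 3600.0,
    movie_times: Sequence[float] | None = None,
    movie_duration: float = 2.0,
    max_trace_duration: float | None = None,
) -> list[MoleculeTrace]:
    """Generate an independent, per-molecule-seeded trace ensemble.

    Two sampling modes:

    * continuous (``movie_times=None``): every molecule is recorded for the
      full horizon (or until shortly after absorption when
      ``max_trace_duration`` trimming applies);
    * short movies: ``movie_times`` wall-clock times are covered by 2 s
      movies recorded from disjoint molecule subsets (round-robin split),
      emulating snapshot histograms from separate fields of view.

    Each molecule uses a counter-based RNG stream keyed on
    (condition.seed, molecule index) so ensembles are reproducible and
    order-independent.
    """
    traces: list[MoleculeTrace] = []
    n = condition.n_molecules
    if movie_times is not None and len(movie_times) == 0:
        raise ValueError("movie_times must be non-empty when given")
    for idx in range(n):
        rng = molecule_rng(condition.seed, idx)
        if movie_times is None:
            p = simulate_molecule_path(scheme, horizon, condition.flow_start, rng)
            dur = horizon
            if max_trace_duration is not None:
                last = float(p.times[-1])
                ended = scheme.is_absorbing_index(int(p.states[-1]))
                dur = min(horizon, last + max_trace_duration) if ended else horizon
            tr = synthesize_trace(
                p, scheme, optics, pattern, rng,
                duration=dur, flow_start=condition.flow_start, molecule_id=idx,
            )
        else:
            grp = idx % len(movie_times)
            t_m = float(movie_times[grp])
            span = t_m + movie_duration
            p = simulate_molecule_path(
                scheme, max(span, condition.flow_start + movie_duration), condition.flow_start, rng
            )
            tr = synthesize_trace(
                p, scheme, optics, pattern, rng,
                t_start=t_m, duration=movie_duration,
                flow_start=condition.flow_start, molecule_id=idx,
            )
            tr.meta["movie_time"] = t_m
        traces.append(tr)
    return traces
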