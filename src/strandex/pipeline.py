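"""Closed-loop simulate -> analyze drivers.

These functions wire the generator and the analysis together for each
assay type: simulate an ensemble with a preset's ground-truth rates, run
the full analysis pipeline on the synthetic data only (never peeking at
the latent truth), and report the recovered quantities next to the truth.
They back the CLI ``recover`` command and the acceptance suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fov import synthesize_fov_series
from .fret import (
    assign_bound_components,
    bound_fraction,
    bound_fraction_by_threshold,
    build_histogram,
    compute_fret,
    fit_gaussian_mixture,
)
from .infer import (
    BimolecularFit,
    DwellTimeSet,
    EventCall,
    EventThresholds,
    detect_events,
    fit_bimolecular,
    fit_fraction_decay,
    fit_spot_decay,
    measure_dwell_times,
)
from .kinetics import ExperimentCondition
from .optics import ExcitationPattern, OpticsModel
from .presets import CompetitionPreset, ExchangePreset, RealtimePreset, TransferPreset, get_preset
from .spots import SpotDetectionParams, count_series
from .synth import MoleculeTrace, synthesize_ensemble

__all__ = [
    "TransferRecovery",
    "ExchangeRecovery",
    "DwellRecovery",
    "CompetitionCheck",
    "snapshot_times",
    "recover_transfer_kbi",
    "recover_exchange",
    "recover_dwell",
    "competition_check",
]


def _subseed(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0])


def _snapshot_bound_fraction(
    series, free_E: float, bound_E: float, assign_tol: float = 0.15
) -> float:
    """Gaussian-area bound fraction with a threshold-count fallback.

    When a snapshot's population sits entirely in one peak the histogram
    has too few nonempty bins for a 2-component fit; the nearest-level
    per-molecule vote is then used instead.  An empty bound-component
    assignment (no component near the bound level) is zero bound weight.
    """
    hist = build_histogram(series)
    try:
        fit = fit_gaussian_mixture(
            hist, K=2, init_means=[free_E, bound_E], mean_halfwidth=0.08
        )
    except ValueError:
        return bound_fraction_by_threshold(series, bound_E, free_E)
    idx = assign_bound_components(fit, bound_E, tol=assign_tol)
    return bound_fraction(fit, idx) if idx else 0.0


def snapshot_times(
    k_nominal: float, n_snapshots: int = 12, base_interval: float = 60.0
) -> np.ndarray:
    """Histogram snapshot schedule for an expected decay rate.

    Snapshots every 60 s; for slow conditions the spacing is widened in
    whole minutes so the schedule spans ~2.5 decay lifetimes (the
    experimenter images until the transfer has visibly progressed).
    """
    span = 2.5 / max(k_nominal, 1e-12)
    interval = max(base_interval, base_interval * math.ceil(span / (n_snapshots - 1) / base_interval))
    return interval * np.arange(n_snapshots)


@dataclass
class TransferRecovery:
    preset_name: str
    truth_k_bi: float
    k_bi: float
    bimolecular: BimolecularFit
    per_concentration: list[dict] = field(default_factory=list)
    n_molecules_total: int = 0

    @property
    def relative_error(self) -> float:
        return abs(self.k_bi - self.truth_k_bi) / self.truth_k_bi


def recover_transfer_kbi(
    preset_name: str,
    seed: int,
    *,
    concentrations: Sequence[float] | None = None,
    n_per_snapshot: int = 84,
    n_snapshots: int = 12,
    optics: OpticsModel | None = None,
    pattern: ExcitationPattern | None = None,
) -> TransferRecovery:
    """Full snapshot-histogram closed loop: traces -> E -> GMM -> decay -> slope.

    For each competitor concentration an ensemble of short 2 s movies is
    synthesized at the snapshot times from disjoint molecule subsets; each
    snapshot's pooled E histogram is decomposed into free/bound Gaussians,
    the bound-component weight forms the bound-fraction time course, a
    single-exponential fit gives k_obs, and the weighted linear fit of
    k_obs over concentration gives the recovered bimolecular constant.
    """
    preset = get_preset(preset_name)
    if not isinstance(preset, TransferPreset):
        raise TypeError(f"{preset_name!r} is not a transfer preset")
    concs = tuple(concentrations if concentrations is not None else preset.conc_range)
    # unlabeled competitor: no fluorescent flow background
    optics = optics or OpticsModel(flow_background_step=0.0)
    pattern = pattern or ExcitationPattern(mode="alex")
    points = []
    per_conc = []
    n_total = 0
    for ic, conc in enumerate(concs):
        scheme = preset.scheme(conc)
        k_nom = preset.k_bi * conc
        times = snapshot_times(k_nom, n_snapshots)
        cond = ExperimentCondition(
            "transfer", competitor_conc=conc,
            n_molecules=n_per_snapshot * n_snapshots, seed=_subseed(seed, ic),
        )
        traces = synthesize_ensemble(
            cond, scheme, optics, pattern,
            horizon=float(times[-1] + 2.5), movie_times=times,
        )
        n_total += cond.n_molecules
        fracs, ns = [], []
        for t_m in times:
            grp = [tr for tr in traces if tr.meta.get("movie_time") == t_m]
            series = [compute_fret(tr, optics.leakage, total_intensity=optics.total_intensity) for tr in grp]
            f = _snapshot_bound_fraction(
                series, preset.fret_free, preset.fret_bound, preset.bound_assign_tol
            )
            fracs.append(f)
            ns.append(len(grp))
        decay = fit_fraction_decay(times, fracs, ns, with_plateau=False)
        points.append((conc, decay.k_obs, decay.k_sd))
        per_conc.append(
            {
                "conc_M": conc, "times_s": list(map(float, times)),
                "bound_fraction": list(map(float, fracs)),
                "k_obs": decay.k_obs, "k_obs_sd": decay.k_sd,
                "n_molecules": int(sum(ns)),
            }
        )
    bi = fit_bimolecular(points)
    return TransferRecovery(preset_name, preset.k_bi, bi.slope, bi, per_conc, n_total)


@dataclass
class ExchangeRecovery:
    preset_name: str
    truth_k_bi: float
    truth_fraction: float
    k_bi: float
    exchange_fraction: float
    bimolecular: BimolecularFit
    per_concentration: list[dict] = field(default_factory=list)
    n_spots_total: int = 0

    @property
    def relative_error(self) -> float:
        return abs(self.k_bi - self.truth_k_bi) / self.truth_k_bi


def recover_exchange(
    preset_name: str,
    seed: int,
    *,
    concentrations: Sequence[float] | None = None,
    n_times: int = 14,
    image_shape: tuple[int, int] = (512, 512),
    params: SpotDetectionParams | None = None,
) -> ExchangeRecovery:
    """Spot-count closed loop: FOV images -> detection -> decay -> slope.

    Synthesizes field-of-view series with exponential spot survival toward
    the preset's residual fraction, counts spots per image, fits
    N(t) = N_res + (N0-N_res)exp(-kt) per concentration, and recovers the
    bimolecular constant from the concentration dependence and the
    exchange fraction from the plateau.
    """
    preset = get_preset(preset_name)
    if not isinstance(preset, ExchangePreset):
        raise TypeError(f"{preset_name!r} is not an exchange preset")
    concs = tuple(concentrations if concentrations is not None else preset.conc_range)
    params = params or SpotDetectionParams()
    points, fractions, per_conc = [], [], []
    n_spots_total = 0
    for ic, conc in enumerate(concs):
        k_true = preset.k_bi * conc
        t_end = 4.5 / k_true
        times = np.linspace(0.0, t_end, n_times)
        fov = synthesize_fov_series(
            preset.n_spots, k_true, 1.0 - preset.exchange_fraction,
            image_shape, times, _subseed(seed, ic),
            psf_sigma=params.psf_sigma_expected,
        )
        counts = count_series(fov, params)
        res = fit_spot_decay(counts, with_plateau=True)
        points.append((conc, res.decay.k_obs, res.decay.k_sd))
        fractions.append(res.exchange_fraction)
        n_spots_total += int(counts.n_initial)
        per_conc.append(
            {
                "conc_M": conc, "times_s": list(map(float, times)),
                "counts": list(map(int, counts.counts)),
                "k_obs": res.decay.k_obs, "k_obs_sd": res.decay.k_sd,
                "exchange_fraction": res.exchange_fraction,
            }
        )
    bi = fit_bimolecular(points)
    return ExchangeRecovery(
        preset_name, preset.k_bi, preset.exchange_fraction,
        bi.slope, float(np.mean(fractions)), bi, per_conc, n_spots_total,
    )


@dataclass
class DwellRecovery:
    preset_name: str
    truth_dwell: float
    dwell: DwellTimeSet
    events: list[EventCall]
    traces: list[MoleculeTrace] | None = None

    @property
    def gaussian_mean(self) -> float:
        return self.dwell.gaussian_mean

    @property
    def relative_error(self) -> float:
        return abs(self.dwell.gaussian_mean - self.truth_dwell) / self.truth_dwell


def recover_dwell(
    preset_name: str,
    seed: int,
    *,
    n_traces: int = 250,
    conc: float | None = None,
    horizon: float = 3000.0,
    optics: OpticsModel | None = None,
    keep_traces: bool = False,
    thresholds: EventThresholds = EventThresholds(),
) -> DwellRecovery:
    """Real-time labeled-competitor closed loop: traces -> events -> dwell fit.

    Simulates continuous 50 ms green-excitation traces with the labeled
    competitor (flow background step, intensity spikes for failed
    attempts, two-donor acceptor boost during the ternary complex),
    detects binding and completed transfer per trace, and fits the pooled
    dwell-time histogram with a Gaussian.
    """
    preset = get_preset(preset_name)
    if not isinstance(preset, RealtimePreset):
        raise TypeError(f"{preset_name!r} is not a real-time preset")
    conc = conc if conc is not None else preset.default_conc
    scheme = preset.scheme(conc)
    optics = optics or OpticsModel()  # labeled competitor: flow step present
    pattern = ExcitationPattern(mode="continuous_green")
    cond = ExperimentCondition(
        "transfer", competitor_conc=conc, flow_start=preset.flow_start,
        n_molecules=n_traces, seed=_subseed(seed, 0),
    )
    traces = synthesize_ensemble(
        cond, scheme, optics, pattern, horizon=horizon, max_trace_duration=30.0
    )
    events: list[EventCall] = []
    for tr in traces:
        series = compute_fret(tr, optics.leakage, total_intensity=optics.total_intensity)
        events.extend(detect_events(tr, series, thresholds))
    dwell = measure_dwell_times(events)
    return DwellRecovery(
        preset_name, preset.dwell_mean, dwell, events, traces if keep_traces else None
    )


@dataclass
class CompetitionCheck:
    preset_name: str
    dna_bound_fraction: float
    rna_bound_fraction: float
    horizon: float


def competition_check(
    preset_name: str,
    seed: int,
    *,
    horizon: float = 600.0,
    n_molecules: int = 150,
) -> CompetitionCheck:
    """Competing-RNA asymmetry: RNA-bound protein transfers, DNA-bound stays.

    Runs both substrate schemes under the RNA-competitor condition through
    the snapshot histogram pipeline and reports the bound fraction of each
    substrate population at the end of the horizon.
    """
    preset = get_preset(preset_name)
    if not isinstance(preset, CompetitionPreset):
        raise TypeError(f"{preset_name!r} is not a competition preset")
    from .kinetics import build_competition_scheme

    optics = OpticsModel(flow_background_step=0.0)
    pattern = ExcitationPattern(mode="alex")
    fractions = {}
    for tag, substrate in enumerate(("DNA", "RNA")):
        k_rna = (
            preset.k_displace_by_RNA_on_DNA
            if substrate == "DNA"
            else preset.k_displace_by_RNA_on_RNA
        )
        bound_e = preset.fret_bound_DNA if substrate == "DNA" else preset.fret_bound_RNA
        free_e = preset.fret_free_DNA if substrate == "DNA" else preset.fret_free_RNA
        scheme = build_competition_scheme(
            substrate, k_rna, 0.0, {"RNA": preset.rna_conc, "DNA": 0.0},
            fret_bound=bound_e, fret_free=free_e,
        )
        cond = ExperimentCondition(
            "competition", competitor_conc=preset.rna_conc,
            n_molecules=n_molecules, seed=_subseed(seed, tag),
        )
        traces = synthesize_ensemble(
            cond, scheme, optics, pattern,
            horizon=horizon + 2.5, movie_times=[horizon],
        )
        series = [compute_fret(tr, optics.leakage, total_intensity=optics.total_intensity) for tr in traces]
        fractions[substrate] = _snapshot_bound_fraction(series, free_e, bound_e)
    return CompetitionCheck(preset_name, fractions["DNA"], fractions["RNA"], horizon)
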