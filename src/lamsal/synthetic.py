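"""Synthetic inputs with known ground truth.

Everything the analysis pipeline consumes can be generated here: block-design
stimulus timelines, laminar partial-volume phantoms, paired nulled/not-nulled
VASO acquisitions, pRF node tables, condition-coupled depth timeseries for
connectivity, and 1-kHz gaze traces with blinks.

Study conditions emulated by the defaults: 30-s stimulus blocks interleaved
with 15-s fixation, 60 texture events per block (200 ms stimulus, 200/300/400
ms ISI), three orientation-contrast conditions (theta = 90, 15, 0 degrees),
a paired repetition time of 5.02 s, and five partial-volume compartments
(WM, deep, middle, superficial, CSF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exceptions import InvalidArgumentError
from .hrf import block_regressors, double_gamma_hrf

__all__ = [
    "COMPARTMENTS",
    "Event",
    "Block",
    "StimulusTimeline",
    "LaminarPhantom",
    "PairedVasoRun",
    "GazeTrace",
    "generate_block_design",
    "generate_laminar_phantom",
    "simulate_paired_vaso_run",
    "generate_prf_nodes",
    "simulate_coupled_depth_series",
    "simulate_gaze",
]

#: Partial-volume compartments, in matrix-column order.
COMPARTMENTS = ("wm", "deep", "middle", "superficial", "csf")

#: Cortical-layer subset of :data:`COMPARTMENTS`.
LAYERS = ("deep", "middle", "superficial")


class Event(NamedTuple):
    onset: float       # seconds from run start
    duration: float    # seconds (stimulus on-time)
    theta: float       # orientation contrast, degrees
    side: str          # "left" or "right"


class Block(NamedTuple):
    start: float
    end: float
    theta: float


@dataclass(frozen=True)
class StimulusTimeline:
    """Block/event schedule of one run."""

    events: tuple
    blocks: tuple
    run_duration: float
    paired_tr: float = 5.02
    conditions: tuple = (90.0, 15.0, 0.0)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["onset", "duration", "theta", "side"])

    def blocks_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.blocks, columns=["start", "end", "theta"])

    def block_labels(self, times: np.ndarray) -> np.ndarray:
        """Theta per time sample; NaN during fixation."""
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, np.nan)
        for start, end, theta in self.blocks:
            out[(times >= start) & (times < end)] = theta
        return out


@dataclass(frozen=True)
class LaminarPhantom:
    """Voxel layer-weight matrix with known per-layer, per-condition truth.

    ``weights`` is (n_voxels, 5) of volume fractions over
    (WM, deep, middle, superficial, CSF); each row sums to 1. ``b_true`` is
    (5, n_conditions) response amplitude in percent signal change.
    """

    weights: np.ndarray
    b_true: np.ndarray
    noise_sd: float = 0.5          # percent signal change
    drift_amplitude: float = 0.5   # percent over one run
    conditions: tuple = (90.0, 15.0, 0.0)
    profile_name: str = "custom"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != len(COMPARTMENTS):
            raise InvalidArgumentError("weights must be (n_voxels, 5)")
        if (w < 0).any():
            raise InvalidArgumentError("weights must be non-negative")
        if not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidArgumentError("every weight row must sum to 1")


@dataclass(frozen=True)
class PairedVasoRun:
    """Alternating blood-nulled / not-nulled acquisitions of one run."""

    nulled: np.ndarray       # (n_voxels, n_pairs), arbitrary scanner units
    not_nulled: np.ndarray   # same shape
    paired_tr: float = 5.02
    baseline: np.ndarray | None = None  # per-voxel nulled baseline
    nulled_first: bool = True

    def __post_init__(self):
        if self.nulled.shape != self.not_nulled.shape:
            raise InvalidArgumentError("nulled and not_nulled must have identical shapes")
        if self.baseline is not None and (np.asarray(self.baseline) <= 0).any():
            raise InvalidArgumentError("baseline values must be strictly positive")


@dataclass
class GazeTrace:
    """1-kHz gaze positions in degrees relative to fixation."""

    t: np.ndarray                  # milliseconds, strictly increasing 1-ms steps
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray              # False inside blink intervals
    blink_intervals: tuple = ()
    block_labels: np.ndarray | None = None  # theta per sample, NaN in fixation

    def frame(self) -> pd.DataFrame:
        d = {"t_ms": self.t, "x_deg": self.x, "y_deg": self.y, "valid": self.valid}
        if self.block_labels is not None:
            d["condition"] = self.block_labels
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_block_design(
    n_blocks: int = 6,
    block_s: float = 30.0,
    fix_s: float = 15.0,
    stim_ms: float = 200.0,
    isi_choices_ms: Sequence[float] = (200.0, 300.0, 400.0),
    events_per_block: int = 60,
    conditions: Sequence[float] = (90.0, 15.0, 0.0),
    seed: int = 0,
    paired_tr: float = 5.02,
) -> StimulusTimeline:
    """Blocked stimulus schedule with balanced condition order.

    Blocks of ``block_s`` s are each followed by a ``fix_s`` fixation gap, so
    ``run_duration = n_blocks * (block_s + fix_s)``. Within a block exactly
    ``events_per_block`` events are packed: each event is ``stim_ms`` of
    stimulus followed by an ISI drawn uniformly from ``isi_choices_ms``; the
    final ISI is set so the last event slot ends exactly at the block
    boundary (if the drawn ISIs overflow the block, all ISIs are shrunk
    proportionally instead).
    """
    if len(conditions) == 0:
        raise InvalidArgumentError("conditions must be non-empty")
    if block_s <= 0 or fix_s <= 0 or stim_ms <= 0:
        raise InvalidArgumentError("durations must be positive")
    if n_blocks < 0 or events_per_block <= 0:
        raise InvalidArgumentError("counts must be positive")
    if n_blocks == 0:
        return StimulusTimeline((), (), 0.0, paired_tr, tuple(conditions))
    if n_blocks % len(conditions) != 0:
        raise InvalidArgumentError("n_blocks must be a multiple of the number of conditions")
    stim_s = stim_ms / 1000.0
    if events_per_block * stim_s > block_s:
        raise InvalidArgumentError("stimuli alone exceed the block duration")

    rng = np.random.default_rng(seed)
    order = rng.permutation(np.repeat(np.asarray(conditions, dtype=float),
                                      n_blocks // len(conditions)))
    isi_choices = np.asarray(isi_choices_ms, dtype=float) / 1000.0

    events: list[Event] = []
    blocks: list[Block] = []
    for i, theta in enumerate(order):
        start = i * (block_s + fix_s)
        blocks.append(Block(start, start + block_s, float(theta)))
        isis = rng.choice(isi_choices, size=events_per_block)
        head = events_per_block * stim_s + isis[:-1].sum()
        if head <= block_s:
            isis[-1] = block_s - head          # pad/truncate the final ISI
        else:
            isis *= (block_s - events_per_block * stim_s) / isis.sum()
        sides = rng.choice(["left", "right"], size=events_per_block)
        onset = start
        for k in range(events_per_block):
            events.append(Event(onset, stim_s, float(theta), str(sides[k])))
            onset += stim_s + isis[k]
    run_duration = n_blocks * (block_s + fix_s)
    return StimulusTimeline(tuple(events), tuple(blocks), float(run_duration),
                            paired_tr, tuple(conditions))


# Laminar contrast profiles: relative 90-vs-15 effect over (deep, mid, sup).
# v1_like peaks superficially (horizontal-connection locus), ips_like in the
# middle (feedforward-recipient), v2_like in middle+superficial.
_PROFILES = {
    "v1_like": np.array([0.3, 0.5, 1.0]),
    "v2_like": np.array([0.3, 1.0, 0.9]),
    "ips_like": np.array([0.4, 1.0, 0.4]),
    "flat": np.array([1.0, 1.0, 1.0]),
}


def generate_laminar_phantom(
    n_voxels: int = 300,
    profile_name: str = "v1_like",
    effect_size: float = 1.0,
    pv_concentration: float = 50.0,
    seed: int = 0,
    base_response: float = 1.0,
    noise_sd: float = 0.5,
    drift_amplitude: float = 0.5,
    conditions: Sequence[float] = (90.0, 15.0, 0.0),
) -> LaminarPhantom:
    """Partial-volume phantom with a known laminar saliency effect.

    Each voxel is assigned a home compartment and its volume fractions are
    drawn from a Dirichlet concentrated there (``pv_concentration`` controls
    purity; neighbouring compartments share mass, mimicking voxels straddling
    layer boundaries). ``b_true`` gives every cortical layer a common
    ``base_response`` for all conditions plus a 90-degree increment of
    ``effect_size`` scaled by the profile's laminar weights; WM and CSF are
    silent.
    """
    if n_voxels < 5:
        raise InvalidArgumentError("need at least 5 voxels (one per compartment)")
    if profile_name not in _PROFILES:
        raise InvalidArgumentError(
            f"unknown profile {profile_name!r}; choose from {sorted(_PROFILES)}")
    if pv_concentration <= 0:
        raise InvalidArgumentError("pv_concentration must be positive")
    rng = np.random.default_rng(seed)

    n_comp = len(COMPARTMENTS)
    home = np.tile(np.arange(n_comp), n_voxels // n_comp + 1)[:n_voxels]
    rng.shuffle(home)
    weights = np.empty((n_voxels, n_comp))
    for c in range(n_comp):
        kernel = np.full(n_comp, 0.02)
        kernel[c] = 1.0
        if c > 0:
            kernel[c - 1] = 0.3
        if c < n_comp - 1:
            kernel[c + 1] = 0.3
        idx = home == c
        if idx.any():
            weights[idx] = rng.dirichlet(pv_concentration * kernel, size=int(idx.sum()))
    weights /= weights.sum(axis=1, keepdims=True)

    conditions = tuple(float(c) for c in conditions)
    b_true = np.zeros((n_comp, len(conditions)))
    w_eff = _PROFILES[profile_name]
    for j, theta in enumerate(conditions):
        b_true[1:4, j] = base_response
        if theta == 90.0:
            b_true[1:4, j] += effect_size * w_eff
    return LaminarPhantom(weights, b_true, noise_sd, drift_amplitude,
                          conditions, profile_name)


def simulate_paired_vaso_run(
    phantom: LaminarPhantom,
    timeline: StimulusTimeline,
    cbv_gain: float = 1.0,
    bold_gain: float = 1.0,
    seed: int = 0,
    baseline_range: tuple = (800.0, 1200.0),
) -> PairedVasoRun:
    """Simulate alternating nulled / not-nulled volumes for one run.

    The per-condition neural regressor is the block boxcar convolved with the
    canonical HRF (unit peak). Voxel CBV amplitude is ``weights @ b_true`` in
    percent signal change. Following the VASO convention the nulled signal
    *dips* with a CBV increase (scaled by ``cbv_gain``); a positive BOLD-like
    component (same laminar amplitudes, scaled by ``bold_gain``) multiplies
    both series so that nulled/not-nulled division removes it. Gaussian noise
    (``phantom.noise_sd`` %) and a per-voxel linear drift
    (``phantom.drift_amplitude`` % over the run) are added. Nulled volumes are
    sampled at k*TR, not-nulled at k*TR + TR/2 (alternating acquisition).
    """
    tr = timeline.paired_tr
    if timeline.run_duration < 2 * tr:
        raise InvalidArgumentError("run must cover at least two paired TRs")
    n_pairs = int(timeline.run_duration // tr)
    rng = np.random.default_rng(seed)
    n_vox = phantom.weights.shape[0]

    t_null = np.arange(n_pairs) * tr
    t_nn = t_null + tr / 2.0
    amp = phantom.weights @ phantom.b_true          # (n_vox, n_cond), psc

    def psc_components(times):
        reg = block_regressors(timeline, times, conditions=phantom.conditions)
        return amp @ reg.T                           # (n_vox, n_times)

    cbv_n, cbv_nn = psc_components(t_null), psc_components(t_nn)
    base = rng.uniform(*baseline_range, size=n_vox)
    base_nn = base * rng.uniform(1.3, 1.7, size=n_vox)
    slope = rng.uniform(-1.0, 1.0, size=n_vox) * phantom.drift_amplitude

    def drift(times):
        return slope[:, None] * (times[None, :] / max(timeline.run_duration, 1.0) - 0.5)

    noise_n = rng.standard_normal((n_vox, n_pairs)) * phantom.noise_sd
    noise_nn = rng.standard_normal((n_vox, n_pairs)) * phantom.noise_sd
    nulled = base[:, None] * (
        (1.0 - cbv_gain * cbv_n / 100.0)
        * (1.0 + bold_gain * cbv_n / 100.0)
        * (1.0 + (drift(t_null) + noise_n) / 100.0)
    )
    not_nulled = base_nn[:, None] * (
        (1.0 + bold_gain * cbv_nn / 100.0)
        * (1.0 + (drift(t_nn) + noise_nn) / 100.0)
    )
    return PairedVasoRun(nulled, not_nulled, tr, base)


def generate_prf_nodes(
    n_nodes: int,
    hemisphere: str = "left",
    Am: float = 120.0,
    Em: float = 4.0,
    sigma_slope: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic pRF node table (stand-in for an atlas-derived table).

    Polar angles A are uniform on [0, 180] degrees (within-hemisphere
    convention: 0 = upper vertical meridian, 180 = lower vertical meridian),
    eccentricities E log-uniform on [0.5, 10] degrees, and sizes
    sigma = max(0.1, sigma_slope * E). Node 0 is anchored exactly at
    (Am, Em) — the localizer-peak coordinates used for pRF correction.
    """
    if not (0.0 < Am < 180.0):
        raise InvalidArgumentError("Am must lie strictly inside (0, 180) degrees")
    if Em <= 0:
        raise InvalidArgumentError("Em must be positive")
    if n_nodes < 1:
        raise InvalidArgumentError("n_nodes must be >= 1")
    if hemisphere not in ("left", "right"):
        raise InvalidArgumentError("hemisphere must be 'left' or 'right'")
    rng = np.random.default_rng(seed)
    A = np.concatenate([[Am], rng.uniform(0.0, 180.0, size=n_nodes - 1)])
    E = np.concatenate([[Em], np.exp(rng.uniform(np.log(0.5), np.log(10.0),
                                                 size=n_nodes - 1))])
    sigma = np.maximum(0.1, sigma_slope * E)
    return pd.DataFrame({
        "node": np.arange(n_nodes),
        "hemisphere": hemisphere,
        "A": A,
        "E": E,
        "sigma": sigma,
    })


def simulate_coupled_depth_series(
    timeline: StimulusTimeline,
    tr: float,
    coupling: dict | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple:
    """Seed/target timeseries pair with condition-dependent coupling.

    The seed is stimulus-driven activity (HRF-convolved blocks summed over
    conditions) plus noise. Inside a theta block the target receives
    ``coupling[theta] * seed``; outside, no coupling. This is the generative
    model that gPPI is designed to recover: its delta estimates
    ``coupling[90] - coupling[15]``.
    """
    if coupling is None:
        coupling = {90.0: 1.0, 15.0: 0.3, 0.0: 0.3}
    rng = np.random.default_rng(seed)
    n = int(timeline.run_duration // tr)
    times = np.arange(n) * tr
    reg = block_regressors(timeline, times, conditions=timeline.conditions)
    seed_ts = reg.sum(axis=1) + rng.standard_normal(n) * noise_sd
    labels = timeline.block_labels(times)
    gain = np.zeros(n)
    for theta, g in coupling.items():
        gain[labels == float(theta)] = g
    target_ts = gain * seed_ts + rng.standard_normal(n) * noise_sd
    return seed_ts, target_ts


def simulate_gaze(
    duration_s: float,
    sigma_x: float = 0.3,
    sigma_y: float = 0.2,
    rho: float = 0.0,
    blink_rate_hz: float = 0.2,
    seed: int = 0,
    ar_coef: float = 0.95,
    blink_mean_ms: float = 100.0,
    timeline: StimulusTimeline | None = None,
) -> GazeTrace:
    """Bivariate-Gaussian fixation trace at 1000 Hz with blinks.

    Gaze follows an AR(1) process (lag-1 coefficient ``ar_coef``) whose
    stationary covariance matches the requested moments, so BCEA estimators
    face realistic autocorrelation. Blinks arrive as a Poisson process at
    ``blink_rate_hz`` with exponentially distributed durations (mean
    ``blink_mean_ms``); samples inside a blink are flagged invalid.
    """
    if not (abs(rho) < 1.0):
        raise InvalidArgumentError("|rho| must be < 1")
    if sigma_x <= 0 or sigma_y <= 0:
        raise InvalidArgumentError("sigmas must be positive")
    if duration_s <= 0:
        raise InvalidArgumentError("duration must be positive")
    if blink_rate_hz < 0:
        raise InvalidArgumentError("blink rate must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * 1000.0))
    t = np.arange(n)

    cov = np.array([[sigma_x**2, rho * sigma_x * sigma_y],
                    [rho * sigma_x * sigma_y, sigma_y**2]])
    chol = np.linalg.cholesky(cov)
    innov = rng.standard_normal((n, 2)) @ (chol.T * np.sqrt(1.0 - ar_coef**2))
    x0 = chol @ rng.standard_normal(2)
    xy = lfilter([1.0], [1.0, -ar_coef], innov, axis=0)
    xy += np.power(ar_coef, np.arange(1, n + 1))[:, None] * x0

    valid = np.ones(n, dtype=bool)
    blink_intervals = []
    if blink_rate_hz > 0:
        t_ms = rng.exponential(1000.0 / blink_rate_hz)
        while t_ms < n:
            dur = rng.exponential(blink_mean_ms)
            a, b = int(t_ms), int(min(n, t_ms + dur))
            blink_intervals.append((a, b))
            valid[a:b] = False
            t_ms = b + rng.exponential(1000.0 / blink_rate_hz)

    labels = None
    if timeline is not None:
        labels = timeline.block_labels(t / 1000.0)
    return GazeTrace(t, xy[:, 0], xy[:, 1], valid, tuple(blink_intervals), labels)
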