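"""Canonical haemodynamic response function and block-design regressors.

The simulator and the GLM share one regressor construction so that, in the
noiseless limit, fitted betas equal the generating per-condition amplitudes in
percent signal change.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats as _st

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import StimulusTimeline

__all__ = ["double_gamma_hrf", "block_regressors"]


def double_gamma_hrf(
    t: np.ndarray,
    peak: float = 6.0,
    undershoot: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    dispersion: float = 1.0,
) -> np.ndarray:
    """Unit-peak double-gamma HRF evaluated at times ``t`` (seconds).

    The positive lobe peaks near ``peak`` s and the undershoot near
    ``undershoot`` s with relative amplitude ``undershoot_ratio``. Values for
    t < 0 are zero. The curve is normalized to a maximum of 1 so that a
    convolved unit boxcar keeps percent-signal-change units.
    """
    t = np.asarray(t, dtype=float)
    pos = _st.gamma.pdf(t, peak / dispersion, scale=dispersion)
    neg = _st.gamma.pdf(t, undershoot / dispersion, scale=dispersion)
    h = np.where(t < 0, 0.0, pos - undershoot_ratio * neg)
    m = h.max()
    if m <= 0:
        raise ValueError("HRF has non-positive peak; check parameters")
    return h / m


def block_regressors(
    timeline: "StimulusTimeline",
    times: Sequence[float],
    hrf=double_gamma_hrf,
    dt: float = 0.1,
    conditions: Sequence[float] | None = None,
) -> np.ndarray:
    """Condition regressors: block boxcars convolved with the canonical HRF.

    Each column is the boxcar of one orientation-contrast condition convolved
    with ``hrf`` on a fine grid (step ``dt`` s), unit-peak scaled, and sampled
    at ``times``. With unit-peak scaling, a GLM beta against these regressors
    reads directly as the block-plateau response amplitude.

    Returns an array of shape ``(len(times), n_conditions)``.
    """
    if conditions is None:
        conditions = timeline.conditions
    times = np.asarray(times, dtype=float)
    pad = 32.0  # allow the HRF tail to develop
    n_fine = int(np.ceil((timeline.run_duration + pad) / dt)) + 1
    t_fine = np.arange(n_fine) * dt
    kernel = hrf(np.arange(0.0, pad, dt))
    out = np.zeros((times.size, len(conditions)))
    for j, theta in enumerate(conditions):
        box = np.zeros(n_fine)
        for start, end, th in timeline.blocks:
            if th == theta:
                box[(t_fine >= start) & (t_fine < end)] = 1.0
        conv = np.convolve(box, kernel)[:n_fine] * dt
        m = conv.max()
        if m > 0:
            conv = conv / m
        out[:, j] = np.interp(times, t_fine, conv)
    return out
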