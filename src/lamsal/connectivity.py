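"""Layer-dependent gPPI effective connectivity without deconvolution.

Because the CBV haemodynamic response is uncertain, the psychophysiological
interaction regressor is built directly in signal space: the per-condition
stimulus boxcar, shifted by one TR to allow for the haemodynamic delay, is
multiplied elementwise with the z-scored seed timecourse. The GLM includes
the seed timecourse, the stimulus regressors, the three PPI terms, and
drift/motion nuisance columns. Saliency-dependent connectivity is the
difference of the 90- and 15-degree PPI betas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import InvalidArgumentError, InvalidDesignError
from .synthetic import LAYERS, StimulusTimeline
from .vaso import _check_rank, _legendre_drift

__all__ = [
    "PpiDesign",
    "ConnectivityResult",
    "GPPI",
    "build_ppi_design",
    "fit_gppi",
    "pathway_analysis",
    "PathwayResult",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PpiDesign:
    """Assembled gPPI design for one seed timecourse."""

    seed_z: np.ndarray        # z-scored seed, mean 0 / SD 1
    stim: np.ndarray          # (n, n_cond) shifted boxcars
    ppi: np.ndarray           # (n, n_cond) shifted boxcar * seed_z
    nuisance: np.ndarray      # (n, k) drift + user columns
    conditions: tuple
    tr: float

    def matrix(self) -> tuple:
        X = np.concatenate(
            [self.nuisance, self.seed_z[:, None], self.stim, self.ppi], axis=1)
        names = ([f"nuisance_{k}" for k in range(self.nuisance.shape[1])]
                 + ["seed"]
                 + [f"stim_{c:g}" for c in self.conditions]
                 + [f"ppi_{c:g}" for c in self.conditions])
        return X, names


def build_ppi_design(seed_ts: np.ndarray, timeline: StimulusTimeline,
                     tr: float, shift_trs: int = 1,
                     nuisance=None, drift_order: int = 2) -> PpiDesign:
    """Build the deconvolution-free PPI design for a seed timecourse.

    The seed is z-scored over the run. Per-condition boxcars are sampled at
    ``tr`` and shifted forward by ``shift_trs`` samples (haemodynamic delay);
    each PPI term is the elementwise product of the shifted boxcar and the
    z-scored seed, hence zero wherever the shifted boxcar is zero.
    """
    seed_ts = np.asarray(seed_ts, dtype=float).ravel()
    n_expected = int(timeline.run_duration // tr)
    if seed_ts.size != n_expected:
        raise InvalidArgumentError(
            f"seed length {seed_ts.size} does not match timeline sampling "
            f"({n_expected} samples at tr={tr})")
    sd = seed_ts.std()
    if sd == 0:
        raise InvalidArgumentError("seed timeseries has zero variance")
    seed_z = (seed_ts - seed_ts.mean()) / sd

    times = np.arange(n_expected) * tr
    labels = timeline.block_labels(times)
    stim = np.zeros((n_expected, len(timeline.conditions)))
    for j, theta in enumerate(timeline.conditions):
        box = (labels == float(theta)).astype(float)
        stim[:, j] = np.concatenate([np.zeros(shift_trs), box[:-shift_trs]]) \
            if shift_trs > 0 else box
    ppi = stim * seed_z[:, None]

    drift = _legendre_drift(n_expected, drift_order)
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_expected:
            nuisance = nuisance.T
        if nuisance.shape[0] != n_expected:
            raise InvalidArgumentError("nuisance length mismatch")
        drift = np.concatenate([drift, nuisance], axis=1)
    return PpiDesign(seed_z, stim, ppi, drift, tuple(timeline.conditions), tr)


@dataclass(frozen=True)
class ConnectivityResult:
    """gPPI betas for one seed-target pair."""

    beta_ppi: dict            # theta -> PPI beta
    beta_seed: float
    beta_stim: dict           # theta -> stimulus beta
    delta: float              # beta_ppi(90) - beta_ppi(15)
    pathway: str = ""
    stderr_ppi: dict = field(default_factory=dict)


class GPPI(BaseEstimator):
    """OLS generalized psychophysiological interaction model.

    Fit a target timecourse on a :class:`PpiDesign`; fitted attributes hold
    the per-condition PPI betas and the 90-minus-15 connectivity difference.
    """

    def fit(self, design: PpiDesign, target_ts: np.ndarray):
        y = np.asarray(target_ts, dtype=float).ravel()
        X, names = design.matrix()
        if y.size != X.shape[0]:
            raise InvalidArgumentError("target length does not match the design")
        _check_rank(X, names)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(y.size - X.shape[1], 1)
        sigma2 = (resid**2).sum() / dof
        se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
        lut = dict(zip(names, beta))
        selut = dict(zip(names, se))
        self.beta_ppi_ = {c: lut[f"ppi_{c:g}"] for c in design.conditions}
        self.stderr_ppi_ = {c: selut[f"ppi_{c:g}"] for c in design.conditions}
        self.beta_stim_ = {c: lut[f"stim_{c:g}"] for c in design.conditions}
        self.beta_seed_ = lut["seed"]
        self.delta_ = self.beta_ppi_[90.0] - self.beta_ppi_[15.0] \
            if 90.0 in self.beta_ppi_ and 15.0 in self.beta_ppi_ else np.nan
        self.conditions_ = design.conditions
        return self

    def result_(self, pathway: str = "") -> ConnectivityResult:
        return ConnectivityResult(dict(self.beta_ppi_), float(self.beta_seed_),
                                  dict(self.beta_stim_), float(self.delta_),
                                  pathway, dict(self.stderr_ppi_))


def fit_gppi(target_ts: np.ndarray, design: PpiDesign,
             pathway: str = "") -> ConnectivityResult:
    """OLS gPPI fit; see :class:`GPPI`."""
    return GPPI().fit(design, target_ts).result_(pathway)


@dataclass(frozen=True)
class PathwayResult:
    """Hemisphere-averaged feedforward and feedback connectivity."""

    feedforward: ConnectivityResult   # V1 superficial -> IPS middle
    feedback: ConnectivityResult      # IPS deep -> V1 deep
    matrix: pd.DataFrame              # V1-seed x IPS-target delta matrix
    per_hemisphere: dict


def _average_results(results, pathway: str) -> ConnectivityResult:
    conds = results[0].beta_ppi.keys()
    return ConnectivityResult(
        {c: float(np.mean([r.beta_ppi[c] for r in results])) for c in conds},
        float(np.mean([r.beta_seed for r in results])),
        {c: float(np.mean([r.beta_stim[c] for r in results])) for c in conds},
        float(np.mean([r.delta for r in results])),
        pathway,
    )


def pathway_analysis(v1_layers: dict, ips_layers: dict,
                     timeline: StimulusTimeline, tr: float,
                     shift_trs: int = 1, nuisance=None) -> PathwayResult:
    """Feedforward/feedback gPPI between V1 and IPS depth timeseries.

    ``v1_layers`` and ``ips_layers`` map hemisphere -> {depth -> timeseries}
    with depths 'deep', 'middle', 'superficial'. Feedforward couples the V1
    superficial seed to the IPS middle target; feedback couples the IPS deep
    seed to the V1 deep target. Fits run per hemisphere and betas are
    averaged; with a single hemisphere the averaging is skipped and logged.
    The full V1-seed-depth x IPS-target-depth delta matrix is also returned.
    """
    hemis = sorted(set(v1_layers) & set(ips_layers))
    if not hemis:
        raise InvalidArgumentError("no common hemispheres supplied")
    if len(hemis) == 1:
        logger.info("single hemisphere %s supplied; averaging skipped", hemis[0])
    for hemi in hemis:
        for depth in LAYERS:
            if depth not in v1_layers[hemi] or depth not in ips_layers[hemi]:
                raise InvalidArgumentError(
                    f"missing depth series {depth!r} in hemisphere {hemi!r}")

    ff, fb, per_hemi = [], [], {}
    mats = []
    for hemi in hemis:
        d_ff = build_ppi_design(v1_layers[hemi]["superficial"], timeline, tr,
                                shift_trs, nuisance)
        r_ff = fit_gppi(ips_layers[hemi]["middle"], d_ff, "feedforward")
        d_fb = build_ppi_design(ips_layers[hemi]["deep"], timeline, tr,
                                shift_trs, nuisance)
        r_fb = fit_gppi(v1_layers[hemi]["deep"], d_fb, "feedback")
        ff.append(r_ff)
        fb.append(r_fb)
        per_hemi[hemi] = {"feedforward": r_ff, "feedback": r_fb}
        mat = np.empty((len(LAYERS), len(LAYERS)))
        for i, seed_depth in enumerate(LAYERS):
            d = build_ppi_design(v1_layers[hemi][seed_depth], timeline, tr,
                                 shift_trs, nuisance)
            for j, tgt_depth in enumerate(LAYERS):
                mat[i, j] = fit_gppi(ips_layers[hemi][tgt_depth], d).delta
        mats.append(mat)
    matrix = pd.DataFrame(np.mean(mats, axis=0),
                          index=[f"v1_{d}" for d in LAYERS],
                          columns=[f"ips_{d}" for d in LAYERS])
    return PathwayResult(_average_results(ff, "feedforward"),
                         _average_results(fb, "feedback"), matrix, per_hemi)
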