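"""Partial-volume layer unmixing and normalized laminar saliency statistics.

A voxel's measured response is a volume-weighted mixture of compartment
responses (WM, three equi-volume cortical layers, CSF). Unmixing solves the
spatial regression Y = X B + U by least squares, where X holds each voxel's
volume fractions. Group profiles are normalized per subject by the RMS
response over the 3 layers x 3 conditions cells and rescaled by the group
mean of that normalizer, so every subject contributes with equal overall
magnitude while the group units remain percent signal change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import InvalidArgumentError, InvalidDesignError
from .synthetic import COMPARTMENTS, LAYERS

__all__ = [
    "LayerUnmixer",
    "LayerProfile",
    "SaliencyContrasts",
    "unmix_layers",
    "normalize_responses",
    "saliency_contrasts",
    "snr_normalized_saliency",
]


class LayerUnmixer(BaseEstimator):
    """Least-squares unmixing of voxel responses into compartment responses.

    Solves ``B = argmin ||Y - X B||^2`` for the 5 compartments jointly (all
    five are estimated; downstream statistics use the 3 cortical layers and
    WM/CSF are retained for QC).

    Attributes (after ``fit``)
    --------------------------
    coef_ : (5,) or (5, k) compartment responses.
    stderr_ : matching standard errors from the residual variance.
    residual_sd_ : residual standard deviation(s).
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise InvalidArgumentError("X must be a 2-D weight matrix")
        n_vox, n_comp = X.shape
        if n_vox < n_comp:
            raise InvalidArgumentError(
                f"need at least {n_comp} voxels, got {n_vox}")
        if np.linalg.matrix_rank(X) < n_comp:
            raise InvalidDesignError("layer-weight matrix is rank deficient")
        y2 = y if y.ndim == 2 else y[:, None]
        if y2.shape[0] != n_vox:
            raise InvalidArgumentError("Y and X must have the same number of voxels")
        beta, _, _, _ = np.linalg.lstsq(X, y2, rcond=None)
        resid = y2 - X @ beta
        dof = max(n_vox - n_comp, 1)
        sigma2 = (resid**2).sum(axis=0) / dof
        xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
        stderr = np.sqrt(np.outer(xtx_inv_diag, sigma2))
        if y.ndim == 1:
            beta, stderr, sigma2 = beta[:, 0], stderr[:, 0], sigma2[0]
        self.coef_ = beta
        self.stderr_ = stderr
        self.residual_sd_ = np.sqrt(sigma2)
        self.n_voxels_ = n_vox
        return self


def unmix_layers(y: np.ndarray, X: np.ndarray):
    """Unmix voxel betas into per-compartment betas; returns ``(B, stderr)``."""
    est = LayerUnmixer().fit(X, y)
    return est.coef_, est.stderr_


@dataclass(frozen=True)
class LayerProfile:
    """Per-subject laminar responses and their normalized counterparts.

    ``r`` is the raw (subjects, layers, conditions) array restricted to the 3
    cortical layers; ``s_fmri`` is r scaled per subject by r_bar / r_norm(s),
    where r_norm(s) is the subject's RMS over the 9 layer-condition cells and
    r_bar the group mean of r_norm.
    """

    r: np.ndarray
    r_norm: np.ndarray
    r_bar: float
    s_fmri: np.ndarray
    conditions: tuple
    layers: tuple = LAYERS

    def frame(self) -> pd.DataFrame:
        rows = []
        for s in range(self.r.shape[0]):
            for li, layer in enumerate(self.layers):
                for ci, theta in enumerate(self.conditions):
                    rows.append((s, layer, theta, self.r[s, li, ci],
                                 self.s_fmri[s, li, ci]))
        return pd.DataFrame(rows, columns=["subject", "layer", "condition",
                                           "r", "s_fmri"])


def normalize_responses(r: np.ndarray,
                        conditions=(90.0, 15.0, 0.0)) -> LayerProfile:
    """RMS-normalize laminar responses across subjects.

    ``r`` has shape (subjects, layers, conditions) with layers either the 3
    cortical layers or all 5 compartments ordered as WM, deep, middle,
    superficial, CSF (the cortical slice is extracted; normalization always
    uses the 3 x n_conditions cortical cells only).
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 3:
        raise InvalidArgumentError("r must be (subjects, layers, conditions)")
    if r.shape[1] == len(COMPARTMENTS):
        r = r[:, 1:4, :]
    elif r.shape[1] != len(LAYERS):
        raise InvalidArgumentError("layer axis must have length 3 or 5")
    r_norm = np.sqrt((r**2).mean(axis=(1, 2)))
    zero = np.where(r_norm == 0)[0]
    if zero.size:
        raise InvalidArgumentError(
            f"subject(s) {zero.tolist()} have all-zero responses")
    r_bar = float(r_norm.mean())
    s_fmri = r / r_norm[:, None, None] * r_bar
    return LayerProfile(r, r_norm, r_bar, s_fmri, tuple(conditions))


@dataclass(frozen=True)
class SaliencyContrasts:
    """Per-subject, per-layer condition contrasts of the normalized responses."""

    ss: np.ndarray            # S(90) - S(15)
    alt: np.ndarray           # S(90) - S(0)
    suppression: np.ndarray   # (S(90) + S(15)) / 2 - S(0)
    layers: tuple = LAYERS


def saliency_contrasts(profile: LayerProfile) -> SaliencyContrasts:
    """Saliency-sensitive response SS = S(90) - S(15) and companion contrasts."""
    cond = list(profile.conditions)
    try:
        i90, i15, i0 = cond.index(90.0), cond.index(15.0), cond.index(0.0)
    except ValueError as err:
        raise InvalidArgumentError(
            "all three conditions (90, 15, 0) must be present") from err
    s = profile.s_fmri
    ss = s[:, :, i90] - s[:, :, i15]
    alt = s[:, :, i90] - s[:, :, i0]
    suppression = (s[:, :, i90] + s[:, :, i15]) / 2.0 - s[:, :, i0]
    return SaliencyContrasts(ss, alt, suppression, profile.layers)


def snr_normalized_saliency(ss: np.ndarray, snr: np.ndarray) -> np.ndarray:
    """Divide per-layer saliency contrasts by per-layer SNR (tSNR or CNR)."""
    ss = np.asarray(ss, dtype=float)
    snr = np.asarray(snr, dtype=float)
    if (snr <= 0).any():
        raise InvalidArgumentError("SNR values must be strictly positive")
    return ss / snr
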