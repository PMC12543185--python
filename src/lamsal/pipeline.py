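"""End-to-end pipeline orchestration and reproduction from deposited tables.

``run_pipeline`` chains the package: simulate subjects (laminar phantoms,
paired VASO runs, behavioral staircases, coupled depth timeseries, pRF
tables, gaze traces) -> BOLD correction -> block GLM -> layer unmixing ->
normalized saliency statistics -> gPPI pathways -> visual-field maps ->
group inference, writing tidy CSVs and a JSON summary stamped with the
config hash and seed. Re-running an identical config reproduces identical
outputs.

``reproduce_deposited`` recomputes the group statistics of a selected
analysis from per-participant values in a deposited XLSX workbook.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import connectivity as conn
from . import io as lio
from . import laminar as lam
from . import retinotopy as ret
from . import stats as st
from . import synthetic as syn
from . import vaso
from .exceptions import InvalidArgumentError

__all__ = ["PipelineConfig", "run_pipeline", "reproduce_deposited"]

logger = logging.getLogger(__name__)

ROI_PROFILES = {"V1": "v1_like", "V2": "v2_like", "IPS": "ips_like"}
PEAK_LAYER = {"V1": "superficial", "V2": "superficial", "IPS": "middle"}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated, serializable configuration of one pipeline run."""

    seed: int = 0
    n_subjects: int = 20
    n_runs: int = 3
    n_voxels: int = 300
    n_blocks: int = 6
    effect_size: float = 1.0
    noise_sd: float = 0.5
    drift_amplitude: float = 0.5
    pv_concentration: float = 50.0
    cbv_gain: float = 1.0
    bold_gain: float = 2.0
    use_bold_for_gppi: bool = True
    snr_normalization: bool = False
    n_prf_nodes: int = 150
    gaze_duration_s: float = 30.0
    out_dir: str | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidArgumentError("n_subjects must be >= 1")
        if self.n_runs < 1 or self.n_voxels < 5:
            raise InvalidArgumentError("n_runs >= 1 and n_voxels >= 5 required")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _subject_seed(root: int, *indices: int) -> int:
    """Deterministic per-component seed below 2**31."""
    h = hashlib.sha256(("/".join(map(str, (root, *indices)))).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _laminar_responses(cfg: PipelineConfig, traits: np.ndarray) -> dict:
    """Simulate and analyze laminar responses; returns roi -> (S, 5, 3) r."""
    out = {}
    for ri, (roi, profile) in enumerate(ROI_PROFILES.items()):
        r = np.empty((cfg.n_subjects, 5, 3))
        for s in range(cfg.n_subjects):
            phantom = syn.generate_laminar_phantom(
                cfg.n_voxels, profile, cfg.effect_size * traits[s],
                cfg.pv_concentration, seed=_subject_seed(cfg.seed, 1, ri, s),
                noise_sd=cfg.noise_sd, drift_amplitude=cfg.drift_amplitude)
            betas = []
            for run_i in range(cfg.n_runs):
                tl = syn.generate_block_design(
                    n_blocks=cfg.n_blocks,
                    seed=_subject_seed(cfg.seed, 2, ri, s, run_i))
                run = syn.simulate_paired_vaso_run(
                    phantom, tl, cbv_gain=cfg.cbv_gain, bold_gain=cfg.bold_gain,
                    seed=_subject_seed(cfg.seed, 3, ri, s, run_i))
                ts = vaso.boco_correct(run)
                glm = vaso.fit_block_glm(ts, tl, resample_tr=tl.paired_tr)
                betas.append(glm.condition_betas(phantom.conditions))
            y = np.mean(betas, axis=0)
            B, _ = lam.unmix_layers(y, phantom.weights)
            r[s] = B
        out[roi] = r
    return out


def _behavior(cfg: PipelineConfig, traits: np.ndarray) -> pd.DataFrame:
    """Simulate the staircase protocol per subject and condition."""
    rows = []
    for s in range(cfg.n_subjects):
        # higher saliency trait -> lower 90-degree threshold (higher S90)
        alphas = {90.0: 0.05 / traits[s], 15.0: 0.10}
        sens = {}
        for theta, alpha in alphas.items():
            obs = bh.ObserverModel(alpha=alpha, beta=3.0)
            recs = bh.run_staircase_session(
                obs, seed=_subject_seed(cfg.seed, 4, s, int(theta)),
                condition=theta)
            sens[theta] = bh.fit_weibull(recs).sensitivity
        ss = bh.behavioral_saliency(sens[90.0], sens[15.0])
        rows.append({"subject": s, "s90": ss.s90, "s15": ss.s15,
                     "ss_behavior": ss.ss_behavior})
    return pd.DataFrame(rows)


def _connectivity(cfg: PipelineConfig, traits: np.ndarray):
    """Simulate coupled depth series and run the pathway gPPI per subject."""
    tl = syn.generate_block_design(n_blocks=cfg.n_blocks,
                                   seed=_subject_seed(cfg.seed, 5))
    tr = tl.paired_tr / 2.0
    n = int(tl.run_duration // tr)
    times = np.arange(n) * tr
    from .hrf import block_regressors
    stim_drive = block_regressors(tl, times).sum(axis=1)
    labels = tl.block_labels(times)
    results = []
    for s in range(cfg.n_subjects):
        rng = np.random.default_rng(_subject_seed(cfg.seed, 6, s))
        ff_coupling = {90.0: 0.8 * traits[s], 15.0: 0.3, 0.0: 0.3}
        fb_coupling = {90.0: 0.4, 15.0: 0.4, 0.0: 0.4}
        v1, ips = {}, {}
        for hemi in ("left", "right"):
            v1[hemi] = {d: stim_drive + rng.standard_normal(n)
                        for d in syn.LAYERS}
            ips[hemi] = {d: stim_drive + rng.standard_normal(n)
                         for d in syn.LAYERS}
            gain_ff = np.zeros(n)
            gain_fb = np.zeros(n)
            for theta in tl.conditions:
                gain_ff[labels == theta] = ff_coupling[theta]
                gain_fb[labels == theta] = fb_coupling[theta]
            ips[hemi]["middle"] = ips[hemi]["middle"] \
                + gain_ff * v1[hemi]["superficial"]
            v1[hemi]["deep"] = v1[hemi]["deep"] + gain_fb * ips[hemi]["deep"]
        results.append(conn.pathway_analysis(v1, ips, tl, tr))
    return results


def _retinotopy(cfg: PipelineConfig):
    """Synthetic depth-resolved back-projection of a superficial saliency peak."""
    grid = ret.GridSpec()
    depth_gain = dict(zip(syn.LAYERS, syn._PROFILES["v1_like"]))
    maps = []
    for s in range(cfg.n_subjects):
        rng = np.random.default_rng(_subject_seed(cfg.seed, 7, s))
        frames = []
        for hemi in ("left", "right"):
            nodes = syn.generate_prf_nodes(
                cfg.n_prf_nodes, hemi, Am=120.0, Em=4.0, sigma_slope=0.25,
                seed=_subject_seed(cfg.seed, 8, s, hemi == "right"))
            Ac, Ec = ret.correct_prf(nodes["A"].to_numpy(),
                                     nodes["E"].to_numpy(), 120.0, 4.0)
            nodes = nodes.assign(Ac=Ac, Ec=Ec)
            frames.append(nodes)
        nodes = pd.concat(frames, ignore_index=True)
        near = (np.abs(nodes["Ac"] - ret.FOREGROUND_ANGLE) < 12.0) \
            & (np.abs(nodes["Ec"] - ret.FOREGROUND_ECC) < 1.0)
        per_depth = []
        for depth in syn.LAYERS:
            nd = nodes.assign(depth=depth)
            resp = np.where(near,
                            depth_gain[depth] + rng.normal(0, 0.05, len(nd)),
                            0.0)
            per_depth.append((nd, np.clip(resp, 0, None)))
        all_nodes = pd.concat([nd for nd, _ in per_depth], ignore_index=True)
        all_resp = np.concatenate([r for _, r in per_depth])
        maps.append(ret.reconstruct_field_map(all_resp, all_nodes, grid))
    return ret.average_field_maps(maps)


def _gaze(cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    n_eye = min(cfg.n_subjects, 12)
    for s in range(n_eye):
        for theta in (90.0, 15.0, 0.0):
            trace = syn.simulate_gaze(
                cfg.gaze_duration_s, sigma_x=0.3, sigma_y=0.2, rho=0.1,
                blink_rate_hz=0.2,
                seed=_subject_seed(cfg.seed, 9, s, int(theta)))
            rows.append({"subject": s, "theta": theta,
                         "bcea": st.bcea(trace).area})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the full synthetic study; returns a result bundle.

    Stages run in order (simulate -> preprocess -> laminar -> connectivity ->
    retinotopy -> stats); a failure aborts with the stage name. When
    ``out_dir`` (or ``config.out_dir``) is set, tidy CSVs and a JSON summary
    are written there.
    """
    out_dir = Path(out_dir or config.out_dir) if (out_dir or config.out_dir) else None
    rng = np.random.default_rng(config.seed)
    traits = np.clip(rng.normal(1.0, 0.25, size=config.n_subjects), 0.4, None)
    bundle: dict = {"config": config.to_dict(), "config_hash": config.hash(),
                    "seed": config.seed}
    stage = "simulate+laminar"
    try:
        raw = _laminar_responses(config, traits)
        profiles = {roi: lam.normalize_responses(r) for roi, r in raw.items()}
        contrasts = {roi: lam.saliency_contrasts(p) for roi, p in profiles.items()}
        stage = "behavior"
        behav = _behavior(config, traits)
        stage = "connectivity"
        pathways = _connectivity(config, traits)
        stage = "retinotopy"
        fieldmap = _retinotopy(config)
        stage = "stats"
        layer_means = {roi: {layer: float(c.ss[:, li].mean())
                             for li, layer in enumerate(syn.LAYERS)}
                       for roi, c in contrasts.items()}
        anova = {}
        for roi, c in contrasts.items():
            tidy = pd.DataFrame({
                "subject": np.repeat(np.arange(config.n_subjects), 3),
                "depth": np.tile(syn.LAYERS, config.n_subjects),
                "ss": c.ss.ravel(),
            })
            anova[roi] = st.rm_anova(tidy, "ss", "depth", "subject")
        t_behav = st.paired_t(behav["s90"], behav["s15"])
        peak_ss = {roi: contrasts[roi].ss[:, syn.LAYERS.index(PEAK_LAYER[roi])]
                   for roi in ROI_PROFILES}
        fmri_mat = np.column_stack([peak_ss[r] for r in ROI_PROFILES])
        perm = st.permutation_fwe(behav["ss_behavior"].to_numpy(), fmri_mat,
                                  n_perm=2000, seed=_subject_seed(config.seed, 10))
        ff = np.array([p.feedforward.delta for p in pathways])
        fb = np.array([p.feedback.delta for p in pathways])
        t_paths = st.paired_t(ff, fb)
        if config.n_subjects >= 2:
            one_sample = [float(st.paired_t(x, np.zeros_like(x)).p)
                          for x in (ff, fb)]
            p_holm = st.holm_correct(one_sample)
        else:
            p_holm = [np.nan, np.nan]
        gaze = _gaze(config)
        gaze_anova = st.rm_anova(gaze, "bcea", "theta", "subject") \
            if gaze["subject"].nunique() >= 2 else None
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    bundle.update({
        "layer_ss_means": layer_means,
        "behavior": {"s90_mean": float(behav["s90"].mean()),
                     "s15_mean": float(behav["s15"].mean()),
                     "t": t_behav.t, "df": t_behav.df, "p": t_behav.p},
        "connectivity": {
            "feedforward_delta_mean": float(ff.mean()),
            "feedback_delta_mean": float(fb.mean()),
            "t_ff_vs_fb": t_paths.t, "p_ff_vs_fb": t_paths.p,
            "p_holm": list(map(float, p_holm)),
        },
        "correlation": {
            "rois": list(ROI_PROFILES),
            "r": perm.observed_r.tolist(),
            "p_fwe": perm.p_fwe.tolist(),
            "fwe_threshold": perm.fwe_threshold,
        },
        "fieldmap_peaks": {d: fieldmap.peak_location(d) for d in fieldmap.maps},
    })
    results = {"bundle": bundle, "profiles": profiles, "contrasts": contrasts,
               "behavior": behav, "pathways": pathways, "fieldmap": fieldmap,
               "anova": anova, "gaze": gaze, "gaze_anova": gaze_anova}
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        stamp = {"config_hash": config.hash(), "seed": config.seed}
        for roi, p in profiles.items():
            df = p.frame()
            for k, v in stamp.items():
                df[k] = v
            df.to_csv(out_dir / f"laminar_{roi}.csv", index=False)
        behav.assign(**stamp).to_csv(out_dir / "behavior.csv", index=False)
        pd.DataFrame({"subject": np.arange(config.n_subjects),
                      "feedforward_delta": ff, "feedback_delta": fb}) \
            .assign(**stamp).to_csv(out_dir / "connectivity.csv", index=False)
        gaze.assign(**stamp).to_csv(out_dir / "gaze_bcea.csv", index=False)
        (out_dir / "summary.json").write_text(json.dumps(bundle, indent=2))
    return results


# ---------------------------------------------------------------------------
# reproduction from deposited per-participant tables
# ---------------------------------------------------------------------------

def reproduce_deposited(xlsx_path, which: str, schema=None) -> pd.DataFrame:
    """Recompute group statistics from per-participant deposited values.

    ``which`` selects the analysis: ``behavior`` (group means and paired t of
    the 90- vs 15-degree sensitivities), ``laminar`` (rm-ANOVA of the
    saliency contrast across depths per ROI plus depth-pair t tests),
    ``connectivity`` (paired t of feedforward vs feedback deltas and per-
    pathway one-sample tests, Holm corrected), or ``bcea`` (one-way rm-ANOVA
    across orientation-contrast conditions). Returns a tidy statistics table.
    """
    df = lio.read_deposited_workbook(xlsx_path, which, schema)
    rows = []
    if which == "behavior":
        t = st.paired_t(df["s90"], df["s15"])
        ss = bh.behavioral_saliency(df["s90"].mean(), df["s15"].mean())
        rows += [
            ("behavior", "mean_S90", df["s90"].mean(), None, None),
            ("behavior", "mean_S15", df["s15"].mean(), None, None),
            ("behavior", "SS_behavior_of_means", ss.ss_behavior, None, None),
            ("behavior", "paired_t_90_vs_15", t.t, t.df, t.p),
        ]
    elif which == "laminar":
        df = df.assign(theta=df["theta"].astype(float))
        for roi, sub in df.groupby("roi"):
            wide = sub.pivot_table(index=["subject", "depth"], columns="theta",
                                   values="s_fmri").reset_index()
            wide["ss"] = wide[90.0] - wide[15.0]
            aov = st.rm_anova(wide, "ss", "depth", "subject")
            f = aov.iloc[0]
            rows.append((f"laminar_{roi}", "rm_anova_depth_F", f["F"],
                         (f["df1"], f["df2"]), f["p"]))
            depths = list(wide["depth"].unique())
            for i, d1 in enumerate(depths):
                for d2 in depths[i + 1:]:
                    a = wide.loc[wide["depth"] == d1].sort_values("subject")["ss"]
                    b = wide.loc[wide["depth"] == d2].sort_values("subject")["ss"]
                    t = st.paired_t(a.to_numpy(), b.to_numpy())
                    rows.append((f"laminar_{roi}", f"t_{d1}_vs_{d2}", t.t, t.df, t.p))
    elif which == "connectivity":
        wide = df.pivot_table(index="subject", columns="pathway",
                              values="delta")
        t = st.paired_t(wide["feedforward"], wide["feedback"])
        rows.append(("connectivity", "paired_t_ff_vs_fb", t.t, t.df, t.p))
        pvals = []
        for pw in ("feedforward", "feedback"):
            tt = st.paired_t(wide[pw].to_numpy(),
                             np.zeros(len(wide)))
            rows.append(("connectivity", f"one_sample_t_{pw}", tt.t, tt.df, tt.p))
            pvals.append(tt.p)
        for pw, padj in zip(("feedforward", "feedback"), st.holm_correct(pvals)):
            rows.append(("connectivity", f"p_holm_{pw}", padj, None, None))
    elif which == "bcea":
        aov = st.rm_anova(df, "bcea", "theta", "subject")
        f = aov.iloc[0]
        rows.append(("bcea", "rm_anova_theta_F", f["F"], (f["df1"], f["df2"]),
                     f["p"]))
    return pd.DataFrame(rows, columns=["analysis", "statistic", "value", "df", "p"])
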