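"""End-to-end orchestration of the analysis chain on a synthetic study.

``run_pipeline`` executes, per subject: simulation -> EDF round trip ->
preprocessing (filter, reject, re-reference, mechanical trial bounds) ->
mixture ICA -> trial model-fit classification; then across subjects:
dipole fitting and clustering, per-cluster masked spectrograms with ERD
statistics, and 4-way decoding with grand-average confusion matrices.
Every stage persists its artifacts under the output directory and the
whole run is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate as sim
from .config import PipelineConfig
from .decode import aggregate_confusion, crossvalidate, reduce_resolution
from .headmodel import SphereModel
from .io import read_recording, write_recording
from .mixture_ica import (MixtureICA, anova_model_probabilities,
                          classify_trials_by_model)
from .preprocess import preprocess_recording
from .source_space import cluster_components, make_component_records
from .spectro import (bootstrap_mask, compare_effort_ttest, erd_statistic,
                      log_freq_grid, trial_spectrogram)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sphere(config: PipelineConfig) -> SphereModel:
    return SphereModel(radius=config.head_radius_mm,
                       conductivity=config.conductivity,
                       brain_radius_fraction=config.brain_radius_fraction)


def _seed_for(config: PipelineConfig, *tags) -> int:
    ss = np.random.SeedSequence([config.seed] + [abs(hash(t)) % (2 ** 31) for t in tags])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# --- stages ---------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out: Path) -> dict:
    sphere = _sphere(config)
    sim_dir = out / "sim"
    sim_dir.mkdir(parents=True, exist_ok=True)
    subjects = {}
    for i in range(config.n_subjects):
        sid = f"S{i:02d}"
        rec, events, sources, gt = sim.simulate_subject(
            subject_id=sid, seed=_seed_for(config, "sim", sid),
            reps=config.reps, n_channels=config.n_channels, sphere=sphere,
            fs=config.fs, fs_aux=config.fs_aux,
            sensor_noise_uv=config.sensor_noise_uv,
            line_amp_uv=config.line_amp_uv, drift_step_uv=config.drift_step_uv,
        )
        write_recording(rec, events, sim_dir / sid)
        truth = {
            "sources": [{"name": s.name, "role": s.role,
                         "location": list(np.round(s.location, 3))}
                        for s in gt.source_specs],
            "n_trials": int(len(events)),
        }
        (sim_dir / f"{sid}.truth.json").write_text(json.dumps(truth, indent=1))
        subjects[sid] = {"ground_truth": gt, "sources": sources}
        logger.info("simulated %s: %d trials, %.1f s", sid, len(events), rec.duration)
    return subjects


def stage_preprocess(config: PipelineConfig, out: Path, subjects: dict) -> None:
    pre_dir = out / "preprocess"
    pre_dir.mkdir(parents=True, exist_ok=True)
    for sid, st in subjects.items():
        rec, events = read_recording(out / "sim" / sid)
        rec, events, report = preprocess_recording(
            rec, events, cutoff=config.highpass_hz,
            std_limit_uv=config.std_limit_uv, kurtosis_sd=config.kurtosis_sd,
            corr_threshold=config.corr_threshold,
            corr_window_s=config.corr_window_s,
            corr_max_fraction=config.corr_max_fraction,
        )
        report.to_frame().to_csv(pre_dir / f"{sid}.rejection.tsv", sep="\t", index=False)
        events.to_csv(pre_dir / f"{sid}.events_refined.tsv", sep="\t", index=False)
        st["recording"], st["events"], st["report"] = rec, events, report
        logger.info("preprocessed %s: %d/%d channels kept", sid,
                    report.retained, config.n_channels)


def stage_ica(config: PipelineConfig, out: Path, subjects: dict) -> dict:
    ica_dir = out / "ica"
    ica_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    knee_probs, ankle_probs = [], []
    for sid, st in subjects.items():
        rec, events = st["recording"], st["events"]
        # fit on concatenated trial samples: the pauses would otherwise offer
        # the mixture a competing trial-vs-rest split to specialise on
        from .io import trial_sample_mask
        X = rec.eeg[:, trial_sample_mask(events, rec.n_samples)].T
        stride = max(X.shape[0] // config.ica_fit_samples, 1)
        mix = MixtureICA(n_models=config.n_models,
                         n_components=min(config.n_components, rec.n_channels),
                         max_iter=config.ica_max_iter, tol=config.ica_tol,
                         random_state=_seed_for(config, "ica", sid))
        mix.fit(X[::stride])
        st["mixica"] = mix
        from .mixture_ica import save_mixture
        save_mixture(mix, ica_dir / f"{sid}.mixture")
        result = classify_trials_by_model(mix, rec.eeg, rec.fs_eeg, events)
        st["trial_classification"] = result
        for subset, bucket in (("knee", knee_probs), ("ankle", ankle_probs)):
            sel = events["joint"] == subset
            seg = np.concatenate([rec.eeg[:, ev.onset_sample:ev.offset_sample]
                                  for ev in events[sel].itertuples(index=False)], axis=1)
            p = mix.model_probability(seg.T)
            model_for = [m for m, j in result["mapping"].items() if j == "knee"][0]
            bucket.append(p[model_for])
        rows.append({"subject": sid, "accuracy": result["accuracy"],
                     "accuracy_isometric": result.get("accuracy_isometric", np.nan),
                     "accuracy_isotonic": result.get("accuracy_isotonic", np.nan),
                     "n_iter": mix.n_iter_, "loglik": mix.loglik_trace_[-1]})
        logger.info("ICA %s: joint accuracy %.3f", sid, result["accuracy"])
    F, p = anova_model_probabilities([knee_probs, ankle_probs])
    summary = pd.DataFrame(rows)
    summary.to_csv(ica_dir / "trial_classification.tsv", sep="\t", index=False)
    (ica_dir / "model_probability_anova.json").write_text(
        json.dumps({"F": F, "p": p,
                    "knee_model_prob_on_knee_data": list(map(float, knee_probs)),
                    "knee_model_prob_on_ankle_data": list(map(float, ankle_probs))},
                   indent=1))
    return {"trial_accuracy_mean": float(summary["accuracy"].mean()),
            "anova_F": F, "anova_p": p}


def stage_localize(config: PipelineConfig, out: Path, subjects: dict) -> dict:
    loc_dir = out / "localize"
    loc_dir.mkdir(parents=True, exist_ok=True)
    sphere = _sphere(config)
    records = []
    for sid, st in subjects.items():
        rec = st["recording"]
        mix = st["mixica"]
        stride = max(rec.n_samples // 50_000, 1)
        acts = np.stack([mix.transform(rec.eeg[:, ::stride].T, model=h).T
                         for h in range(config.n_models)])
        recs = make_component_records(mix, sid, rec.electrode_positions,
                                      activations=acts, fs=rec.fs_eeg / stride,
                                      sphere=sphere)
        records.extend(recs)
        st["component_records"] = recs
    tab = pd.DataFrame([{
        "subject": r.subject_id, "model": r.model_id, "component": r.component_index,
        "x": r.dipole.location[0], "y": r.dipole.location[1], "z": r.dipole.location[2],
        "qx": r.dipole.moment[0], "qy": r.dipole.moment[1], "qz": r.dipole.moment[2],
        "rv": r.dipole.residual_variance, "label": r.label,
    } for r in records])
    tab.to_csv(loc_dir / "dipoles.tsv", sep="\t", index=False)

    cortical = [r for r in records if r.label == "cortical"]
    k = min(config.cluster_k, max(len(cortical) // 2, 2))
    clusters = cluster_components(cortical, k=k,
                                  seed=_seed_for(config, "cluster"),
                                  location_weight=config.cluster_location_weight,
                                  sphere=sphere)
    cl_tab = pd.DataFrame([{
        "cluster": i, "x": c.centroid[0], "y": c.centroid[1], "z": c.centroid[2],
        "n_members": len(c.members), "n_subjects": c.subject_count,
        "retained": c.retained,
    } for i, c in enumerate(clusters)])
    cl_tab.to_csv(loc_dir / "clusters.tsv", sep="\t", index=False)
    retained = [c for c in clusters if c.retained]
    logger.info("clustering: %d clusters, %d retained", len(clusters), len(retained))
    return {"clusters": clusters, "n_retained": len(retained),
            "n_cortical": len(cortical)}


def _cluster_activation(st: dict, cluster) -> np.ndarray | None:
    """Best member activation (lowest dipole RV) for one subject, or None."""
    members = [m for m in cluster.members
               if m.subject_id == st["recording"].subject_id]
    if not members:
        return None
    best = min(members, key=lambda m: m.dipole.residual_variance)
    mix = st["mixica"]
    act = mix.transform(st["recording"].eeg.T, model=best.model_id)
    return act[:, best.component_index]


def _label_clusters(clusters) -> dict:
    """Geometric roles on the synthetic head: medial premotor vs visual."""
    retained = [c for c in clusters if c.retained] or list(clusters)
    sma = min(retained, key=lambda c: np.linalg.norm(c.centroid - np.array([0.0, -10.0, 60.0])))
    visual = min(retained, key=lambda c: c.centroid[1])
    return {"sma": sma, "visual": visual if visual is not sma else None}


def _trial_spectrograms(config, activation, fs, events, freqs, target):
    specs = []
    kept = []
    for i, ev in enumerate(events.itertuples(index=False)):
        try:
            s = trial_spectrogram(activation, fs, ev.onset_sample / fs,
                                  ev.offset_sample / fs, target, freqs=freqs,
                                  pre=config.pre_s, post=config.post_s,
                                  baseline=tuple(config.baseline_s),
                                  window=config.window_s, step=config.step_s,
                                  dtype=np.float32)
        except ValueError:
            continue
        specs.append(s)
        kept.append(i)
    return specs, np.asarray(kept, dtype=int)


def stage_spectro(config: PipelineConfig, out: Path, subjects: dict,
                  clusters: list) -> dict:
    sp_dir = out / "spectro"
    sp_dir.mkdir(parents=True, exist_ok=True)
    freqs = log_freq_grid(config.n_freq_bins, config.fmin_hz, config.fmax_hz)
    labels_map = _label_clusters(clusters)
    sma = labels_map["sma"]

    all_durations = np.concatenate([
        (st["events"]["offset_sample"] - st["events"]["onset_sample"]).to_numpy()
        / st["recording"].fs_eeg for st in subjects.values()])
    target = float(np.median(all_durations))

    erd_rows = []
    per_subject_erd = {"isometric": {"high": [], "low": []},
                       "isotonic": {"high": [], "low": []}}
    for sid, st in subjects.items():
        act = _cluster_activation(st, sma)
        if act is None:
            continue
        rec, events = st["recording"], st["events"]
        specs, kept = _trial_spectrograms(config, act, rec.fs_eeg, events,
                                          freqs, target)
        if not specs:
            continue
        ev_kept = events.iloc[kept].reset_index(drop=True)
        arr = np.stack([s.values for s in specs])
        times = specs[0].times
        from .spectro import null_pool_columns
        base_cols = null_pool_columns(times, baseline=tuple(config.baseline_s),
                                      window=config.window_s)
        st["sma_trial_specs"] = (arr, times, ev_kept)
        for mode in ("isometric", "isotonic"):
            for effort in ("high", "low"):
                sel = ((ev_kept["mode"] == mode)
                       & (ev_kept["effort"] == effort)).to_numpy()
                if sel.sum() < 3:
                    continue
                res = bootstrap_mask(arr[sel], base_cols, alpha=config.alpha,
                                     n_boot=config.n_boot,
                                     seed=_seed_for(config, "boot", sid, mode, effort))
                for band in ("alpha", "beta"):
                    stat = erd_statistic(res.grand, res.mask, times, freqs,
                                         band, (0.0, target))
                    erd_rows.append({"subject": sid, "mode": mode,
                                     "effort": effort, "band": band,
                                     "erd_db": stat.mean_db,
                                     "n_points": stat.n_points})
                both = [erd_statistic(res.grand, res.mask, times, freqs, b,
                                      (0.0, target)).mean_db
                        for b in ("alpha", "beta")]
                per_subject_erd[mode][effort].append(np.nanmean(both))

    pd.DataFrame(erd_rows).to_csv(sp_dir / "erd_stats.tsv", sep="\t", index=False)
    ttests = {}
    for mode in ("isometric", "isotonic"):
        hi, lo = per_subject_erd[mode]["high"], per_subject_erd[mode]["low"]
        n = min(len(hi), len(lo))
        if n >= 2:
            t, p = compare_effort_ttest(np.array(hi[:n]), np.array(lo[:n]))
            ttests[mode] = {"t": t, "p": p, "n": n}
    (sp_dir / "effort_ttests.json").write_text(json.dumps(ttests, indent=1))
    return {"target_duration": target, "effort_ttests": ttests}


def stage_decode(config: PipelineConfig, out: Path, subjects: dict,
                 clusters: list, target: float) -> dict:
    dec_dir = out / "decode"
    dec_dir.mkdir(parents=True, exist_ok=True)
    freqs = log_freq_grid(config.n_freq_bins, config.fmin_hz, config.fmax_hz)
    labels_map = _label_clusters(clusters)
    sma, visual = labels_map["sma"], labels_map["visual"]
    retained = [c for c in clusters if c.retained] or list(clusters)
    use_all = [c for c in retained
               if not (config.exclude_visual and c is visual)]

    grand = {"sma": [], "all": []}
    accs = {"sma": [], "all": []}
    for sid, st in subjects.items():
        rec, events = st["recording"], st["events"]
        per_cluster = []
        spec_times = None
        for c in use_all:
            act = _cluster_activation(st, c)
            if act is None:
                continue
            specs, kept = _trial_spectrograms(config, act, rec.fs_eeg, events,
                                              freqs, target)
            if not specs:
                continue
            arr = np.stack([s.values for s in specs])
            spec_times = specs[0].times
            red = reduce_resolution(arr, config.reduction_factor)
            per_cluster.append((c, kept, red))
        if not per_cluster:
            continue
        kept_common = per_cluster[0][1]
        for _, kept, _ in per_cluster[1:]:
            kept_common = np.intersect1d(kept_common, kept)
        aligned = []
        for c, kept, red in per_cluster:
            idx = np.searchsorted(kept, kept_common)
            aligned.append((c, red[idx]))
        ev_kept = events.iloc[kept_common].reset_index(drop=True)
        y = (ev_kept["mode"] + "_" + ev_kept["effort"]).to_numpy()
        from .spectro import null_pool_columns
        pool = null_pool_columns(spec_times, baseline=tuple(config.baseline_s),
                                 window=config.window_s)
        base_cols = np.unique(pool // config.reduction_factor)
        k = min(config.cv_folds,
                int(pd.Series(y).value_counts().min()))
        if k < 2:
            continue
        for key, cl_set in (("sma", [a for a in aligned if a[0] is sma]),
                            ("all", aligned)):
            if not cl_set:
                continue
            folds = crossvalidate([a[1] for a in cl_set], y, base_cols, k=k,
                                  seed=_seed_for(config, "cv", sid, key),
                                  alpha=config.alpha, n_boot=config.n_boot,
                                  paper_mode=config.paper_mode)
            cm = aggregate_confusion(folds)
            grand[key].append(cm)
            accs[key].append(cm.accuracy)
        logger.info("decode %s: sma %.3f all %.3f", sid,
                    accs["sma"][-1] if accs["sma"] else np.nan,
                    accs["all"][-1] if accs["all"] else np.nan)

    results = {}
    for key in ("sma", "all"):
        if not grand[key]:
            continue
        cm = aggregate_confusion(grand[key])
        tab = pd.DataFrame(cm.normalized, index=cm.classes, columns=cm.classes)
        tab.to_csv(dec_dir / f"confusion_{key}.tsv", sep="\t")
        results[f"accuracy_{key}"] = float(np.mean(accs[key]))
        results[f"accuracy_{key}_sd"] = float(np.std(accs[key]))
    (dec_dir / "summary.json").write_text(json.dumps(results, indent=1))
    return results


# --- driver ---------------------------------------------------------------

_STAGE_ORDER = ["simulate", "preprocess", "ica", "localize", "spectro", "decode"]


def run_pipeline(config: PipelineConfig, out_dir, stages=None) -> dict:
    """Run the pipeline end to end; returns the summary results dict.

    ``stages`` restricts execution to a prefix of
    simulate/preprocess/ica/localize/spectro/decode (earlier stages always
    run, since later ones consume their in-memory state).  Any stage
    failure raises :class:`PipelineError` naming the stage; artifacts of
    completed stages remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    wanted = _STAGE_ORDER if stages is None else _STAGE_ORDER[
        : max(_STAGE_ORDER.index(s) for s in stages) + 1]
    results: dict = {"config": config.to_dict()}
    subjects: dict = {}
    try:
        stage = "simulate"
        subjects = stage_simulate(config, out)
        if "preprocess" in wanted:
            stage = "preprocess"
            stage_preprocess(config, out, subjects)
        if "ica" in wanted:
            stage = "ica"
            results["ica"] = stage_ica(config, out, subjects)
        if "localize" in wanted:
            stage = "localize"
            loc = stage_localize(config, out, subjects)
            results["localize"] = {"n_retained": loc["n_retained"],
                                   "n_cortical": loc["n_cortical"]}
        if "spectro" in wanted:
            stage = "spectro"
            sp = stage_spectro(config, out, subjects, loc["clusters"])
            results["spectro"] = {k: v for k, v in sp.items()}
        if "decode" in wanted:
            stage = "decode"
            results["decode"] = stage_decode(config, out, subjects,
                                             loc["clusters"], sp["target_duration"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    (out / "results.json").write_text(json.dumps(results, indent=1, default=str))
    return results
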