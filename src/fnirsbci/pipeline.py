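"""End-to-end orchestration: simulate -> convert -> preprocess ->
featurize -> classify -> stats -> report, as one reproducible run.

A run is driven by a :class:`PipelineConfig` (loadable from YAML) in
which every acquisition and analysis constant — 8.138 Hz sampling,
780/850 nm, 3 cm separation, the 0.01-0.1 Hz 4th-order band-pass,
the -1..0 s baseline and 0..60 s analysis window, k = 10 folds and
C = 1.0 — is a named default rather than a hard-coded value.  The
:class:`RunManifest` records the config snapshot, seeds, per-stage
outputs and input hashes; re-running with the same config and seed
reproduces identical result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import crossvalidate
from .features import concat_features, extract_features
from .hemodynamics import mbll_invert
from .io import write_purchases, write_questionnaire, write_recording
from .montage import default_layout
from .preprocessing import bandpass, channel_means, collect_channel_means, epoch
from .stats import (ancova_gender, asymmetry_index, channel_contrast,
                    cronbach_alpha, grand_average_trace, purchase_tests,
                    roi_anova, summary_anova, topographic_map)
from .synthetic import (DEFAULT_PURCHASE_SUMS, DEFAULT_QUESTIONNAIRE_PARAMS,
                        SimulationConfig, simulate_cohort,
                        simulate_purchases, simulate_questionnaire)

log = logging.getLogger("fnirsbci")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "cohort_analysis"]


def cohort_analysis(sim: SimulationConfig, sessions: tuple[int, ...] = (1, 2),
                    k: int = 10, seed: int | None = None,
                    classify: bool = True) -> dict:
    """Run the analysis chain in memory on one synthetic cohort.

    Simulates every subject-session, inverts the optical density,
    band-pass filters, epochs, and returns the channel-means table,
    pooled feature matrix, ground truth, and (optionally) the
    cross-validation result.
    """
    from .synthetic import simulate_recording

    seed = sim.seed if seed is None else seed
    epochsets = []
    for subject in range(sim.n_subjects):
        for session in sessions:
            rec = simulate_recording(sim, subject, session)
            h = mbll_invert(rec, sim.extinction, sim.dpf, sim.distance_cm)
            epochsets.append(epoch(bandpass(h)))
    means = collect_channel_means([channel_means(e) for e in epochsets])
    fm = concat_features([extract_features(e) for e in epochsets])
    out = {"epochsets": epochsets, "channel_means": means, "features": fm}
    if classify:
        out["cv"] = crossvalidate(fm, k=k, seed=seed)
    return out


@dataclass
class PipelineConfig:
    """Per-stage settings; see docs/methods.md for parameter meanings."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    recording_format: str = "csv"          # "csv" | "snirf"
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    filter_order: int = 4
    attenuation_db: float = 40.0
    zero_phase: bool = True
    filter_method: str = "cheby2"
    epoch_pre_s: float = 1.0
    epoch_post_s: float = 60.0
    cv_folds: int = 10
    svm_C: float = 1.0
    pooled_scaling: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        sim = SimulationConfig(**sim_raw) if sim_raw else SimulationConfig()
        cfg = cls(simulation=sim, **raw)
        cfg.simulation.seed = cfg.seed
        return cfg

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["amplitude_map"] = {
            k: list(map(float, v))
            for k, v in self.simulation.amplitude_map.items()}
        return d


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stage_outputs: dict[str, list[str]] = field(default_factory=dict)
    input_hashes: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         default=str))
        return Path(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _timed(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2f s", name, dt)
            else:
                log.error("stage %s: failed after %.2f s: %s", name, dt, exc)
            return False
    return _Timer()


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 make_figures: bool = True) -> RunManifest:
    """Run every stage on a synthetic cohort and write all outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.simulation.seed = config.seed
    manifest = RunManifest(config=config.snapshot(), seed=config.seed,
                           version=__version__)
    layout = default_layout()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    try:
        with _timed("simulate"):
            recs, truth = simulate_cohort(config.simulation)
            rec_dir = out / "recordings"
            rec_dir.mkdir(exist_ok=True)
            suffix = ".snirf" if config.recording_format == "snirf" else ".csv"
            paths = []
            for rec in recs:
                p = rec_dir / f"{rec.subject_id}_ses{rec.session}{suffix}"
                write_recording(rec, p, config.recording_format)
                paths.append(str(p))
            truth.to_json(out / "ground_truth.json")
            n_subj = config.simulation.n_subjects
            q_frames, q_reports = [], {}
            for construct, params in DEFAULT_QUESTIONNAIRE_PARAMS.items():
                scaled = {cond: (m, sd, n_subj) for cond, (m, sd, _) in params.items()}
                qdf, rep = simulate_questionnaire(rng, construct, scaled)
                q_frames.append(qdf)
                q_reports[construct] = rep
            questionnaire = pd.concat(q_frames, ignore_index=True)
            write_questionnaire(questionnaire, out / "questionnaire.csv")
            # category sums are per-30-subject totals; scale to cohort size
            sums = {s: {cat: (total * n_subj / 30.0, sd)
                        for cat, (total, sd) in cats.items()}
                    for s, cats in DEFAULT_PURCHASE_SUMS.items()}
            purchases = simulate_purchases(rng, sums, n_subj)
            write_purchases(purchases, out / "purchases.csv")
            manifest.stage_outputs["simulate"] = paths + [
                str(out / "ground_truth.json"), str(out / "questionnaire.csv"),
                str(out / "purchases.csv")]
            manifest.input_hashes = {p: _sha256(Path(p)) for p in paths[:4]}

        with _timed("convert"):
            hemos = [mbll_invert(rec, config.simulation.extinction,
                                 config.simulation.dpf,
                                 config.simulation.distance_cm)
                     for rec in recs]
            manifest.stage_outputs["convert"] = [f"{len(hemos)} series (in memory)"]

        with _timed("preprocess"):
            filtered = [bandpass(h, config.band_low_hz, config.band_high_hz,
                                 config.filter_order, config.attenuation_db,
                                 config.zero_phase, config.filter_method)
                        for h in hemos]
            epochsets = [epoch(h, config.epoch_pre_s, config.epoch_post_s)
                         for h in filtered]
            means = collect_channel_means([channel_means(e) for e in epochsets])
            means.to_csv(out / "channel_means.csv", index=False)
            manifest.stage_outputs["preprocess"] = [str(out / "channel_means.csv")]

        with _timed("featurize"):
            fm = concat_features([extract_features(e) for e in epochsets])
            fm.to_csv(out / "features.csv")
            manifest.stage_outputs["featurize"] = [str(out / "features.csv")]

        with _timed("classify"):
            cv = crossvalidate(fm, k=config.cv_folds, seed=config.seed,
                               C=config.svm_C,
                               pooled_scaling=config.pooled_scaling)
            cv.folds.to_csv(out / "cv_folds.csv", index=False)
            (out / "cv_summary.json").write_text(
                json.dumps(cv.summary(), indent=1))
            manifest.stage_outputs["classify"] = [
                str(out / "cv_folds.csv"), str(out / "cv_summary.json")]

        with _timed("stats"):
            contrast = channel_contrast(means)
            contrast.to_csv(out / "channel_contrast.csv", index=False)
            stats_json: dict = {"roi_anova": {}}
            for s in (1, 2):
                res = roi_anova(means, layout, session=s)
                res["posthoc"] = res["posthoc"].to_dict(orient="records")
                stats_json["roi_anova"][str(s)] = res
            ib = DEFAULT_QUESTIONNAIRE_PARAMS["impulse_buying"]
            (m1, sd1, n1), (m2, sd2, n2) = ib["session1"], ib["session2"]
            stats_json["impulse_anova"] = summary_anova(m1, sd1, n1, m2, sd2, n2)
            q_ib = questionnaire[questionnaire["construct"] == "impulse_buying"]
            scores = (q_ib.groupby(["respondent_id", "condition", "gender"])
                      ["score"].mean().reset_index()
                      .rename(columns={"condition": "session"}))
            anc = ancova_gender(scores)
            stats_json["ancova_gender"] = {
                k: v for k, v in anc.items() if k != "model"}
            stats_json["reliability"] = {
                c: dataclasses.asdict(cronbach_alpha(questionnaire, c))
                for c in questionnaire["construct"].unique()}
            stats_json["questionnaire_calibration"] = q_reports
            ptests = purchase_tests(purchases)
            ptests.to_csv(out / "purchase_tests.csv", index=False)
            asym = asymmetry_index(means, layout)
            asym.to_csv(out / "asymmetry.csv", index=False)
            topo = topographic_map(means, layout)
            stats_json["topography"] = {
                str(s): list(map(float, v)) for s, v in topo.normalized.items()}
            trace = grand_average_trace(epochsets)
            stats_json["grand_trace_contrast"] = trace.get("contrast", {})
            (out / "stats.json").write_text(
                json.dumps(stats_json, indent=1, default=float))
            manifest.stage_outputs["stats"] = [
                str(out / "channel_contrast.csv"), str(out / "stats.json"),
                str(out / "purchase_tests.csv"), str(out / "asymmetry.csv")]

        with _timed("report"):
            outputs = []
            if make_figures:
                outputs = _figures(out, contrast, trace, topo, cv)
            manifest.stage_outputs["report"] = outputs
    except Exception as exc:
        raise RuntimeError(f"pipeline aborted: {exc}") from exc

    manifest.to_json(out / "manifest.json")
    return manifest


def _figures(out: Path, contrast: pd.DataFrame, trace: dict, topo,
             cv) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []

    fig, ax = plt.subplots(figsize=(9, 4))
    x = np.arange(len(contrast))
    w = 0.38
    ax.bar(x - w / 2, contrast["mean_s1"], w, yerr=contrast["sem_s1"],
           label="session 1 (impulse)", color="tab:blue")
    ax.bar(x + w / 2, contrast["mean_s2"], w, yerr=contrast["sem_s2"],
           label="session 2 (control)", color="tab:red")
    ymax = (contrast[["mean_s1", "mean_s2"]].abs().to_numpy().max())
    for i, row in contrast.iterrows():
        if row["stars"]:
            ax.text(i, ymax * 1.05, row["stars"], ha="center", fontsize=8)
    ax.set_xticks(x, contrast["channel"])
    ax.set_xlabel("channel")
    ax.set_ylabel("mean dHbO (uM)")
    ax.legend()
    fig.tight_layout()
    p = out / "channel_bars.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(str(p))

    fig, ax = plt.subplots(figsize=(7, 4))
    colors = {1: "tab:red", 2: "tab:blue"}
    for s, m in trace["mean"].items():
        sd = trace["sd"][s]
        ax.plot(trace["times"], m, color=colors.get(s, "k"),
                label=f"session {s}")
        ax.fill_between(trace["times"], m - sd, m + sd,
                        color=colors.get(s, "k"), alpha=0.2)
    ax.set_xlabel("time relative to task onset (s)")
    ax.set_ylabel("dHbO (uM)")
    ax.legend()
    fig.tight_layout()
    p = out / "grand_average.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(str(p))

    fig, axes = plt.subplots(1, len(topo.grids), figsize=(9, 4))
    for ax, (s, grid) in zip(np.atleast_1d(axes), sorted(topo.grids.items())):
        im = ax.imshow(grid, origin="lower", cmap="RdBu_r", vmin=-1, vmax=1,
                       extent=[topo.grid_x[0], topo.grid_x[-1],
                               topo.grid_y[0], topo.grid_y[-1]])
        for ch, (cx, cy) in topo.channel_positions.items():
            ax.plot(cx, cy, "ko", ms=3)
            ax.annotate(str(ch), (cx, cy), fontsize=6,
                        textcoords="offset points", xytext=(3, 3))
        ax.set_title(f"session {s}")
        fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    p = out / "topomaps.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(str(p))

    fig, ax = plt.subplots(figsize=(9, 4))
    means = cv.subject_means
    ax.bar(np.arange(len(means)), means.to_numpy(), color="tab:gray")
    ax.bar([len(means)], [cv.grand_mean], color="tab:green")
    ax.set_xticks(list(range(len(means))) + [len(means)],
                  list(means.index) + ["A"], rotation=90, fontsize=7)
    ax.set_ylim(0, 1.05)
    ax.set_ylabel("accuracy")
    ax.axhline(0.5, color="k", ls=":")
    fig.tight_layout()
    p = out / "accuracies.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(str(p))
    return paths
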