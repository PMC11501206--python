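"""End-to-end phenotyping runs on a synthetic cohort.

``run_phenotype`` simulates a cohort with genotype × sex structure
(simulate → detect → SE/PID metrics → diary metrics → histology → group
statistics), writes per-subject metric tables, group statistics and a
raster figure to a run directory, and stamps every run with a provenance
block (package version, seed, parameter hash).  Each stage failure is
re-raised with a stage tag and a FAILED marker is flushed to the run
directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detect import DetectorParams, baseline_stats, detect_seizures
from .diary import find_clusters, raster, summarize
from .episode import count_seizures_2hr, latency_to_first_seizure, pid_score, se_bounds
from .histo import count_particles
from .stats import anova2_tukey, fisher_exact
from .synth import (SynthConfig, gen_background, gen_diary, gen_histo_image,
                    gen_se, inject_seizure, inject_suppression)

log = logging.getLogger("epiphen")

GROUPS = [("Cre-", "F"), ("Cre-", "M"), ("Cre+", "F"), ("Cre+", "M")]


@dataclass
class RunConfig:
    """Configuration of a full synthetic phenotyping run.

    The cohort emulates the study's contrasts: control females have more
    cluster days and more postictal depression than the other groups.
    """

    out_dir: str = "runs/demo"
    seed: int = 0
    n_per_group: int = 2
    se_onset_s: float = 300.0
    se_continuous_min: dict = field(default_factory=lambda: {
        "Cre-": 9.0, "Cre+": 7.0})
    se_post_s: float = 900.0
    n_days: int = 21
    base_rate: dict = field(default_factory=lambda: {
        ("Cre-", "F"): 0.6, ("Cre-", "M"): 0.3,
        ("Cre+", "F"): 0.3, ("Cre+", "M"): 0.3})
    n_clusters: dict = field(default_factory=lambda: {
        ("Cre-", "F"): 2, ("Cre-", "M"): 1,
        ("Cre+", "F"): 1, ("Cre+", "M"): 1})
    cluster_rate: float = 10.0
    pid_scale: dict = field(default_factory=lambda: {
        ("Cre-", "F"): 0.3, ("Cre-", "M"): 0.8,
        ("Cre+", "F"): 0.6, ("Cre+", "M"): 0.8})
    dcx_area_um2: dict = field(default_factory=lambda: {
        "Cre-": [12.0] * 15, "Cre+": [12.0] * 30})

    def param_hash(self) -> str:
        blob = json.dumps({k: sorted(str(i) for i in v.items())
                           if isinstance(v, dict) else v
                           for k, v in self.__dict__.items()},
                          sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"[stage:{name}] {exc}") from exc
        return wrapped
    return deco


@_stage("se_day")
def _se_day_metrics(genotype: str, sex: str, cfg: RunConfig, seed: int) -> dict:
    base_cfg = SynthConfig(seed=seed)
    rec, manifest = gen_se(
        base_cfg, onset_s=cfg.se_onset_s,
        continuous_s=60.0 * cfg.se_continuous_min[genotype],
        post_s=cfg.se_post_s)
    base = baseline_stats(rec, (0.0, cfg.se_onset_s - 60.0))
    events = detect_seizures(rec, base, DetectorParams())
    episode = se_bounds(rec, events, base)
    return {
        "latency_min": latency_to_first_seizure(events, rec),
        "n_seizures_2hr": count_seizures_2hr(events, rec),
        "se_duration_min": episode.duration_min if episode else np.nan,
        "se_resolved": bool(episode.resolved) if episode else False,
    }


@_stage("pid")
def _pid_metrics(genotype: str, sex: str, cfg: RunConfig, seed: int) -> dict:
    scale = cfg.pid_scale[(genotype, sex)]
    scfg = SynthConfig(duration_s=420.0, seed=seed)
    rec, manifest = gen_background(scfg)
    inject_seizure(rec, manifest, onset_s=120.0, duration_s=30.0)
    inject_suppression(rec, manifest, onset_s=150.5, duration_s=60.0,
                       scale=scale)
    base = baseline_stats(rec, (0.0, 60.0))
    events = detect_seizures(rec, base)
    if not events:
        return {"pid_fraction": np.nan, "n_scored": 0}
    results = [pid_score(rec, ev, events) for ev in events]
    scored = [r for r in results if r.scorable]
    frac = (sum(r.pid for r in scored) / len(scored)) if scored else np.nan
    return {"pid_fraction": frac, "n_scored": len(scored)}


@_stage("diary")
def _diary_metrics(genotype: str, sex: str, cfg: RunConfig, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    specs = []
    day = int(rng.integers(2, 5))
    for _ in range(cfg.n_clusters[(genotype, sex)]):
        specs.append((day, day + 2, cfg.cluster_rate))
        day += 3 + int(rng.integers(4, 7))
    specs = [(s, e, r) for s, e, r in specs if e < cfg.n_days]
    d, truth = gen_diary(cfg.n_days, cfg.base_rate[(genotype, sex)],
                         specs, seed=seed)
    summary = summarize(d)
    clusters = find_clusters(d)
    return {
        "total_seizures": summary["total"],
        "frequency_per_day": summary["frequency_per_day"],
        "days_with_seizures": summary["days_with_seizures"],
        "max_seizure_free_days": summary["max_seizure_free_days"],
        "mean_duration_s": summary["mean_duration_s"],
        "n_clusters": clusters.n_clusters,
        "max_intercluster_days": clusters.max_intercluster_days,
        "raster": raster(d).tolist(),
    }


@_stage("histology")
def _histo_metrics(genotype: str, sex: str, cfg: RunConfig, seed: int) -> dict:
    img, roi, truth = gen_histo_image(cfg.dcx_area_um2[genotype], seed=seed)
    res = count_particles(img, roi, threshold=128.0)
    return {"dcx_area_fraction_pct": res.area_fraction_pct,
            "hilar_particles": res.particle_count}


@_stage("group_stats")
def _group_stats(table: pd.DataFrame) -> dict:
    out = {}
    anova_in = table.rename(columns={"total_seizures": "value"})[
        ["value", "genotype", "sex"]]
    out["total_seizures_anova"] = {
        k: v for k, v in anova2_tukey(anova_in).items() if k != "tukey"}
    f_pid = table[table.sex == "F"]
    m_pid = table[table.sex == "M"]
    a = int(round(f_pid.pid_fraction.mean() * len(f_pid) * 10))
    b = len(f_pid) * 10 - a
    c = int(round(m_pid.pid_fraction.mean() * len(m_pid) * 10))
    d = len(m_pid) * 10 - c
    out["pid_sex_fisher_p"] = fisher_exact([[a, b], [c, d]])
    return out


def run_phenotype(cfg: RunConfig) -> dict:
    """Run the full pipeline on a synthetic cohort and write a report.

    Returns the report dict; also writes ``metrics.csv``,
    ``group_stats.json``, ``raster.png`` and ``provenance.json`` under
    ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    try:
        for genotype, sex in GROUPS:
            for i in range(cfg.n_per_group):
                seed = int(rng.integers(0, 2 ** 31 - 1))
                subject = f"{genotype}{sex}{i}"
                log.info("subject %s (seed %d)", subject, seed)
                row = {"subject": subject, "genotype": genotype, "sex": sex}
                row.update(_se_day_metrics(genotype, sex, cfg, seed))
                row.update(_pid_metrics(genotype, sex, cfg, seed + 1))
                row.update(_diary_metrics(genotype, sex, cfg, seed + 2))
                row.update(_histo_metrics(genotype, sex, cfg, seed + 3))
                rows.append(row)
        table = pd.DataFrame(rows)
        stats = _group_stats(table)
    except StageError as exc:
        (out / "FAILED").write_text(str(exc))
        if rows:
            pd.DataFrame(rows).to_csv(out / "metrics.partial.csv", index=False)
        raise

    rasters = np.array([r["raster"] for r in rows])
    table = table.drop(columns=["raster"])
    table.to_csv(out / "metrics.csv", index=False)
    with open(out / "group_stats.json", "w") as fh:
        json.dump(_jsonable(stats), fh, indent=2)
    _plot_raster(rasters, [r["subject"] for r in rows], out / "raster.png")
    provenance = {
        "package": "epiphen",
        "version": __version__,
        "seed": cfg.seed,
        "param_hash": cfg.param_hash(),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return {"metrics": table, "group_stats": stats, "provenance": provenance}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _plot_raster(rasters: np.ndarray, subjects: list, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 0.4 * len(subjects) + 1))
    ax.imshow(rasters, aspect="auto", cmap="Greys", vmin=0, vmax=2,
              interpolation="nearest")
    ax.set_yticks(range(len(subjects)), subjects, fontsize=7)
    ax.set_xlabel("day")
    ax.set_title("days with seizures (grey) and cluster days (black)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
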