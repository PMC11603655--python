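"""End-to-end study orchestration: synth -> events -> decode -> network -> stats.

``run_study`` drives a full synthetic (or pre-generated) study through every
analysis stage, writing one directory per stage (long-format CSV + JSON
summaries), a run log, and a machine-readable ``summary.json``.  Outputs are
deterministic for a given config + seed, and every file records the config
hash so mismatched caches are detectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import decode as dec
from . import events as ev
from . import network as net
from . import stats as st
from . import synth
from .synth import CONDITIONS, SynthConfig

logger = logging.getLogger("cortexscope")

LOW_BIN_LABEL = "2.0-2.5"


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def build_synth_config(overrides: dict | None, seed: int) -> SynthConfig:
    """SynthConfig from a plain-dict override block (YAML-friendly)."""
    overrides = dict(overrides or {})
    if "drug_effects" in overrides:
        overrides["drug_effects"] = {
            k: synth.DrugEffect(**v) for k, v in overrides["drug_effects"].items()
        }
    if "artifact" in overrides:
        overrides["artifact"] = synth.ArtifactConfig(**overrides["artifact"])
    if "amplitude_law" in overrides:
        overrides["amplitude_law"] = synth.TruncatedLognormal(**overrides["amplitude_law"])
    if "shared_latent_corr" in overrides:
        overrides["shared_latent_corr"] = np.asarray(overrides["shared_latent_corr"], dtype=float)
    overrides.setdefault("seed", seed)
    return SynthConfig(**overrides)


def _events_stage(sessions, manifest, out: Path, cfg_hash: str) -> dict:
    """Detect events on post sessions; amplitude bins; Friedman/Dunn on the
    lowest (2.0-2.5 SD) class per region."""
    frames = []
    for row in manifest.itertuples(index=False):
        if row.phase != "post":
            continue
        traces, _truth = sessions[(row.subject, row.day, row.phase)]
        df = ev.detect_events_traces(traces)
        frames.append(df)
    events = pd.concat(frames, ignore_index=True)
    bins = ev.amplitude_histogram_table(events)
    low = bins[bins["bin"] == LOW_BIN_LABEL].copy()
    stats_table = st.friedman_dunn_table(
        low, value="relative_freq", group_by=["region"], reference="saline"
    )
    events.to_csv(out / "events.csv", index=False)
    bins.to_csv(out / "amplitude_bins.csv", index=False)
    stats_table.to_csv(out / "event_stats.csv", index=False)
    sig = stats_table[stats_table["p_adj"] < 0.05]
    return {
        "n_events": int(len(events)),
        "low_bin_significant": sorted(
            {f"{r.region}: {r.contrast}" for r in sig.itertuples(index=False)}
        ),
    }


def _decode_stage(sessions, manifest, out: Path, cfg_hash: str, n_resamples: int, seed: int) -> dict:
    rows = []
    subjects = sorted(manifest["subject"].unique())
    for subject in subjects:
        for phase in ("pre", "post"):
            sub = manifest[(manifest["subject"] == subject) & (manifest["phase"] == phase)]
            sess = [
                (sessions[(r.subject, r.day, r.phase)][0], r.condition, r.day)
                for r in sub.itertuples(index=False)
            ]
            X, y = dec.assemble_dataset(sess)
            res = dec.train_eval(
                X,
                y,
                dec.DecodeConfig(n_resamples=n_resamples),
                seed=np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(4001, subject, 0 if phase == "pre" else 1))
                ),
            )
            rows.append({"subject": subject, "phase": phase, "accuracy": res.accuracy_mean})
    acc = pd.DataFrame(rows)
    acc.to_csv(out / "accuracies.csv", index=False)
    pre = acc[acc["phase"] == "pre"].sort_values("subject")["accuracy"].to_numpy()
    post = acc[acc["phase"] == "post"].sort_values("subject")["accuracy"].to_numpy()
    t, p = dec.compare_phases(pre, post)
    return {
        "pre_mean": float(pre.mean()),
        "post_mean": float(post.mean()),
        "paired_t": float(t),
        "paired_p": float(p),
    }


def _network_stage(sessions, manifest, out: Path, cfg_hash: str, threshold: float) -> dict:
    rows = []
    for row in manifest.itertuples(index=False):
        if row.phase != "post":
            continue
        traces, _ = sessions[(row.subject, row.day, row.phase)]
        graph = net.session_graph(traces, threshold=threshold)
        metrics = net.node_metrics(graph)
        for rec in metrics.itertuples(index=False):
            for metric in net.METRICS:
                rows.append(
                    {
                        "subject": row.subject,
                        "condition": row.condition,
                        "region": rec.node,
                        "metric": metric,
                        "value": float(getattr(rec, metric)),
                    }
                )
    metrics_long = pd.DataFrame(rows)
    stats_table = net.group_compare(metrics_long)
    metrics_long.to_csv(out / "node_metrics.csv", index=False)
    stats_table.to_csv(out / "network_stats.csv", index=False)
    sig = stats_table[stats_table["p_adj"] < 0.05]
    return {
        "significant": sorted(
            {f"{r.region}/{r.metric}: {r.contrast}" for r in sig.itertuples(index=False)}
        )
    }


def run_study(config: dict | str | Path, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run the full pipeline on a synthetic study defined by ``config``.

    Config keys: ``synth`` (SynthConfig overrides), ``decode``
    (``n_resamples``), ``network`` (``threshold``), ``stages`` (subset of
    events/decode/network).  Returns the summary dict also written to
    ``summary.json``.
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text()) or {}
    config = dict(config)
    seed = int(config.get("seed", 0) if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    chash = config_hash({**config, "seed": seed})
    stages = config.get("stages", ["events", "decode", "network"])
    summary: dict = {"config_hash": chash, "seed": seed, "stages": {}}
    try:
        scfg = build_synth_config(config.get("synth"), seed)
        logger.info("generating study (seed=%d, %d subjects)", seed, scfg.n_subjects)
        manifest, sessions = synth.generate_study(scfg, seed)
        manifest.to_csv(out / "manifest.csv", index=False)
        for stage in stages:
            stage_out = out / stage
            stage_out.mkdir(exist_ok=True)
            logger.info("stage %s", stage)
            try:
                if stage == "events":
                    summary["stages"]["events"] = _events_stage(sessions, manifest, stage_out, chash)
                elif stage == "decode":
                    summary["stages"]["decode"] = _decode_stage(
                        sessions, manifest, stage_out, chash,
                        n_resamples=int(config.get("decode", {}).get("n_resamples", 200)),
                        seed=seed,
                    )
                elif stage == "network":
                    summary["stages"]["network"] = _network_stage(
                        sessions, manifest, stage_out, chash,
                        threshold=float(config.get("network", {}).get("threshold", 0.8)),
                    )
                else:
                    raise ValueError(f"unknown stage {stage!r}")
            except Exception:
                (out / "FAILED").write_text(f"stage {stage} failed\n")
                logger.exception("stage %s failed", stage)
                raise
        (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return summary
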