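"""Session file format, pipeline configuration, and the end-to-end runner.

A session is a directory of plain delimited text tables — inspectable and
diff-able, with no binary dependency:

- ``trials.tsv``: one row per trial (choice, port-entry/exit timestamps,
  reward flag, block id, latent target, optional generator annotations),
- ``spikes.tsv``: unit id and spike time, one spike per row,
- ``xy.tsv`` (optional): head-position samples (time, x, y),
- ``manifest.json``: metadata and table inventory.

Timestamps are seconds from session start; trial indices are 0-based.
``run_pipeline`` executes parse -> prevalence -> binning -> state-space
metrics -> classifiers -> encoding -> population decoding for a list of
sessions and writes per-stage tables plus a summary; outputs are
deterministic under a fixed config (no wall-clock content), so repeated
runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from seqprev import classify, encoding, parsing, population, prevalence, statespace

__all__ = [
    "SessionBundle",
    "PipelineConfig",
    "read_session",
    "write_session",
    "run_pipeline",
]

TRIAL_COLUMNS = [
    "choice",
    "t_center_in",
    "t_center_out",
    "t_side_in",
    "t_side_out",
    "rewarded",
    "block_id",
    "latent_target",
]


class SessionFormatError(ValueError):
    """Raised when a session directory violates the schema."""


@dataclass
class SessionBundle:
    """In-memory session: trial table, spike trains, optional tracking."""

    trials: pd.DataFrame
    spikes: dict = field(default_factory=dict)
    xy: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def span(self) -> float:
        if self.n_trials == 0:
            return 0.0
        return float(self.trials["t_side_out"].iloc[-1])

    def validate(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise SessionFormatError(f"trials table missing columns: {missing}")
        bad = ~self.trials["choice"].isin(["L", "R"])
        if bad.any():
            raise SessionFormatError(
                f"invalid choices at rows {list(self.trials.index[bad][:5])}"
            )
        ts = self.trials[
            ["t_center_in", "t_center_out", "t_side_in", "t_side_out"]
        ].to_numpy(dtype=float)
        flat = ts.ravel()
        if len(flat) and np.any(np.diff(flat) <= 0):
            row = int(np.argmax(np.diff(flat) <= 0) // 4)
            raise SessionFormatError(
                f"timestamps not strictly increasing near trial {row}"
            )
        span = self.span
        for uid, st in self.spikes.items():
            st = np.asarray(st, dtype=float)
            if len(st) and (st.min() < 0 or st.max() > span + 1.0):
                raise SessionFormatError(
                    f"unit {uid} has spikes outside the session span "
                    f"[0, {span:.3f}]"
                )
        if self.xy is not None:
            for col in ("time", "x", "y"):
                if col not in self.xy.columns:
                    raise SessionFormatError(f"xy table missing column {col!r}")


def write_session(bundle: SessionBundle, path) -> Path:
    """Write a session directory; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle.trials.to_csv(path / "trials.tsv", sep="\t", index=False)
    rows = [
        (uid, t)
        for uid in sorted(bundle.spikes)
        for t in np.asarray(bundle.spikes[uid], dtype=float)
    ]
    spikes = pd.DataFrame(rows, columns=["unit", "time"])
    spikes.to_csv(path / "spikes.tsv", sep="\t", index=False)
    if bundle.xy is not None:
        bundle.xy.to_csv(path / "xy.tsv", sep="\t", index=False)
    manifest = {
        "format": "seqprev-session/1",
        "n_trials": bundle.n_trials,
        "n_units": len(bundle.spikes),
        "has_xy": bundle.xy is not None,
        "metadata": bundle.metadata,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return path


def read_session(path) -> SessionBundle:
    """Read and validate a session directory."""
    path = Path(path)
    if not (path / "trials.tsv").exists():
        raise SessionFormatError(f"no trials.tsv under {path}")
    trials = pd.read_csv(
        path / "trials.tsv", sep="\t", dtype={"choice": str, "latent_target": str}
    )
    if len(trials):
        trials["rewarded"] = trials["rewarded"].astype(bool)
    spikes = {}
    if (path / "spikes.tsv").exists():
        sp = pd.read_csv(path / "spikes.tsv", sep="\t")
        for uid, grp in sp.groupby("unit"):
            spikes[int(uid)] = np.sort(grp["time"].to_numpy(dtype=float))
    xy = None
    if (path / "xy.tsv").exists():
        xy = pd.read_csv(path / "xy.tsv", sep="\t")
    metadata = {}
    if (path / "manifest.json").exists():
        metadata = json.loads((path / "manifest.json").read_text()).get(
            "metadata", {}
        )
    bundle = SessionBundle(trials=trials, spikes=spikes, xy=xy, metadata=metadata)
    bundle.validate()
    return bundle


@dataclass(frozen=True)
class PipelineConfig:
    """All analysis constants in one place; defaults are the standard values."""

    sequences: tuple = ("LLR", "RRL")
    kernel: prevalence.KernelSpec = field(default_factory=prevalence.KernelSpec)
    window: statespace.WindowSpec = field(default_factory=statespace.WindowSpec)
    classifier: classify.ClassifierSpec = field(
        default_factory=classify.ClassifierSpec
    )
    decoder: population.DecoderSpec = field(default_factory=population.DecoderSpec)
    # parsing thresholds (seconds / trials)
    dwell_rescue_s: float = parsing.STEP3_DWELL_RESCUE_S
    side_to_center_rescue_s: float = parsing.STEP3_SIDE_TO_CENTER_RESCUE_S
    break_removal_s: float = parsing.CENTER_TO_SIDE_BREAK_S
    dominance_run_length: int = parsing.DOMINANCE_RUN_LENGTH
    tail_max_incompatible: int = parsing.TAIL_MAX_INCOMPATIBLE
    # session gates
    session_min_instances: int = 200
    session_min_rate: float = 0.15
    # minimum instances per context for state-space / encoding stages
    min_instances_stage: int = 10
    n_shuffles: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "dwell_rescue_s",
            "side_to_center_rescue_s",
            "break_removal_s",
            "session_min_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return _as_plain(dataclasses.asdict(self))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if "sequences" in kw:
            kw["sequences"] = tuple(kw["sequences"])
        if "kernel" in kw:
            kw["kernel"] = prevalence.KernelSpec(**kw["kernel"])
        if "window" in kw:
            w = dict(kw["window"])
            if "anchors" in w:
                w["anchors"] = tuple(tuple(a) for a in w["anchors"])
            kw["window"] = statespace.WindowSpec(**w)
        if "classifier" in kw:
            c = dict(kw["classifier"])
            if "windows_used" in c:
                c["windows_used"] = tuple(c["windows_used"])
            kw["classifier"] = classify.ClassifierSpec(**c)
        if "decoder" in kw:
            d = dict(kw["decoder"])
            if "neuron_classes_included" in d:
                d["neuron_classes_included"] = tuple(d["neuron_classes_included"])
            kw["decoder"] = population.DecoderSpec(**d)
        unknown = set(kw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kw)


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_as_plain(v) for v in obj.tolist()]
    return obj


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(_as_plain(obj), sort_keys=True, indent=1))


def _analysis_contexts(instances):
    """Instances in the dominant (incl. tail) and exploratory contexts,
    with the binary label used for context statistics."""
    keep = [
        i
        for i in instances
        if i.context
        in (parsing.DOMINANT, parsing.DOMINANT_TAIL, parsing.EXPLORATORY)
    ]
    labels = [
        "EXPLORATORY" if i.context == parsing.EXPLORATORY else "DOMINANT"
        for i in keep
    ]
    return keep, np.array(labels)


def _run_session(bundle: SessionBundle, cfg: PipelineConfig, out: Path, log):
    trials = bundle.trials
    passed, reason = parsing.session_passes_filter(
        trials, min_instances=cfg.session_min_instances, min_rate=cfg.session_min_rate
    )
    summary = {"session_filter": {"passed": bool(passed), "reason": reason}}
    if not passed:
        log(f"excluded: {reason}")
        return summary

    instances = parsing.parse_session(trials, seqs=cfg.sequences)
    parsing.instances_to_frame(instances).to_csv(
        out / "instances.tsv", sep="\t", index=False
    )
    prev_cols = {}
    for seq in cfg.sequences:
        prev_cols[f"prevalence_{seq}"] = prevalence.sequence_prevalence(
            trials, seq, cfg.kernel
        ).values
        prev_cols[f"reward_prevalence_{seq}"] = prevalence.reward_prevalence(
            trials, cfg.kernel, prevalence.REWARD_SEQ_SPECIFIC, seq
        ).values
    prev_cols["reward_prevalence"] = prevalence.reward_prevalence(
        trials, cfg.kernel, prevalence.REWARD_ANY
    ).values
    pd.DataFrame(prev_cols).to_csv(out / "prevalence.tsv", sep="\t", index=False)

    per_seq = {}
    seq_tensors = {}
    for seq in cfg.sequences:
        insts, labels = _analysis_contexts([i for i in instances if i.seq == seq])
        stage = {"n_instances": len(insts)}
        if len(insts) < cfg.min_instances_stage or not bundle.spikes:
            stage["skipped"] = "too few instances or no spikes"
            per_seq[seq] = stage
            continue
        tensor = statespace.bin_instance_activity(
            bundle.spikes, insts, trials, cfg.window
        )
        series = prevalence.PrevalenceSeries(
            values=prev_cols[f"prevalence_{seq}"], kernel=cfg.kernel,
            event_definition=prevalence.SEQ_COMPLETION, seq=seq,
        )
        inst_prev = np.array(
            [prevalence.instance_prevalence(i, series) for i in tensor.instances]
        )
        labels = np.array(
            [
                "EXPLORATORY" if i.context == parsing.EXPLORATORY else "DOMINANT"
                for i in tensor.instances
            ]
        )
        seq_tensors[seq] = (tensor, inst_prev, labels)

        # state-space context statistics
        counts = pd.Series(labels).value_counts()
        if len(counts) == 2 and counts.min() >= max(2, cfg.min_instances_stage // 2):
            state = statespace.build_state_space(tensor)
            null, observed, pct = statespace.shuffle_null(
                state, labels, n_shuffles=cfg.n_shuffles, seed=cfg.seed
            )
            scores = []
            for uid in tensor.unit_ids:
                try:
                    ts = statespace.transition_score(
                        tensor.unit_slice(uid), labels, unit_id=uid
                    )
                    scores.append({"unit": uid, "score": ts.score})
                except ValueError:
                    pass
            per_w, any_w, _ = statespace.context_modulation_fraction(tensor, labels)
            stage["statespace"] = {
                "centroid_distance": observed,
                "shuffle_null_mean": float(null.mean()),
                "shuffle_null_sd": float(null.std()),
                "observed_percentile": pct,
                "transition_scores": scores,
                "modulation_fraction_per_window": list(per_w),
                "modulation_fraction_any_window": any_w,
            }
        else:
            stage["statespace"] = {"skipped": "need both contexts populated"}

        # single-neuron encoding
        enc_rows = []
        for uid in tensor.unit_ids:
            act = tensor.unit_slice(uid)
            try:
                fits = encoding.fit_prevalence_model(
                    act, inst_prev, labels,
                    min_per_context=cfg.min_instances_stage,
                    seed=cfg.seed,
                )
            except ValueError:
                continue
            for ctx, res in fits.items():
                enc_rows.append(
                    {
                        "unit": uid,
                        "context": ctx,
                        "best_window": res.best_window,
                        "best_cv_ev": res.best_ev,
                        **{f"cv_ev_w{w}": res.per_window[w]
                           for w in range(len(res.per_window))},
                    }
                )
        if enc_rows:
            pd.DataFrame(enc_rows).to_csv(
                out / f"encoding_{seq}.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            stage["encoding"] = {
                "n_fits": len(enc_rows),
                "median_best_cv_ev": float(
                    np.median([r["best_cv_ev"] for r in enc_rows])
                ),
            }

        # population decoding
        try:
            classes, admitted = population.assign_neuron_classes(
                tensor, inst_prev, cfg.decoder
            )
            stage["decoding"] = {
                "admitted": bool(admitted),
                "classes": {str(c.unit_id): c.cls for c in classes},
            }
            if admitted:
                window_ev = [
                    population.fit_window_decoder(
                        tensor, w, inst_prev, cfg.decoder, classes=classes
                    ).cv_ev
                    for w in range(cfg.window.n_windows)
                ]
                shared = population.fit_shared_weight_decoder(
                    tensor, inst_prev, cfg.decoder, classes=classes
                )
                stage["decoding"].update(
                    best_of_five_cv_ev=float(np.max(window_ev)),
                    per_window_cv_ev=[float(v) for v in window_ev],
                    shared_cv_ev=shared.cv_ev,
                    shared_worst_window_cv_ev=shared.worst_window_cv_ev,
                )
        except ValueError as exc:
            stage["decoding"] = {"skipped": str(exc)}
        per_seq[seq] = stage

    # sequence-identity classifier (side windows of both sequences)
    if len(seq_tensors) == 2:
        side_windows = [
            w for w, (_, ev) in enumerate(cfg.window.anchors) if ev == "side_in"
        ]
        feats, labels_cls = [], []
        for seq, (tensor, _, _) in seq_tensors.items():
            f = tensor.counts()[:, :, side_windows] / cfg.window.width
            feats.append(f.reshape(len(f), -1))
            labels_cls.extend([seq] * len(f))
        try:
            res = classify.fit_sequence_classifier(
                np.vstack(feats), np.array(labels_cls), cfg.classifier
            )
            summary["sequence_classifier"] = {
                "mean_cv_error": res.mean_cv_error,
                "n_per_class": res.n_per_class,
            }
        except ValueError as exc:
            summary["sequence_classifier"] = {"skipped": str(exc)}
    summary["per_sequence"] = per_seq
    return summary


def run_pipeline(config: PipelineConfig, session_paths, out_dir) -> Path:
    """Run the full analysis over sessions; writes a report directory.

    Per session: instance table, prevalence table, state-space statistics,
    classifier and decoder reports; plus ``summary.json`` over the cohort and
    ``run.log`` with the config hash and seeds.  A stage failing for lack of
    data is recorded and skipped, never fatal.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log_lines = [f"config_hash={chash}", f"seed={config.seed}"]
    summaries = {}
    for spath in session_paths:
        spath = Path(spath)
        name = spath.name
        sess_out = out_dir / name
        sess_out.mkdir(exist_ok=True)
        log_lines.append(f"session={name}")
        bundle = read_session(spath)

        def log(msg, _name=name):
            log_lines.append(f"  [{_name}] {msg}")

        summaries[name] = _run_session(bundle, config, sess_out, log)
        summaries[name]["config_hash"] = chash
    _json_dump(
        {"config_hash": chash, "config": config.to_dict(), "sessions": summaries},
        out_dir / "summary.json",
    )
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return out_dir
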