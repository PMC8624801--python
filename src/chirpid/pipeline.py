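"""End-to-end pipeline: recordings -> segments -> images -> models -> metrics.

Two surfaces are provided. ``build_sample_sets`` / ``make_sample_sets`` keep
everything in memory for library use and testing; the ``stage_*`` functions
are file-based (WAV/TSV/PNG/JSON artifacts) and are what the command-line
interface chains. ``run_pipeline`` executes the stages in order from one YAML
config with a single master seed, so a rerun with the same config is
reproducible artifact-for-artifact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .audio import AudioClip, load_wav
from .fusion import build_fusion_model, self_omega, train_fusion
from .metrics import evaluate_prediction_table, map_paper, read_predictions
from .sfim import ModelSpec, SfimModel, build_sfim
from .signal_prep import (apply_hamming, frame_signal, pre_emphasize,
                          segment_syllables, segments_to_table)
from .synthetic import (DatasetRecipe, SpeciesSpec, default_recipe,
                        generate_dataset, write_dataset)
from .tfr import (KINDS, SpectrogramImage, compute_spectrogram,
                  default_chirplet_bank, render_image, slice_windows)
from .training import (SampleSet, TrainConfig, predict, sampleset_arrays,
                       split_dataset, train_sfim)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised with the name of the failing stage in the message."""

    def __init__(self, stage: str, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


@dataclass
class SegmentationParams:
    frame_ms: float = 50.0
    overlap_frac: float = 0.3
    pre_emphasis: float = 0.95
    threshold_ratio: float = 0.5


# ---------------------------------------------------------------------------
# In-memory path


def segment_clip(clip: AudioClip, params: SegmentationParams | None = None):
    """Pre-emphasise, frame, window and segment one clip.

    Returns (pre-emphasised clip, FrameMatrix, segments).
    """
    p = params or SegmentationParams()
    emph = pre_emphasize(clip, p.pre_emphasis)
    fm = apply_hamming(frame_signal(emph, p.frame_ms, p.overlap_frac))
    return emph, fm, segment_syllables(fm, p.threshold_ratio)


def build_sample_images(recordings, duration_ms: float = 300.0,
                        kinds=KINDS, params: SegmentationParams | None = None,
                        n_fft: int | None = None, bank=None
                        ) -> dict[str, list[SpectrogramImage]]:
    """Render aligned per-kind image lists from a list of labelled clips.

    Every window yields one image per requested kind with an identical
    (clip_id, segment, window) key, so the per-kind sample sets have the same
    size and label sequence by construction.
    """
    p = params or SegmentationParams()
    images: dict[str, list[SpectrogramImage]] = {k: [] for k in kinds}
    for clip in recordings:
        emph, fm, segments = segment_clip(clip, p)
        the_bank = bank
        if "ch" in kinds and the_bank is None:
            the_bank = default_chirplet_bank(clip.sample_rate, fm.frame_len)
        for si, seg in enumerate(segments):
            for wi, win in enumerate(slice_windows(emph, [seg], duration_ms)):
                wfm = apply_hamming(frame_signal(win, p.frame_ms,
                                                 p.overlap_frac))
                for kind in kinds:
                    spec = compute_spectrogram(wfm, kind, n_fft=n_fft,
                                               bank=the_bank)
                    images[kind].append(render_image(
                        spec, window_start_s=win.start_s,
                        window_dur_ms=duration_ms, label=clip.label,
                        clip_id=clip.clip_id, segment_idx=si, window_idx=wi))
    return images


def make_sample_sets(images: dict[str, list[SpectrogramImage]]
                     ) -> tuple[dict[str, SampleSet], SampleSet]:
    """Per-kind SampleSets plus the key-aligned triple set for fusion."""
    kinds = list(images)
    names = sorted({im.label for im in images[kinds[0]]})
    to_idx = {n: i for i, n in enumerate(names)}
    sets = {}
    for kind in kinds:
        items = [(im, to_idx[im.label]) for im in images[kind]]
        sets[kind] = SampleSet(items, len(names), kind, names)
    keys = [im.key for im in images[kinds[0]]]
    for kind in kinds[1:]:
        if [im.key for im in images[kind]] != keys:
            raise PipelineError("spectrogram",
                                "per-kind sample sets are not key-aligned")
    triple_items = [
        (tuple(images[k][i] for k in ("spe", "mel", "ch")),
         to_idx[images[kinds[0]][i].label])
        for i in range(len(keys))
    ] if set(("spe", "mel", "ch")) <= set(kinds) else []
    triple = SampleSet(triple_items, len(names), "triple", names)
    return sets, triple


# ---------------------------------------------------------------------------
# File-based stages


def stage_make_synthetic(recipe: DatasetRecipe, out_dir: str | Path
                         ) -> pd.DataFrame:
    ds = generate_dataset(recipe)
    return write_dataset(ds, out_dir)


def _load_manifest_clips(manifest_path: str | Path) -> list[AudioClip]:
    df = pd.read_csv(manifest_path, sep="\t")
    clips = []
    for _, row in df.iterrows():
        clip = load_wav(row["path"], label=row.get("label"))
        clip.clip_id = row["clip_id"]
        clips.append(clip)
    return clips


def stage_segment(manifest_path: str | Path, out_path: str | Path,
                  params: SegmentationParams | None = None) -> pd.DataFrame:
    """Segment every recording in a manifest into a syllable table (TSV)."""
    try:
        clips = _load_manifest_clips(manifest_path)
        tables = []
        for clip in clips:
            _, _, segments = segment_clip(clip, params)
            tables.append(segments_to_table(segments, clip))
        out = pd.concat(tables, ignore_index=True)
    except (OSError, ValueError, KeyError) as e:
        raise PipelineError("segment", str(e)) from e
    out.to_csv(out_path, sep="\t", index=False)
    return out


def stage_spectrogram(manifest_path: str | Path, duration_ms: float,
                      out_dir: str | Path, kinds=KINDS,
                      params: SegmentationParams | None = None
                      ) -> pd.DataFrame:
    """Render PNG sample images plus the samples manifest the trainers read."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    try:
        clips = _load_manifest_clips(manifest_path)
        images = build_sample_images(clips, duration_ms, kinds, params)
    except (OSError, ValueError, KeyError) as e:
        raise PipelineError("spectrogram", str(e)) from e
    rows = []
    for kind in kinds:
        for im in images[kind]:
            name = f"{im.clip_id}_{im.segment_idx}_{im.window_idx}_{im.kind}.png"
            path = out / "images" / name
            Image.fromarray(im.pixels).save(path)
            rows.append({"path": str(path), "label": im.label, "kind": im.kind,
                         "duration_ms": duration_ms, "clip_id": im.clip_id,
                         "segment": im.segment_idx, "window": im.window_idx})
    samples = pd.DataFrame(rows)
    samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    return samples


def _sampleset_from_manifest(samples: pd.DataFrame, kind: str) -> SampleSet:
    sub = samples[samples["kind"] == kind].sort_values(
        ["clip_id", "segment", "window"])
    names = sorted(samples["label"].unique())
    to_idx = {n: i for i, n in enumerate(names)}
    items = []
    for _, row in sub.iterrows():
        px = np.asarray(Image.open(row["path"]).convert("RGB"), dtype=np.uint8)
        im = SpectrogramImage(px, kind, 0.0, float(row["duration_ms"]),
                              label=row["label"], clip_id=row["clip_id"],
                              segment_idx=int(row["segment"]),
                              window_idx=int(row["window"]))
        items.append((im, to_idx[row["label"]]))
    return SampleSet(items, len(names), kind, names)


def _tripleset_from_manifest(samples: pd.DataFrame) -> SampleSet:
    per_kind = {k: _sampleset_from_manifest(samples, k)
                for k in ("spe", "mel", "ch")}
    base = per_kind["spe"]
    items = []
    for i, (im, y) in enumerate(base.items):
        triple = tuple(per_kind[k].items[i][0] for k in ("spe", "mel", "ch"))
        for t in triple:
            if t.key != im.key:
                raise PipelineError("train-fusion",
                                    "sample sets are not key-aligned")
        items.append((triple, y))
    return SampleSet(items, base.n_classes, "triple", base.class_names)


def _metrics_for(model, test_set: SampleSet, input_size: int) -> dict:
    x, y = sampleset_arrays(test_set, input_size)
    pred = predict(model, x)
    per_class = []
    for c in range(test_set.n_classes):
        mask = y == c
        per_class.append(float(np.mean(pred[mask] == c)))
    return {"map": map_paper(pred, y, test_set.n_classes),
            "per_class_avep": per_class}


def stage_train_sfim(samples_path: str | Path, kind: str, out_dir: str | Path,
                     model_spec: ModelSpec, cfg: TrainConfig,
                     train_frac: float = 0.7) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        samples = pd.read_csv(samples_path, sep="\t")
        ss = _sampleset_from_manifest(samples, kind)
        train, test = split_dataset(ss, train_frac, cfg.seed)
        model = build_sfim(model_spec, seed=cfg.seed)
        history = train_sfim(model, train, test, cfg)
    except (OSError, ValueError, KeyError) as e:
        raise PipelineError("train-sfim", str(e)) from e
    model.save(out / "checkpoint")
    (out / "history.jsonl").write_text(
        "\n".join(json.dumps(h, sort_keys=True) for h in history) + "\n")
    metrics = _metrics_for(model, test, model_spec.input_size)
    metrics["kind"] = kind
    (out / "metrics.json").write_text(
        json.dumps(metrics, indent=2, sort_keys=True))
    return metrics


def stage_train_fusion(samples_path: str | Path, mode: str,
                       backbone_dirs, out_dir: str | Path, cfg: TrainConfig,
                       hidden: int | None = None, train_frac: float = 0.7
                       ) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        samples = pd.read_csv(samples_path, sep="\t")
        triple = _tripleset_from_manifest(samples)
        train, test = split_dataset(triple, train_frac, cfg.seed)
        backbones = [SfimModel.load(Path(d) / "checkpoint")
                     for d in backbone_dirs]
        fm = build_fusion_model(backbones, mode, triple.n_classes,
                                hidden=hidden, seed=cfg.seed)
        history = train_fusion(fm, train, test, cfg)
    except (OSError, ValueError, KeyError) as e:
        raise PipelineError("train-fusion", str(e)) from e
    fm.save(out / "checkpoint")
    (out / "history.jsonl").write_text(
        "\n".join(json.dumps(h, sort_keys=True) for h in history) + "\n")
    from .fusion import triple_arrays
    x_test, y_test = triple_arrays(test, backbones[0].spec.input_size)
    pred = np.argmax(fm.forward(x_test), axis=1)
    per_class = [float(np.mean(pred[y_test == c] == c))
                 for c in range(triple.n_classes)]
    metrics = {"map": map_paper(pred, y_test, triple.n_classes),
               "per_class_avep": per_class, "mode": mode,
               "omega": self_omega(fm)}
    (out / "metrics.json").write_text(
        json.dumps(metrics, indent=2, sort_keys=True))
    return metrics


def stage_evaluate(pred_path: str | Path, out_path: str | Path) -> dict:
    try:
        metrics = evaluate_prediction_table(read_predictions(pred_path))
    except (OSError, ValueError, KeyError) as e:
        raise PipelineError("evaluate", str(e)) from e
    Path(out_path).write_text(json.dumps(metrics, indent=2, sort_keys=True))
    return metrics


# ---------------------------------------------------------------------------
# Chained run


def _recipe_from_config(cfg: dict, seed: int) -> DatasetRecipe:
    syn = cfg.get("synthetic", {})
    if "species" in syn:
        species = [SpeciesSpec(**s) for s in syn["species"]]
        return DatasetRecipe(species, syn["counts"],
                             syn.get("snr_db", 20.0),
                             syn.get("sample_rate", 44100), seed)
    return default_recipe(syn.get("n_species", 3),
                          syn.get("counts"), syn.get("snr_db", 20.0),
                          syn.get("sample_rate", 44100), seed)


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None
                 ) -> dict:
    """Chain make-synthetic -> segment -> spectrogram -> training -> metrics.

    The whole run is driven by one master seed; the aggregated metrics are
    written to ``<out_dir>/metrics.json`` (sorted keys, so reruns with the
    same seed produce byte-identical files).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir or config.get("out_dir", "runs/chirpid"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    seg_cfg = config.get("segment", {})
    params = SegmentationParams(
        frame_ms=seg_cfg.get("frame_ms", 50.0),
        overlap_frac=seg_cfg.get("overlap", 0.3),
        pre_emphasis=seg_cfg.get("pre_emphasis", 0.95),
        threshold_ratio=seg_cfg.get("threshold", 0.5))
    spec_cfg = config.get("spectrogram", {})
    durations = spec_cfg.get("durations_ms", [300.0])
    kinds = tuple(spec_cfg.get("kinds", list(KINDS)))
    model_cfg = config.get("model", {})
    train_cfg = config.get("train", {})
    cfg = TrainConfig(
        batch_size=train_cfg.get("batch_size", 50),
        learning_rate=train_cfg.get("learning_rate", 0.001),
        max_epochs=train_cfg.get("max_epochs", 100),
        patience=train_cfg.get("patience", 10),
        seed=seed, deterministic=bool(config.get("deterministic", True)))
    train_frac = train_cfg.get("train_frac", 0.7)
    fusion_cfg = config.get("fusion", {})
    modes = fusion_cfg.get("modes", ["result", "feature"])

    recipe = _recipe_from_config(config, seed)
    manifest = stage_make_synthetic(recipe, out / "data")
    stage_segment(out / "data" / "manifest.tsv", out / "segments.tsv", params)

    summary: dict = {"seed": seed}
    for dur in durations:
        dur_key = f"duration_{int(dur)}ms"
        sdir = out / f"samples_{int(dur)}ms"
        samples = stage_spectrogram(out / "data" / "manifest.tsv", dur,
                                    sdir, kinds, params)
        n_classes = samples["label"].nunique()
        mspec = ModelSpec(n_classes,
                          model_cfg.get("width_multiplier", 1.0),
                          model_cfg.get("input_size", 224))
        entry: dict = {}
        backbone_dirs = []
        for kind in kinds:
            rdir = out / f"run_{int(dur)}ms" / f"sfim_{kind}"
            entry[f"sfim_{kind}"] = stage_train_sfim(
                sdir / "samples.tsv", kind, rdir, mspec, cfg, train_frac)
            backbone_dirs.append(rdir)
        if set(("spe", "mel", "ch")) <= set(kinds):
            for mode in modes:
                rdir = out / f"run_{int(dur)}ms" / f"fuse_{mode}"
                entry[f"fuse_{mode}"] = stage_train_fusion(
                    sdir / "samples.tsv", mode, backbone_dirs, rdir, cfg,
                    hidden=fusion_cfg.get("hidden"), train_frac=train_frac)
        summary[dur_key] = entry
    (out / "metrics.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    return summary
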