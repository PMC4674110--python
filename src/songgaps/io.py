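"""Readers and writers: Audacity-style label TSVs, PCM WAV, corpora, and
run artifacts with provenance."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .segment import SyllableInterval
from .simulate import Corpus, GroundTruth, render_corpus

__all__ = [
    "read_label_file",
    "write_label_file",
    "read_wav",
    "write_wav",
    "write_corpus",
    "load_events",
    "read_config_file",
    "provenance",
]

LABEL_HEADER = ["onset_s", "offset_s", "label"]


class LabelFileError(ValueError):
    pass


def read_label_file(path) -> list[SyllableInterval]:
    """Parse a 3-column label TSV (onset_s, offset_s, label) into validated,
    time-ordered syllable intervals.  Malformed rows are reported with their
    line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or [c.strip() for c in lines[0].split("\t")] != LABEL_HEADER:
        raise LabelFileError(f"{path}: expected header {'	'.join(LABEL_HEADER)!r}")
    rendition_id = path.stem
    out: list[SyllableInterval] = []
    prev_offset = -np.inf
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise LabelFileError(f"{path}:{ln}: expected 3 tab-separated fields")
        try:
            onset, offset = float(parts[0]), float(parts[1])
        except ValueError:
            raise LabelFileError(f"{path}:{ln}: non-numeric onset/offset") from None
        label = parts[2].strip()
        if len(label) != 1:
            raise LabelFileError(f"{path}:{ln}: label {label!r} is not one character")
        if offset <= onset:
            raise LabelFileError(f"{path}:{ln}: offset <= onset")
        if onset < prev_offset:
            raise LabelFileError(
                f"{path}:{ln}: interval overlaps or precedes the previous one"
            )
        out.append(SyllableInterval(label, onset, offset, rendition_id=rendition_id))
        prev_offset = offset
    return out


def write_label_file(path, intervals: list[SyllableInterval]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(LABEL_HEADER) + "\n")
        for iv in intervals:
            fh.write(f"{iv.onset:.6f}\t{iv.offset:.6f}\t{iv.label}\n")


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono PCM WAV as float samples in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return data, int(rate)


def write_wav(path, samples: np.ndarray, rate: int) -> None:
    peak = np.max(np.abs(samples)) if len(samples) else 0.0
    scale = 0.95 / peak if peak > 1.0 else 1.0
    wavfile.write(path, rate, np.round(samples * scale * 32767).astype(np.int16))


def _nominal_intervals(bird, rend) -> list[SyllableInterval]:
    t = 0.02
    out = []
    for i, lab in enumerate(rend.labels):
        dur = bird.label_props[lab][0] / 1000.0
        out.append(SyllableInterval(lab, t, t + dur, rendition_id=rend.rendition_id,
                                    bird_id=bird.bird_id))
        t += dur
        if i < len(rend.gaps_ms):
            t += rend.gaps_ms[i] / 1000.0
    return out


def write_corpus(
    corpus: Corpus,
    outdir,
    waveforms: bool = False,
    truth: GroundTruth | None = None,
) -> Path:
    """Write a corpus as one label TSV (and optionally one WAV) per
    rendition, under ``outdir/<bird_id>/``, plus ground truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if waveforms:
        by_key = {}
        for bird_id, rid, samples, bounds, labels in render_corpus(corpus):
            by_key[(bird_id, rid)] = (samples, bounds, labels)
    for bird in corpus.birds:
        bdir = outdir / bird.bird_id
        bdir.mkdir(exist_ok=True)
        for rend in bird.renditions:
            if waveforms:
                samples, bounds, labels = by_key[(bird.bird_id, rend.rendition_id)]
                write_wav(bdir / f"{rend.rendition_id}.wav", samples,
                          corpus.config.waveform.rate)
                ivs = [
                    SyllableInterval(lab, on, off, rendition_id=rend.rendition_id,
                                     bird_id=bird.bird_id)
                    for lab, (on, off) in zip(labels, bounds)
                ]
            else:
                ivs = _nominal_intervals(bird, rend)
            write_label_file(bdir / f"{rend.rendition_id}.txt", ivs)
    if truth is not None:
        (outdir / "ground_truth.json").write_text(truth.to_json())
    return outdir


def load_events(labels_dir, audio: bool = False, threshold_frac: float = 0.1,
                condition: str = "A") -> pd.DataFrame:
    """Build the events frame (one row per syllable instance) from a corpus
    directory of per-bird label TSVs.

    With ``audio=True``, matching WAV files are segmented: label boundaries
    are refined against the amplitude envelope (threshold =
    ``threshold_frac`` of the corpus median syllable peak) and per-syllable
    RMS amplitudes are measured from the baseline-subtracted waveform.
    """
    from .segment import (compute_envelope, estimate_baseline, refine_intervals,
                          rms_amplitude)

    labels_dir = Path(labels_dir)
    bird_dirs = sorted(d for d in labels_dir.iterdir() if d.is_dir())
    if not bird_dirs:
        raise FileNotFoundError(f"no bird directories under {labels_dir}")
    rows = []
    for bdir in bird_dirs:
        label_files = sorted(bdir.glob("*.txt"))
        if not label_files:
            raise FileNotFoundError(f"no label files under {bdir}")
        envelopes = {}
        if audio:
            peaks = []
            for lf in label_files:
                wav = lf.with_suffix(".wav")
                data, rate = read_wav(wav)
                env = compute_envelope(data, rate)
                envelopes[lf] = (env, data, rate)
                for iv in read_label_file(lf):
                    s0 = int(iv.onset * env.rate)
                    s1 = int(np.ceil(iv.offset * env.rate))
                    seg = env.values[s0:s1]
                    if seg.size:
                        peaks.append(seg.max())
            thr = threshold_frac * float(np.median(peaks))
        for lf in label_files:
            ivs = read_label_file(lf)
            amps = None
            if audio:
                env, data, rate = envelopes[lf]
                ivs = refine_intervals(env, ivs, thr)
                baseline = estimate_baseline(env, ivs)
                amps = [
                    rms_amplitude(data, rate, iv.onset, iv.offset, baseline)
                    for iv in ivs
                ]
            n = len(ivs)
            for i, iv in enumerate(ivs):
                gap = (
                    (ivs[i + 1].onset - iv.offset) * 1000.0 if i < n - 1 else np.nan
                )
                if gap < 0:
                    raise LabelFileError(
                        f"{lf}: overlap after refinement at syllable {i}"
                    )
                rows.append(
                    {
                        "bird_id": bdir.name,
                        "condition": condition,
                        "rendition_id": lf.stem,
                        "position": i,
                        "label": iv.label,
                        "next_label": ivs[i + 1].label if i < n - 1 else None,
                        "gap_to_next_ms": gap,
                        **({"amp": amps[i]} if amps is not None else {}),
                    }
                )
    return pd.DataFrame(rows)


def read_config_file(path) -> dict:
    """Flat key-value configuration (YAML subset: ``key: value`` lines)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return cfg


def provenance(config: dict, seed: int) -> dict:
    """Config hash + seed block embedded in every output artifact."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
    }
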