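"""Amplitude-based syllable segmentation and gap/amplitude measurement.

The segmentation convention: a syllable is a region of the amplitude
envelope above threshold, and distinct syllables are separated by at least
5 ms of silence.  The envelope is the rectified waveform smoothed with a
5 ms square window and resampled to 1 kHz.  Gap durations are measured from
the offset of the first syllable of a transition to the onset of the next.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import resample_poly

__all__ = [
    "SyllableInterval",
    "Envelope",
    "GapMeasurement",
    "compute_envelope",
    "segment_syllables",
    "refine_intervals",
    "measure_gaps",
    "normalize_across_recordings",
    "rms_amplitude",
    "platform_normalize",
]

ENVELOPE_RATE = 1000  # Hz, canonical envelope sampling rate
SMOOTH_MS = 5.0  # square smoothing window
MIN_SILENT_MS = 5.0  # syllables are separated by >= 5 ms of silence


@dataclass(frozen=True)
class SyllableInterval:
    """A labelled syllable occurrence; times in seconds from rendition start,
    half-open [onset, offset)."""

    label: str
    onset: float
    offset: float
    rendition_id: str = ""
    bird_id: str = ""
    condition: str = ""

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError(
                f"syllable {self.label!r}: offset {self.offset} <= onset {self.onset}"
            )
        if self.onset < 0:
            raise ValueError(f"syllable {self.label!r}: negative onset")


@dataclass(frozen=True)
class Envelope:
    values: np.ndarray  # nonnegative amplitude samples
    rate: int = ENVELOPE_RATE

    def __post_init__(self):
        if len(self.values) == 0:
            raise ValueError("empty envelope")


@dataclass(frozen=True)
class GapMeasurement:
    context: str  # label transitioned from
    target: str  # label transitioned to
    gap_ms: float
    rendition_id: str = ""


def compute_envelope(audio: np.ndarray, rate: int) -> Envelope:
    """Rectify, smooth (5 ms square window, reflect padding) and resample to
    1 kHz.  Output length is ``ceil(duration_s * 1000)``."""
    audio = np.asarray(audio, dtype=float)
    if audio.size == 0:
        raise ValueError("empty audio")
    if rate < 8000:
        raise ValueError(f"sample rate {rate} Hz < 8 kHz")
    rect = np.abs(audio)
    win = max(1, int(round(SMOOTH_MS / 1000.0 * rate)))
    smooth = uniform_filter1d(rect, size=win, mode="reflect")
    if rate == ENVELOPE_RATE:
        values = smooth
    else:
        from math import gcd

        g = gcd(ENVELOPE_RATE, rate)
        values = resample_poly(smooth, ENVELOPE_RATE // g, rate // g)
    return Envelope(np.clip(values, 0.0, None), ENVELOPE_RATE)


def segment_syllables(
    envelope: Envelope,
    threshold: float,
    min_silent_ms: float = MIN_SILENT_MS,
    min_syllable_ms: float = 10.0,
) -> list[tuple[float, float]]:
    """Threshold the envelope into syllable intervals.

    Maximal runs above ``threshold`` are candidate syllables; candidates
    separated by silence shorter than ``min_silent_ms`` are merged (they are
    one syllable under the >= 5 ms silence definition); merged candidates
    shorter than ``min_syllable_ms`` are discarded.  Boundaries are seconds
    from the 1 kHz envelope, half-open, with the threshold crossing located
    by linear interpolation between the straddling envelope samples.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    v = envelope.values
    above = v > threshold
    if not above.any():
        return []
    # run-length encode
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    min_sil = min_silent_ms / 1000.0 * envelope.rate
    min_syl = min_syllable_ms / 1000.0 * envelope.rate
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and (s - merged[-1][1]) < min_sil:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    def _onset(s: int) -> float:
        if s == 0:
            return 0.0
        frac = (threshold - v[s - 1]) / (v[s] - v[s - 1])
        return (s - 1 + frac) / envelope.rate

    def _offset(e: int) -> float:
        if e >= len(v):
            return len(v) / envelope.rate
        frac = (v[e - 1] - threshold) / (v[e - 1] - v[e])
        return (e - 1 + frac) / envelope.rate

    return [
        (_onset(s), _offset(e)) for s, e in merged if (e - s) >= min_syl
    ]


def refine_intervals(
    envelope: Envelope,
    intervals: list[SyllableInterval],
    threshold: float,
    pad_ms: float = 15.0,
    min_silent_ms: float = MIN_SILENT_MS,
    min_syllable_ms: float = 10.0,
) -> list[SyllableInterval]:
    """Snap label-file boundaries to envelope threshold crossings.

    Labels are authoritative for identity and approximate extent (the primary
    analysis path); the envelope refines onset/offset.  If no above-threshold
    region overlaps a labelled interval, the labelled times are kept.
    """
    segs = segment_syllables(envelope, threshold, min_silent_ms, min_syllable_ms)
    out = []
    for iv in intervals:
        lo, hi = iv.onset - pad_ms / 1000.0, iv.offset + pad_ms / 1000.0
        best, best_ov = None, 0.0
        for s, e in segs:
            ov = min(e, iv.offset) - max(s, iv.onset)
            if s < hi and e > lo and ov > best_ov:
                best, best_ov = (s, e), ov
        if best is None:
            out.append(iv)
        else:
            out.append(
                SyllableInterval(
                    iv.label, best[0], best[1], iv.rendition_id, iv.bird_id, iv.condition
                )
            )
    return out


def measure_gaps(intervals: list[SyllableInterval]) -> list[GapMeasurement]:
    """Gap durations between adjacent syllables of one rendition.

    ``gap_ms = (next.onset - current.offset) * 1000``, attributed to the
    (context, target) transition.  Overlapping intervals signal corrupt
    labels and raise.
    """
    out = []
    for a, b in zip(intervals[:-1], intervals[1:]):
        gap_ms = (b.onset - a.offset) * 1000.0
        if gap_ms < 0:
            raise ValueError(
                f"overlapping syllables {a.label!r}@{a.offset:.4f}s and "
                f"{b.label!r}@{b.onset:.4f}s in rendition {a.rendition_id!r}"
            )
        out.append(GapMeasurement(a.label, b.label, gap_ms, a.rendition_id))
    return out


def _median_envelope(instances: list[np.ndarray]) -> np.ndarray:
    n = min(len(v) for v in instances)
    return np.median(np.vstack([v[:n] for v in instances]), axis=0)


def normalize_across_recordings(
    epoch_a: list[np.ndarray],
    epoch_b: list[np.ndarray],
    threshold_frac: float = 0.1,
    reference_peak: float = 1.0,
    rate: int = ENVELOPE_RATE,
    min_instances: int = 5,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Compare one transition's gap across two recording epochs whose
    absolute amplitudes are not comparable.

    Each instance is a 1 kHz envelope excerpt aligned so index 0 is the
    branch-point syllable onset (the syllable transitioned from) and
    extending past the following syllable.  Per epoch: take the pointwise
    median envelope, rescale it so the branch-point syllable's peak equals
    ``reference_peak``, then apply one common threshold
    (``threshold_frac * reference_peak``) to both normalized medians to
    re-derive the branch syllable offset and the next syllable onset — one
    gap value per epoch.

    Returns ``(median_env_a, median_env_b, gap_a_ms, gap_b_ms)``.
    """
    results = []
    for name, instances in (("A", epoch_a), ("B", epoch_b)):
        if len(instances) < min_instances:
            raise ValueError(
                f"epoch {name}: {len(instances)} instances < required {min_instances}"
            )
        med = _median_envelope([np.asarray(v, dtype=float) for v in instances])
        peak = med.max()
        if peak <= 0:
            raise ValueError(f"epoch {name}: zero peak amplitude")
        # locate the branch-point syllable: the above-threshold region at the
        # start of the excerpt (relative threshold on the unnormalized median)
        segs = segment_syllables(Envelope(med, rate), threshold_frac * peak)
        if len(segs) < 2:
            raise ValueError(
                f"epoch {name}: expected branch syllable + transition syllable, "
                f"found {len(segs)} segments"
            )
        i0 = int(segs[0][0] * rate)
        i1 = int(segs[0][1] * rate)
        branch_peak = med[i0:i1].max()
        if branch_peak <= 0:
            raise ValueError(f"epoch {name}: zero branch-syllable peak")
        norm = med * (reference_peak / branch_peak)
        segs = segment_syllables(Envelope(norm, rate), threshold_frac * reference_peak)
        if len(segs) < 2:
            raise ValueError(f"epoch {name}: transition syllable lost after rescaling")
        gap_ms = (segs[1][0] - segs[0][1]) * 1000.0
        results.append((norm, gap_ms))
    (env_a, gap_a), (env_b, gap_b) = results
    return env_a, env_b, gap_a, gap_b


def rms_amplitude(
    waveform: np.ndarray,
    rate: int,
    onset: float,
    offset: float,
    baseline: float = 0.0,
) -> float:
    """RMS of the baseline-subtracted waveform over [onset, offset)."""
    s0 = int(round(onset * rate))
    s1 = int(round(offset * rate))
    if s0 < 0 or s1 > len(waveform) or s1 <= s0:
        raise ValueError(
            f"window [{onset}, {offset}) s outside waveform of "
            f"{len(waveform) / rate:.3f} s"
        )
    x = np.asarray(waveform[s0:s1], dtype=float) - baseline
    return float(np.sqrt(np.mean(x * x)))


def estimate_baseline(envelope: Envelope, intervals: list[SyllableInterval]) -> float:
    """Median envelope value over the inter-syllable (silent) regions."""
    mask = np.ones(len(envelope.values), dtype=bool)
    for iv in intervals:
        s0 = int(iv.onset * envelope.rate)
        s1 = int(np.ceil(iv.offset * envelope.rate))
        mask[s0:s1] = False
    silent = envelope.values[mask]
    return float(np.median(silent)) if silent.size else 0.0


def platform_normalize(median_rms: dict[str, float]) -> dict[str, float]:
    """Divide each syllable's median RMS by the platform maximum, yielding
    values in (0, 1] with the loudest syllable at exactly 1.0."""
    if not median_rms:
        return {}
    peak = max(median_rms.values())
    if peak <= 0:
        raise ValueError("platform maximum RMS is not positive")
    return {k: v / peak for k, v in median_rms.items()}
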