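"""Synthetic Bengalese-finch-style song corpora with full ground truth.

Adult Bengalese finch song is a sequence of discrete syllables organised into
stereotyped chains (pairwise transition probability > 95%) and branch points,
nodes where the next syllable varies from rendition to rendition.  The
generator emulates the statistical structure that the downstream analyses
assume:

* multi-bird corpora of labelled renditions with 2-5 targets per branch point,
* an inverse (configurable) linear relationship between a transition's
  probability ``p`` and the log10 duration of the silent gap inside it::

      log10(gap_ms) = a + b * p + u_bird + v_sequence + tau_transition + eps,

  with independent zero-mean normal effects for bird, sequence (branch point
  or chain, nested in bird), transition (a fixed bigram within a bird) and
  per-instance residual,
* syllable amplitudes that co-vary with transition probability,
* paired-condition corpora (undirected vs. female-directed song, young vs.
  older adults) in which sequencing and timing changes are coupled,
  decoupled, or absent, and
* optional waveform rendering so that amplitude-threshold segmentation can be
  exercised against exact boundary ground truth.

Every rendition is a walk over a fixed cycle of "units" (stereotyped chains
and branch specs).  After each unit the song either terminates (a reserved
end state, so song-termination exclusion logic is exercisable downstream) or
proceeds to the next unit in the cycle.  Branch targets are drawn
independently on every visit.  All randomness flows from a single root seed
through per-bird ``numpy`` ``SeedSequence`` sub-streams, so a fixed seed
yields byte-identical corpora.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "BranchSpec",
    "GapModel",
    "AmplitudeModel",
    "ConditionEffect",
    "WaveformSpec",
    "GeneratorConfig",
    "Rendition",
    "BirdCorpus",
    "Corpus",
    "GroundTruth",
    "default_config",
    "generate_corpus",
    "generate_condition_pair",
    "synthesize_waveform",
    "render_corpus",
    "events_frame",
]

#: minimum silent interval between syllables (ms); shorter gaps would merge
#: the syllables under the field's segmentation definition.
MIN_SILENT_MS = 5.0


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


# --------------------------------------------------------------------------
# configuration dataclasses
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BranchSpec:
    """One branch point: a context sequence and its target distribution."""

    context: str
    targets: Mapping[str, float]

    def validate(self) -> None:
        if not self.context:
            raise ConfigurationError("branch context must be non-empty")
        if len(self.targets) < 2:
            raise ConfigurationError(
                f"branch {self.context!r} needs >=2 targets, got {len(self.targets)}"
            )
        probs = np.asarray(list(self.targets.values()), dtype=float)
        if (probs < 0).any():
            raise ConfigurationError(f"branch {self.context!r} has negative probabilities")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ConfigurationError(
                f"branch {self.context!r} probabilities sum to {probs.sum()!r}, not 1"
            )


@dataclass(frozen=True)
class GapModel:
    """Linear model for log10 gap duration (ms) as a function of transition
    probability.

    ``intercept`` and ``slope`` are in log10 ms (slope per unit probability);
    the default slope is negative (inverse sequencing-timing coupling).  The
    four standard deviations are the bird, sequence-within-bird,
    transition-within-sequence and per-instance residual effects, all in
    log10 ms.  ``transition_sd`` is the scatter of a transition's median gap
    around the linear model; it is what limits how precisely the coupling
    slope can be recovered at a given corpus size.
    """

    intercept: float = 2.10
    slope: float = -0.240
    bird_sd: float = 0.08
    sequence_sd: float = 0.10
    transition_sd: float = 0.17
    residual_sd: float = 0.10
    min_gap_ms: float = 6.0

    def validate(self) -> None:
        for name in ("bird_sd", "sequence_sd", "transition_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"gap_model.{name} must be >= 0")
        if self.min_gap_ms < MIN_SILENT_MS:
            raise ConfigurationError(
                f"gap_model.min_gap_ms must be >= {MIN_SILENT_MS} ms"
            )


@dataclass(frozen=True)
class AmplitudeModel:
    """Per-syllable amplitude structure.

    Each (bird, label) pair gets a base amplitude drawn uniformly from
    ``base_range``.  The realised log10 amplitude of a syllable instance is
    ``log10(base) + coupling * (p_in - 0.5) + noise`` where ``p_in`` is the
    probability of the transition that produced the syllable, so more
    prevalent targets are louder when ``coupling > 0`` (the pattern reported
    for real song).
    """

    base_range: tuple[float, float] = (0.25, 0.60)
    coupling: float = 0.20
    noise_sd: float = 0.05

    def validate(self) -> None:
        lo, hi = self.base_range
        if not (0 < lo <= hi):
            raise ConfigurationError("amplitude base_range must satisfy 0 < lo <= hi")
        if self.noise_sd < 0:
            raise ConfigurationError("amplitude noise_sd must be >= 0")


@dataclass(frozen=True)
class ConditionEffect:
    """How condition B (e.g. older adult, or female-directed song) differs
    from condition A.

    mode
        ``"coupled"``: each transition's expected log10 gap change is
        ``log10(gap_factor) - coupling_strength * delta_p`` plus transition
        noise — gaps shrink most for transitions that rise in probability
        (age-like pattern).  ``"decoupled"``: a uniform multiplicative gap
        change ``gap_factor`` independent of the probability shifts
        (context-like pattern).  ``"null"``: no systematic change to either
        sequencing or timing.
    prob_shifts
        Optional explicit per-context target shifts.  When absent (and mode
        is not ``"null"``), condition-B branch distributions are drawn per
        bird as ``(1 - prob_mix) * p_A + prob_mix * q`` with
        ``q ~ Dirichlet(prob_concentration * p_template)``, which keeps them
        on the simplex while producing realistic drift (sd(delta_p) ~ 0.14 at
        the defaults).
    """

    mode: str = "coupled"
    gap_factor: float = 0.94
    coupling_strength: float = 0.15
    change_noise_sd: float = 0.03
    prob_mix: float = 0.5
    prob_concentration: float = 2.0
    prob_shifts: Mapping[str, Mapping[str, float]] | None = None

    def validate(self) -> None:
        if self.mode not in ("coupled", "decoupled", "null"):
            raise ConfigurationError(f"unknown condition mode {self.mode!r}")
        if self.gap_factor <= 0:
            raise ConfigurationError("gap_factor must be > 0")
        if not 0 <= self.prob_mix <= 1:
            raise ConfigurationError("prob_mix must be in [0, 1]")
        if self.change_noise_sd < 0:
            raise ConfigurationError("change_noise_sd must be >= 0")


@dataclass(frozen=True)
class WaveformSpec:
    """Audio rendering parameters.

    Syllables are rendered as raised-cosine-edged amplitude envelopes over a
    tonal carrier (or band-limited noise); silent intervals sit at the
    Gaussian noise floor.  Spectral realism is deliberately out of scope —
    only the amplitude structure matters downstream.
    """

    rate: int = 32000
    edge_ms: float = 4.5
    carrier: str = "tone"  # "tone" or "noise"
    noise_floor: float = 0.005
    syllable_ms_range: tuple[float, float] = (60.0, 110.0)
    freq_range: tuple[float, float] = (2000.0, 6000.0)
    pad_ms: float = 20.0

    def validate(self) -> None:
        if self.rate < 8000:
            raise ConfigurationError("waveform rate must be >= 8 kHz")
        if self.carrier not in ("tone", "noise"):
            raise ConfigurationError(f"unknown carrier {self.carrier!r}")
        if self.noise_floor < 0:
            raise ConfigurationError("noise_floor must be >= 0")


def _default_branch_specs() -> tuple[BranchSpec, ...]:
    return (
        BranchSpec("ea", {"f": 0.85, "k": 0.15}),
        BranchSpec("lm", {"n": 0.60, "o": 0.40}),
        BranchSpec("rs", {"t": 0.50, "u": 0.30, "v": 0.20}),
        BranchSpec("wx", {"y": 0.75, "z": 0.20, "q": 0.05}),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic corpus.

    Defaults reproduce the study conditions the analyses were designed for:
    22 birds, 30 renditions each, branch points with 2-3 targets spanning a
    wide probability range, two stereotyped chains, and songs of ~60
    syllables (termination probability 0.05 per unit).
    """

    n_birds: int = 22
    renditions_per_bird: int = 30
    branch_specs: tuple[BranchSpec, ...] = field(default_factory=_default_branch_specs)
    stereotyped_chains: tuple[str, ...] = ("bcd", "ghj")
    end_prob: float = 0.05
    prob_concentration: float | None = 60.0
    gap_model: GapModel = field(default_factory=GapModel)
    amplitude_model: AmplitudeModel = field(default_factory=AmplitudeModel)
    condition_effect: ConditionEffect | None = None
    waveform: WaveformSpec = field(default_factory=WaveformSpec)
    seed: int = 0

    def validate(self) -> None:
        if not self.branch_specs and not self.stereotyped_chains:
            raise ConfigurationError(
                "configuration needs at least one branch spec or stereotyped chain"
            )
        if not (0 < self.end_prob <= 1):
            raise ConfigurationError("end_prob must be in (0, 1]")
        if self.n_birds < 1 or self.renditions_per_bird < 1:
            raise ConfigurationError("n_birds and renditions_per_bird must be >= 1")
        for spec in self.branch_specs:
            spec.validate()
        for chain in self.stereotyped_chains:
            if len(chain) < 2:
                raise ConfigurationError(f"stereotyped chain {chain!r} too short")
        self.gap_model.validate()
        self.amplitude_model.validate()
        self.waveform.validate()
        if self.condition_effect is not None:
            self.condition_effect.validate()


def default_config(**overrides) -> GeneratorConfig:
    """The study-condition configuration, with keyword overrides."""
    return dataclasses.replace(GeneratorConfig(), **overrides)


# --------------------------------------------------------------------------
# corpus containers
# --------------------------------------------------------------------------


@dataclass
class Rendition:
    """One labelled song rendition: labels, per-transition gaps (ms) and
    per-syllable amplitudes."""

    rendition_id: str
    labels: list[str]
    gaps_ms: np.ndarray  # len(labels) - 1
    amps: np.ndarray  # len(labels)


@dataclass
class BirdCorpus:
    bird_id: str
    renditions: list[Rendition]
    #: per-label (duration_ms, carrier_freq_hz, base_amplitude)
    label_props: dict[str, tuple[float, float, float]]


@dataclass
class Corpus:
    birds: list[BirdCorpus]
    condition: str
    config: GeneratorConfig

    def renditions_by_bird(self) -> dict[str, list[list[str]]]:
        return {b.bird_id: [r.labels for r in b.renditions] for b in self.birds}


@dataclass
class GroundTruth:
    """Generator-side truth for every transition (bigram) of every bird.

    ``transitions`` columns: bird_id, condition, from_label, to_label,
    sequence_id, p_true (termination-excluded), mu_log10_gap (expected log10
    median gap, ms), kind (``branch``/``chain``/``junction``).  For condition
    pairs ``expected_change`` adds delta_p and delta_mu per bigram.
    """

    transitions: pd.DataFrame
    expected_change: pd.DataFrame | None = None

    def to_json(self) -> str:
        payload = {"transitions": self.transitions.to_dict(orient="list")}
        if self.expected_change is not None:
            payload["expected_change"] = self.expected_change.to_dict(orient="list")
        return json.dumps(payload, sort_keys=True)


# --------------------------------------------------------------------------
# per-bird generative model
# --------------------------------------------------------------------------


class _Unit:
    __slots__ = ("labels", "targets", "cum", "first", "last_labels")

    def __init__(self, labels: list[str], targets: list[str] | None, probs: np.ndarray | None):
        self.labels = labels  # chain labels, or branch context labels
        self.targets = targets  # None for chains
        self.cum = None if probs is None else np.cumsum(probs)
        self.first = labels[0]
        self.last_labels = [labels[-1]] if targets is None else list(targets)


class _BirdModel:
    """Frozen per-bird parameters: target distributions, random effects and
    the termination-excluded probability of every possible bigram."""

    def __init__(self, bird_id: str, config: GeneratorConfig, rng: np.random.Generator):
        self.bird_id = bird_id
        self.config = config
        gm = config.gap_model

        # per-bird branch target distributions (Dirichlet jitter around the
        # configured templates, concentration prob_concentration)
        self.branch_probs: dict[str, dict[str, float]] = {}
        for spec in config.branch_specs:
            template = np.asarray(list(spec.targets.values()), dtype=float)
            if config.prob_concentration is not None:
                conc = np.maximum(config.prob_concentration * template, 1e-3)
                probs = rng.dirichlet(conc)
            else:
                probs = template
            self.branch_probs[spec.context] = dict(zip(spec.targets.keys(), probs))

        # unit cycle: interleave chains and branch specs
        units: list[_Unit] = []
        chains = list(config.stereotyped_chains)
        branches = list(config.branch_specs)
        n = max(len(chains), len(branches))
        for i in range(n):
            if i < len(chains):
                units.append(_Unit(list(chains[i]), None, None))
            if i < len(branches):
                spec = branches[i]
                probs = np.asarray(list(self.branch_probs[spec.context].values()))
                units.append(_Unit(list(spec.context), list(spec.targets.keys()), probs))
        self.units = units

        # enumerate every bigram, its termination-excluded probability and
        # its sequence (= the order-1 context it belongs to)
        self.bigram_p: dict[tuple[str, str], float] = {}
        self.bigram_kind: dict[tuple[str, str], str] = {}
        for ui, u in enumerate(units):
            for a, b in zip(u.labels[:-1], u.labels[1:]):
                self.bigram_p[(a, b)] = 1.0
                self.bigram_kind[(a, b)] = "chain"
            if u.targets is not None:
                ctx_last = u.labels[-1]
                probs = self.branch_probs["".join(u.labels)]
                for t, p in probs.items():
                    self.bigram_p[(ctx_last, t)] = float(p)
                    self.bigram_kind[(ctx_last, t)] = "branch"
            # junction: every last label of this unit -> first label of next
            nxt = units[(ui + 1) % len(units)]
            for last in u.last_labels:
                key = (last, nxt.first)
                # p excluding termination: the next unit is deterministic
                self.bigram_p[key] = 1.0
                self.bigram_kind[key] = "junction"

        # random effects
        self.u_bird = rng.normal(0.0, gm.bird_sd) if gm.bird_sd > 0 else 0.0
        seqs = sorted({a for (a, _b) in self.bigram_p})
        self.v_seq = {
            s: (rng.normal(0.0, gm.sequence_sd) if gm.sequence_sd > 0 else 0.0)
            for s in seqs
        }
        self.tau = {
            bg: (rng.normal(0.0, gm.transition_sd) if gm.transition_sd > 0 else 0.0)
            for bg in sorted(self.bigram_p)
        }
        self.mu = {
            bg: gm.intercept
            + gm.slope * p
            + self.u_bird
            + self.v_seq[bg[0]]
            + self.tau[bg]
            for bg, p in self.bigram_p.items()
        }

        # per-label acoustic properties (fixed within bird)
        labels = sorted({lab for u in units for lab in u.labels}
                        | {t for u in units if u.targets for t in u.targets})
        wf = config.waveform
        am = config.amplitude_model
        self.label_props = {}
        for lab in labels:
            dur = rng.uniform(*wf.syllable_ms_range)
            freq = rng.uniform(*wf.freq_range)
            base = rng.uniform(*am.base_range)
            self.label_props[lab] = (float(dur), float(freq), float(base))

    # -- sampling ----------------------------------------------------------

    def sample_rendition(
        self,
        rng: np.random.Generator,
        rendition_id: str,
        mu: Mapping[tuple[str, str], float] | None = None,
        branch_cum: Mapping[str, tuple[list[str], np.ndarray]] | None = None,
    ) -> Rendition:
        """Walk the unit cycle until termination; draw gaps and amplitudes."""
        cfg = self.config
        gm = cfg.gap_model
        am = cfg.amplitude_model
        mu = self.mu if mu is None else mu
        labels: list[str] = []
        k = 0
        while True:
            u = self.units[k]
            labels.extend(u.labels)
            if u.targets is not None:
                if branch_cum is not None:
                    tgts, cum = branch_cum["".join(u.labels)]
                else:
                    tgts, cum = u.targets, u.cum
                labels.append(tgts[int(np.searchsorted(cum, rng.random()))])
            if rng.random() < cfg.end_prob:
                break
            k = (k + 1) % len(self.units)

        n = len(labels)
        mus = np.array([mu[(labels[i], labels[i + 1])] for i in range(n - 1)])
        eps = rng.normal(0.0, gm.residual_sd, n - 1) if gm.residual_sd > 0 else 0.0
        gaps = np.maximum(10.0 ** (mus + eps), gm.min_gap_ms)

        p_in = np.empty(n)
        p_in[0] = 1.0
        for i in range(1, n):
            p_in[i] = self.bigram_p.get((labels[i - 1], labels[i]), 1.0)
        base = np.array([self.label_props[lab][2] for lab in labels])
        amp_noise = rng.normal(0.0, am.noise_sd, n) if am.noise_sd > 0 else 0.0
        amps = 10.0 ** (np.log10(base) + am.coupling * (p_in - 0.5) + amp_noise)
        return Rendition(rendition_id, labels, gaps, amps)


def _truth_frame(bird_models: list[_BirdModel], condition: str) -> pd.DataFrame:
    rows = []
    for bm in bird_models:
        for (a, b), p in sorted(bm.bigram_p.items()):
            rows.append(
                {
                    "bird_id": bm.bird_id,
                    "condition": condition,
                    "from_label": a,
                    "to_label": b,
                    "sequence_id": f"{bm.bird_id}:{a}",
                    "p_true": p,
                    "mu_log10_gap": bm.mu[(a, b)],
                    "kind": bm.bigram_kind[(a, b)],
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# public generation API
# --------------------------------------------------------------------------


def _bird_models(config: GeneratorConfig) -> tuple[list[_BirdModel], list[np.random.Generator]]:
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_birds)
    models, rngs = [], []
    width = max(2, len(str(config.n_birds)))
    for i, ss in enumerate(children):
        streams = ss.spawn(3)  # parameters, condition-A renditions, condition-B
        rng_param = np.random.default_rng(streams[0])
        bird_id = f"bird{i + 1:0{width}d}"
        models.append(_BirdModel(bird_id, config, rng_param))
        rngs.append([np.random.default_rng(streams[1]), np.random.default_rng(streams[2])])
    return models, rngs


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a single-condition corpus and its ground truth."""
    config.validate()
    models, rngs = _bird_models(config)
    birds = []
    for bm, (rng_a, _rng_b) in zip(models, rngs):
        rends = [
            bm.sample_rendition(rng_a, f"r{j + 1:04d}")
            for j in range(config.renditions_per_bird)
        ]
        birds.append(BirdCorpus(bm.bird_id, rends, bm.label_props))
    corpus = Corpus(birds, "A", config)
    return corpus, GroundTruth(_truth_frame(models, "A"))


def _condition_b_model(
    bm: _BirdModel, ce: ConditionEffect, rng: np.random.Generator
) -> tuple[dict, dict, dict]:
    """Per-bird condition-B branch distributions, per-bigram expected log10
    gap changes, and the resulting mu_B table."""
    cfg = bm.config
    probs_b: dict[str, dict[str, float]] = {}
    delta_p: dict[tuple[str, str], float] = {}
    for spec in cfg.branch_specs:
        ctx = spec.context
        pa = np.asarray(list(bm.branch_probs[ctx].values()))
        tgts = list(bm.branch_probs[ctx].keys())
        if ce.mode == "null":
            pb = pa.copy()
        elif ce.prob_shifts is not None:
            shift = np.array([ce.prob_shifts.get(ctx, {}).get(t, 0.0) for t in tgts])
            pb = pa + shift
            if (pb < 0).any() or (pb > 1).any():
                raise ConfigurationError(
                    f"prob_shifts push {ctx!r} outside [0, 1]: {pb}"
                )
            if abs(pb.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"prob_shifts for {ctx!r} do not sum to zero")
        else:
            template = np.asarray(list(spec.targets.values()))
            conc = np.maximum(ce.prob_concentration * template, 1e-3)
            q = rng.dirichlet(conc)
            pb = (1.0 - ce.prob_mix) * pa + ce.prob_mix * q
        probs_b[ctx] = dict(zip(tgts, pb))
        last = ctx[-1]
        for t, p_a_i, p_b_i in zip(tgts, pa, pb):
            delta_p[(last, t)] = float(p_b_i - p_a_i)

    delta_mu: dict[tuple[str, str], float] = {}
    base = np.log10(ce.gap_factor)
    for bg in bm.bigram_p:
        dp = delta_p.get(bg, 0.0)
        if ce.mode == "null":
            delta_mu[bg] = 0.0
            continue
        eta = rng.normal(0.0, ce.change_noise_sd) if ce.change_noise_sd > 0 else 0.0
        if ce.mode == "coupled":
            delta_mu[bg] = base - ce.coupling_strength * dp + eta
        else:  # decoupled
            delta_mu[bg] = base + eta

    mu_b = {bg: bm.mu[bg] + delta_mu[bg] for bg in bm.mu}
    return probs_b, {**{bg: delta_p.get(bg, 0.0) for bg in bm.bigram_p}}, (delta_mu, mu_b)


def generate_condition_pair(
    config: GeneratorConfig,
) -> tuple[Corpus, Corpus, GroundTruth]:
    """Generate paired-condition corpora (A, B) sharing bird-level structure.

    Condition B applies the configured probability shifts and gap changes;
    random effects (bird, sequence, transition) are shared across conditions,
    emulating the repeated-measures designs the change analyses assume.
    """
    config.validate()
    ce = config.condition_effect
    if ce is None:
        raise ConfigurationError("generate_condition_pair requires condition_effect")
    models, rngs = _bird_models(config)
    birds_a, birds_b, change_rows = [], [], []
    for bm, (rng_a, rng_b) in zip(models, rngs):
        probs_b, dp, (dmu, mu_b) = _condition_b_model(bm, ce, rng_b)
        branch_cum_b = {
            ctx: (list(t.keys()), np.cumsum(list(t.values())))
            for ctx, t in probs_b.items()
        }
        rends_a = [
            bm.sample_rendition(rng_a, f"r{j + 1:04d}")
            for j in range(config.renditions_per_bird)
        ]
        rends_b = [
            bm.sample_rendition(rng_b, f"r{j + 1:04d}", mu=mu_b, branch_cum=branch_cum_b)
            for j in range(config.renditions_per_bird)
        ]
        birds_a.append(BirdCorpus(bm.bird_id, rends_a, bm.label_props))
        birds_b.append(BirdCorpus(bm.bird_id, rends_b, bm.label_props))
        pb_flat = {}
        for ctx, t in probs_b.items():
            for tgt, p in t.items():
                pb_flat[(ctx[-1], tgt)] = float(p)
        for (a, b), p_a in sorted(bm.bigram_p.items()):
            change_rows.append(
                {
                    "bird_id": bm.bird_id,
                    "from_label": a,
                    "to_label": b,
                    "sequence_id": f"{bm.bird_id}:{a}",
                    "p_a": p_a,
                    "p_b": pb_flat.get((a, b), p_a),
                    "delta_p": dp[(a, b)],
                    "delta_mu": dmu[(a, b)],
                    "kind": bm.bigram_kind[(a, b)],
                }
            )
    corpus_a = Corpus(birds_a, "A", config)
    corpus_b = Corpus(birds_b, "B", config)
    truth = GroundTruth(_truth_frame(models, "A"), pd.DataFrame(change_rows))
    return corpus_a, corpus_b, truth


# --------------------------------------------------------------------------
# waveform rendering
# --------------------------------------------------------------------------


def _envelope(n: int, n_edge: int) -> np.ndarray:
    env = np.ones(n)
    if n_edge > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_edge) / n_edge))
        env[:n_edge] = ramp
        env[n - n_edge:] = ramp[::-1]
    return env


def synthesize_waveform(
    labels: Sequence[str],
    gaps_ms: Sequence[float],
    amps: Sequence[float],
    spec: WaveformSpec,
    durations_ms: Sequence[float],
    freqs_hz: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Render one rendition to audio samples plus exact nominal boundaries.

    Each syllable is a raised-cosine-edged envelope of the given duration and
    amplitude over a tonal carrier (or Gaussian noise when
    ``spec.carrier == "noise"``); silent intervals sit at the configured
    noise floor.  Returned boundaries are the nominal envelope onset/offset
    in seconds, so ``onset[i+1] - offset[i]`` equals the requested gap
    exactly.
    """
    spec.validate()
    gaps = np.asarray(gaps_ms, dtype=float)
    if len(gaps) != len(labels) - 1:
        raise ValueError("need one gap per adjacent syllable pair")
    if (gaps < MIN_SILENT_MS).any():
        raise ValueError(
            f"gaps below the {MIN_SILENT_MS} ms silent-interval minimum: "
            f"{gaps[gaps < MIN_SILENT_MS]}"
        )
    rate = spec.rate
    pad = spec.pad_ms / 1000.0
    boundaries = []
    t = pad
    for i in range(len(labels)):
        onset = t
        offset = onset + durations_ms[i] / 1000.0
        boundaries.append((onset, offset))
        if i < len(gaps):
            t = offset + gaps[i] / 1000.0
        else:
            t = offset
    n = int(round((t + pad) * rate))
    if spec.noise_floor > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        x = spec.noise_floor * rng.standard_normal(n)
    else:
        x = np.zeros(n)
    n_edge = int(round(spec.edge_ms / 1000.0 * rate))
    for i, (onset, offset) in enumerate(boundaries):
        s0 = int(round(onset * rate))
        s1 = int(round(offset * rate))
        m = s1 - s0
        env = _envelope(m, min(n_edge, m // 2))
        if spec.carrier == "tone":
            f = 3000.0 if freqs_hz is None else freqs_hz[i]
            carrier = np.sin(2.0 * np.pi * f * np.arange(m) / rate)
        else:
            if rng is None:
                rng = np.random.default_rng(0)
            carrier = rng.standard_normal(m)
            carrier /= max(np.sqrt(np.mean(carrier**2)), 1e-12)
        x[s0:s1] += amps[i] * env * carrier
    return x, boundaries


def render_corpus(
    corpus: Corpus,
) -> Iterator[tuple[str, str, np.ndarray, list[tuple[float, float]], list[str]]]:
    """Yield ``(bird_id, rendition_id, samples, boundaries, labels)`` for
    every rendition, with per-bird deterministic noise streams."""
    spec = corpus.config.waveform
    for bi, bird in enumerate(corpus.birds):
        rng = np.random.default_rng([corpus.config.seed, 7919, bi])
        for rend in bird.renditions:
            durs = [bird.label_props[lab][0] for lab in rend.labels]
            freqs = [bird.label_props[lab][1] for lab in rend.labels]
            samples, bounds = synthesize_waveform(
                rend.labels, rend.gaps_ms, rend.amps, spec, durs, freqs, rng
            )
            yield bird.bird_id, rend.rendition_id, samples, bounds, rend.labels


# --------------------------------------------------------------------------
# tabular view
# --------------------------------------------------------------------------


def events_frame(corpus: Corpus) -> pd.DataFrame:
    """Flatten a corpus into one row per syllable instance.

    Columns: bird_id, condition, rendition_id, position, label, next_label
    (NaN at rendition end), gap_to_next_ms, amp.  This is the in-memory
    interchange format shared by the label-domain and audio-domain analysis
    paths.
    """
    cols = {k: [] for k in (
        "bird_id", "condition", "rendition_id", "position", "label",
        "next_label", "gap_to_next_ms", "amp",
    )}
    for bird in corpus.birds:
        for rend in bird.renditions:
            n = len(rend.labels)
            cols["bird_id"].extend([bird.bird_id] * n)
            cols["condition"].extend([corpus.condition] * n)
            cols["rendition_id"].extend([rend.rendition_id] * n)
            cols["position"].extend(range(n))
            cols["label"].extend(rend.labels)
            cols["next_label"].extend(rend.labels[1:] + [None])
            cols["gap_to_next_ms"].extend(list(rend.gaps_ms) + [np.nan])
            cols["amp"].extend(rend.amps)
    return pd.DataFrame(cols)
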