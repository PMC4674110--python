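"""Coupling statistics: sequencing vs. timing, amplitude mediation, and
paired-condition change analyses.

The central quantity is the per-transition pair (p, median gap): for every
eligible branch-point or stereotyped transition with at least 5 gap
instances, the transition probability and the log10-transformed median gap
duration.  All models are linear mixed models with random intercepts for
bird and for sequence nested within bird, fitted by REML with unbounded
variance components (see :mod:`songgaps.lmm`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, shapiro

from . import syntax
from .lmm import MixedModelResult, fit_lmm, ls_means, tukey_pairs
from .simulate import Corpus
from .syntax import START, BranchPoint

__all__ = [
    "CorpusAnalysis",
    "analyze_corpus",
    "build_coupling_table",
    "fit_coupling_model",
    "compare_transition_types",
    "residualize_amplitude",
    "categorize_changes",
    "ChangeCategory",
    "build_change_table",
    "change_coupling_analysis",
    "category_contrast",
    "CategoryContrast",
    "screen_normality",
    "NormalityScreen",
]

MIN_INSTANCES = 5  # median gaps are only trusted with >= 5 instances

CATEGORY_ORDER = ["increased", "decreased", "unchanged", "stereotyped"]


@dataclass
class CorpusAnalysis:
    """Branch points and the filtered coupling table for one corpus."""

    branch_points: dict[str, list[BranchPoint]]
    coupling: pd.DataFrame
    flagged: dict[str, set]
    events: pd.DataFrame
    params: dict = field(default_factory=dict)


def _iter_renditions(corpus) -> list[tuple[str, list[str], np.ndarray, np.ndarray | None]]:
    """Normalise a Corpus or events frame to (bird, labels, gaps, amps) tuples."""
    out = []
    if isinstance(corpus, Corpus):
        for bird in corpus.birds:
            for rend in bird.renditions:
                out.append((bird.bird_id, rend.labels, rend.gaps_ms, rend.amps))
        return out
    events = corpus.sort_values(["bird_id", "rendition_id", "position"], kind="stable")
    has_amp = "amp" in events.columns
    birds = events["bird_id"].to_numpy()
    rids = events["rendition_id"].to_numpy()
    labels = events["label"].to_numpy()
    gaps = events["gap_to_next_ms"].to_numpy(dtype=float)
    amps = events["amp"].to_numpy(dtype=float) if has_amp else None
    keys = np.array([f"{b}\x00{r}" for b, r in zip(birds, rids)])
    change = np.flatnonzero(keys[1:] != keys[:-1]) + 1
    starts = np.concatenate([[0], change, [len(keys)]])
    for s, e in zip(starts[:-1], starts[1:]):
        out.append(
            (
                birds[s],
                list(labels[s:e]),
                gaps[s : e - 1],
                amps[s:e] if has_amp else None,
            )
        )
    return out


def _rendition_sequences(rends) -> dict[str, list[list[str]]]:
    out: dict[str, list[list[str]]] = {}
    for bird, labels, _g, _a in rends:
        out.setdefault(bird, []).append(list(labels))
    return out


def analyze_corpus(
    corpus,
    alpha: float = 0.05,
    min_occurrences: int = syntax.MIN_OCCURRENCES,
    min_instances: int = MIN_INSTANCES,
    max_context_order: int = 2,
    exclude_variable_repeats: bool = True,
) -> CorpusAnalysis:
    """Run the syntax stage and assemble the coupling table for a corpus.

    ``corpus`` is a :class:`songgaps.simulate.Corpus` or an events DataFrame
    (columns bird_id, rendition_id, position, label, next_label,
    gap_to_next_ms and optionally amp) — the same representation the audio
    path produces.
    """
    rends = _iter_renditions(corpus)
    sequences = _rendition_sequences(rends)
    branch_points: dict[str, list[BranchPoint]] = {}
    flagged: dict[str, set] = {}
    for bird, bird_seqs in sequences.items():
        if exclude_variable_repeats:
            frag_rends, bird_flagged = syntax.exclude_repeats(bird_seqs)
        else:
            frag_rends, bird_flagged = bird_seqs, set()
        table = syntax.count_transitions(frag_rends, max_context_order)
        bps = syntax.resolve_contexts(
            table, alpha=alpha, min_occurrences=min_occurrences
        )
        for bp in bps:
            bp.bird_id = bird
        branch_points[bird] = bps
        flagged[bird] = bird_flagged
    coupling = build_coupling_table(
        rends, branch_points, flagged, min_instances=min_instances
    )
    return CorpusAnalysis(
        branch_points,
        coupling,
        flagged,
        corpus if isinstance(corpus, pd.DataFrame) else None,
        params={
            "alpha": alpha,
            "min_occurrences": min_occurrences,
            "min_instances": min_instances,
            "max_context_order": max_context_order,
        },
    )


def build_coupling_table(
    corpus,
    branch_points: dict[str, list[BranchPoint]],
    flagged: dict[str, set] | None = None,
    min_instances: int = MIN_INSTANCES,
) -> pd.DataFrame:
    """One row per analyzed transition: probability, median gap, amplitude.

    Gap instances are attributed to the resolved context (split contexts by
    their order-2 predecessor, pooled contexts by the order-1 label);
    transitions touching variable-repeat labels are excluded; rows need at
    least ``min_instances`` gap instances.  ``corpus`` is a Corpus, events
    frame, or the tuple list from the internal iterator.
    """
    rends = (
        corpus
        if isinstance(corpus, list)
        else _iter_renditions(corpus)
    )
    has_amp = any(a is not None for _b, _l, _g, a in rends)
    # per-bird lookup: split contexts keyed by (predecessor, label)
    split_map: dict[str, dict] = {}
    pooled_map: dict[str, dict] = {}
    for bird, bps in branch_points.items():
        split_map[bird] = {}
        pooled_map[bird] = {}
        for bp in bps:
            if bp.predecessors is None:
                pooled_map[bird][bp.context] = bp
            else:
                for pred in bp.predecessors:
                    split_map[bird][(pred, bp.context[-1])] = bp

    samples: dict[tuple, dict] = {}
    for bird, labels, gaps, amps in rends:
        bird_flagged = (flagged or {}).get(bird, set())
        smap = split_map.get(bird, {})
        pmap = pooled_map.get(bird, {})
        for i in range(len(labels) - 1):
            frm, to = labels[i], labels[i + 1]
            if frm in bird_flagged or to in bird_flagged:
                continue
            pred = labels[i - 1] if i > 0 else START
            bp = smap.get((pred, frm)) or pmap.get(frm)
            if bp is None:
                continue
            p = bp.probability(to)
            if p is None:
                continue
            key = (bird, bp.context, to)
            rec = samples.get(key)
            if rec is None:
                rec = samples[key] = {"bp": bp, "gaps": [], "amps": []}
            rec["gaps"].append(gaps[i])
            if amps is not None:
                rec["amps"].append(amps[i + 1])

    rows = []
    for (bird, context, target), rec in sorted(samples.items()):
        gaps = np.asarray(rec["gaps"], dtype=float)
        if len(gaps) < min_instances:
            continue
        bp = rec["bp"]
        med = float(np.median(gaps))
        row = {
            "bird_id": bird,
            "sequence_id": f"{bird}:{context}",
            "context": context,
            "target": target,
            "p": bp.probability(target),
            "n_instances": len(gaps),
            "n_occurrences": bp.n_occurrences,
            "median_gap_ms": med,
            "log10_gap": np.log10(med),
            "transition_type": bp.classification,
        }
        if has_amp:
            amp_med = float(np.median(np.asarray(rec["amps"], dtype=float)))
            row["rms_amp"] = amp_med
            row["log10_amp"] = np.log10(amp_med) if amp_med > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# mixed-model analyses
# --------------------------------------------------------------------------


def _fit(rows: pd.DataFrame, y: np.ndarray, x: np.ndarray, names: list[str]):
    if rows["bird_id"].nunique() < 2:
        raise ValueError("coupling models need data from >= 2 birds")
    X = np.column_stack([np.ones(len(rows)), x])
    return fit_lmm(
        y,
        X,
        {"bird": rows["bird_id"].to_numpy(), "sequence": rows["sequence_id"].to_numpy()},
        fe_names=names,
    )


def fit_coupling_model(
    rows: pd.DataFrame, response: str = "log10_gap", predictor: str = "p"
) -> MixedModelResult:
    """Mixed model ``response ~ predictor`` with bird and
    sequence-within-bird random intercepts (REML, Satterthwaite df)."""
    y = rows[response].to_numpy(dtype=float)
    x = rows[predictor].to_numpy(dtype=float)
    if not (np.isfinite(y).all() and np.isfinite(x).all()):
        raise ValueError("response and predictor must be finite")
    return _fit(rows, y, x, ["intercept", predictor])


def compare_transition_types(rows: pd.DataFrame) -> MixedModelResult:
    """Branch vs. stereotyped contrast on log10 gap durations.

    The coefficient ``branch_minus_stereotyped`` is positive when branch
    gaps are longer.
    """
    types = set(rows["transition_type"])
    if types != {"branch", "stereotyped"}:
        raise ValueError(
            f"need both transition types, got {sorted(types)}"
        )
    x = (rows["transition_type"] == "branch").to_numpy(dtype=float)
    y = rows["log10_gap"].to_numpy(dtype=float)
    return _fit(rows, y, x, ["intercept", "branch_minus_stereotyped"])


def residualize_amplitude(
    rows: pd.DataFrame,
) -> tuple[pd.DataFrame, MixedModelResult, MixedModelResult]:
    """Coupling after removing the amplitude-gap relationship.

    Step 1 regresses log10 gap on log10 amplitude (same random structure)
    and extracts conditional residuals; step 2 regresses those residuals on
    transition probability.  Returns (rows + ``amp_resid``, step-1 fit,
    step-2 fit).
    """
    if "log10_amp" not in rows.columns or rows["log10_amp"].isna().any():
        bad = (
            list(rows.index[rows["log10_amp"].isna()])
            if "log10_amp" in rows.columns
            else list(rows.index)
        )
        raise ValueError(f"missing amplitudes for rows {bad}")
    fit1 = fit_coupling_model(rows, response="log10_gap", predictor="log10_amp")
    out = rows.copy()
    out["amp_resid"] = fit1.resid
    fit2 = fit_coupling_model(out, response="amp_resid", predictor="p")
    return out, fit1, fit2


# --------------------------------------------------------------------------
# paired-condition change analyses
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ChangeCategory:
    target: str
    category: str  # increased / decreased / unchanged
    statistic: float
    pvalue: float
    p_a: float
    p_b: float


def _chi2_2x2(a_t, a_r, b_t, b_r, method: str) -> tuple[float, float]:
    n = a_t + a_r + b_t + b_r
    col1, col2 = a_t + b_t, a_r + b_r
    row1, row2 = a_t + a_r, b_t + b_r
    if min(col1, col2, row1, row2) == 0:
        return 0.0, 1.0
    if method == "chi2":
        stat = n * (a_t * b_r - a_r * b_t) ** 2 / (row1 * row2 * col1 * col2)
    elif method == "lrt":
        obs = np.array([[a_t, a_r], [b_t, b_r]], dtype=float)
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
        stat = 2.0 * terms.sum()
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(stat), float(chi2.sf(stat, 1))


def categorize_changes(
    counts_a: dict[str, int],
    counts_b: dict[str, int],
    alpha: float = 0.05,
    method: str = "chi2",
) -> dict[str, ChangeCategory]:
    """Per-target change category between two conditions.

    Each target is tested with a 2x2 contingency table (this target vs. all
    other targets, condition A vs. B) using the chi-square statistic without
    continuity correction (``method="lrt"`` switches to the G test).
    Significant increases in probability are ``increased``, significant
    decreases ``decreased``, the rest ``unchanged``.
    """
    total_a, total_b = sum(counts_a.values()), sum(counts_b.values())
    if total_a == 0 or total_b == 0:
        raise ValueError("both conditions need non-zero transition totals")
    out = {}
    for target in sorted(set(counts_a) | set(counts_b)):
        a_t = counts_a.get(target, 0)
        b_t = counts_b.get(target, 0)
        stat, p = _chi2_2x2(a_t, total_a - a_t, b_t, total_b - b_t, method)
        p_a, p_b = a_t / total_a, b_t / total_b
        if p < alpha and p_b > p_a:
            cat = "increased"
        elif p < alpha and p_b < p_a:
            cat = "decreased"
        else:
            cat = "unchanged"
        out[target] = ChangeCategory(target, cat, stat, p, p_a, p_b)
    return out


def build_change_table(
    analysis_a: CorpusAnalysis,
    analysis_b: CorpusAnalysis,
    alpha: float = 0.05,
    min_instances: int = MIN_INSTANCES,
    method: str = "chi2",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-transition paired-condition differences.

    Returns ``(change_df, stereotyped_df)``.  ``change_df`` covers contexts
    that are a branch point in at least one condition and occur at least the
    occurrence minimum in both (enforced upstream by branch-point
    resolution), with one row per target having >= ``min_instances`` gap
    instances in both conditions: delta_p, delta_log10_gap,
    pct_gap_change and the contingency-test category.  ``stereotyped_df``
    holds the same gap-change measures for sequences stereotyped in both
    conditions (category ``"stereotyped"``).
    """
    def _index(analysis):
        bps = {}
        for bird, lst in analysis.branch_points.items():
            for bp in lst:
                bps[(bird, bp.context)] = bp
        gaps = {
            (r.bird_id, r.context, r.target): r
            for r in analysis.coupling.itertuples()
        }
        return bps, gaps

    bps_a, gaps_a = _index(analysis_a)
    bps_b, gaps_b = _index(analysis_b)
    change_rows, stereo_rows = [], []
    for key in sorted(set(bps_a) & set(bps_b)):
        bird, context = key
        bp_a, bp_b = bps_a[key], bps_b[key]
        kinds = {bp_a.classification, bp_b.classification}
        counts_a = {t: c for t, c, _p in bp_a.targets}
        counts_b = {t: c for t, c, _p in bp_b.targets}
        if "branch" in kinds:
            cats = categorize_changes(counts_a, counts_b, alpha=alpha, method=method)
            for target, cat in cats.items():
                ra = gaps_a.get((bird, context, target))
                rb = gaps_b.get((bird, context, target))
                if ra is None or rb is None:
                    continue
                if ra.n_instances < min_instances or rb.n_instances < min_instances:
                    continue
                change_rows.append(
                    {
                        "bird_id": bird,
                        "sequence_id": f"{bird}:{context}",
                        "context": context,
                        "target": target,
                        "p_a": cat.p_a,
                        "p_b": cat.p_b,
                        "delta_p": cat.p_b - cat.p_a,
                        "median_gap_a": ra.median_gap_ms,
                        "median_gap_b": rb.median_gap_ms,
                        "delta_log10_gap": rb.log10_gap - ra.log10_gap,
                        "pct_gap_change": 100.0
                        * (rb.median_gap_ms - ra.median_gap_ms)
                        / ra.median_gap_ms,
                        "category": cat.category,
                        "test_statistic": cat.statistic,
                        "test_p": cat.pvalue,
                    }
                )
        else:
            # stereotyped in both conditions: track the dominant transition
            dom_a = max(bp_a.targets, key=lambda t: t[2])[0]
            dom_b = max(bp_b.targets, key=lambda t: t[2])[0]
            if dom_a != dom_b:
                continue
            ra = gaps_a.get((bird, context, dom_a))
            rb = gaps_b.get((bird, context, dom_a))
            if ra is None or rb is None:
                continue
            if ra.n_instances < min_instances or rb.n_instances < min_instances:
                continue
            stereo_rows.append(
                {
                    "bird_id": bird,
                    "sequence_id": f"{bird}:{context}",
                    "context": context,
                    "target": dom_a,
                    "delta_log10_gap": rb.log10_gap - ra.log10_gap,
                    "pct_gap_change": 100.0
                    * (rb.median_gap_ms - ra.median_gap_ms)
                    / ra.median_gap_ms,
                    "category": "stereotyped",
                }
            )
    return pd.DataFrame(change_rows), pd.DataFrame(stereo_rows)


def change_coupling_analysis(
    change_df: pd.DataFrame,
) -> tuple[MixedModelResult, MixedModelResult]:
    """Mixed models of gap change on probability change.

    Returns the fits for ``delta_log10_gap ~ delta_p`` and
    ``pct_gap_change ~ delta_p`` (both with the nested random structure).  A
    negative slope is the age-like coupled pattern; a flat slope the
    context-like decoupled pattern.
    """
    if len(change_df) < 3:
        raise ValueError(f"need >= 3 change records, got {len(change_df)}")
    if np.ptp(change_df["delta_p"].to_numpy(dtype=float)) == 0:
        raise ValueError("delta_p is constant; the change slope is undefined")
    fit_log = fit_coupling_model(
        change_df, response="delta_log10_gap", predictor="delta_p"
    )
    fit_pct = fit_coupling_model(
        change_df, response="pct_gap_change", predictor="delta_p"
    )
    return fit_log, fit_pct


@dataclass
class CategoryContrast:
    fit: MixedModelResult
    lsmeans: pd.DataFrame
    tukey: pd.DataFrame
    omnibus: dict
    levels: list[str]


def category_contrast(
    change_df: pd.DataFrame, stereotyped_df: pd.DataFrame
) -> CategoryContrast:
    """Percent gap change across transition categories.

    Fits ``pct_gap_change ~ category`` (levels: increased, decreased,
    unchanged branch transitions, plus stereotyped transitions) with the
    nested random structure, then compares category least-squares means with
    Tukey-Kramer adjustment.  Categories with fewer than two observations
    are dropped with a warning.
    """
    cols = ["bird_id", "sequence_id", "pct_gap_change", "category"]
    frames = [df[cols] for df in (change_df, stereotyped_df) if len(df)]
    if not frames:
        raise ValueError("no change records")
    data = pd.concat(frames, ignore_index=True)
    counts = data["category"].value_counts()
    drop = [c for c in counts.index if counts[c] < 2]
    if drop:
        warnings.warn(f"dropping categories with a single observation: {drop}")
        data = data[~data["category"].isin(drop)]
    levels = [c for c in CATEGORY_ORDER if c in set(data["category"])]
    if len(levels) < 2:
        raise ValueError("need >= 2 categories with >= 2 observations")
    X = np.column_stack(
        [np.ones(len(data))]
        + [(data["category"] == lev).to_numpy(dtype=float) for lev in levels[1:]]
    )
    names = ["intercept"] + [f"cat[{lev}]" for lev in levels[1:]]
    fit = fit_lmm(
        data["pct_gap_change"].to_numpy(dtype=float),
        X,
        {
            "bird": data["bird_id"].to_numpy(),
            "sequence": data["sequence_id"].to_numpy(),
        },
        fe_names=names,
    )
    k = len(levels)
    rows = {}
    for i, lev in enumerate(levels):
        l = np.zeros(k)
        l[0] = 1.0
        if i > 0:
            l[i] = 1.0
        rows[lev] = l
    L = np.zeros((k - 1, k))
    for i in range(1, k):
        L[i - 1, i] = 1.0
    return CategoryContrast(
        fit=fit,
        lsmeans=ls_means(fit, levels, rows),
        tukey=tukey_pairs(fit, levels, rows),
        omnibus=fit.ftest(L),
        levels=levels,
    )


# --------------------------------------------------------------------------
# distributional screening
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalityScreen:
    statistic: float
    pvalue: float
    log10_values: np.ndarray
    log_statistic: float
    log_pvalue: float
    #: True when the log10 transform left a sample consistent with normality
    normalized: bool


def screen_normality(values: np.ndarray, alpha: float = 0.05) -> NormalityScreen:
    """Shapiro-Wilk screen with the standing log10 transform.

    The log10 values are returned regardless of the raw test outcome (the
    transform is applied throughout for consistency across analyses);
    ``normalized`` records whether the transformed sample passes the screen.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("normality screen needs n >= 3")
    if (values <= 0).any():
        raise ValueError("log10 transform undefined for non-positive values")
    stat, p = shapiro(values)
    logs = np.log10(values)
    lstat, lp = shapiro(logs)
    return NormalityScreen(
        float(stat), float(p), logs, float(lstat), float(lp), bool(lp >= alpha)
    )
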