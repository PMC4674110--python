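"""Song syntax: transition counting, history dependence, branch points.

Branch points are contexts whose following syllable varies across
renditions; stereotyped sequences are those whose pairwise transitions
exceed 95%.  Transition probabilities exclude song terminations (a
rendition-final syllable contributes no outgoing transition).  History
dependence is resolved by a likelihood-ratio (G) test across predecessor
contexts: significantly different target distributions are analyzed
separately, otherwise predecessors are pooled.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import chi2

__all__ = [
    "TransitionTable",
    "BranchPoint",
    "LRTResult",
    "count_transitions",
    "lrt_context_dependence",
    "resolve_contexts",
    "exclude_repeats",
]

#: transitions above this probability mark a stereotyped sequence; the
#: comparison is strict (p == 0.95 is still a branch)
STEREOTYPED_THRESHOLD = 0.95
#: a context enters the analysis only with at least this many occurrences
MIN_OCCURRENCES = 10
#: pseudo-predecessor for transitions at fragment/rendition start
START = "^"
#: pseudo-predecessor collecting sparse contexts pooled before the LRT
OTHER = "*"


@dataclass
class TransitionTable:
    """Counts of observed transitions, per context order.

    ``counts[order][context][target]`` counts real transitions;
    ``terminations[order][context]`` counts rendition-final occurrences of
    the context, which are excluded from probability denominators.
    """

    counts: dict[int, dict[str, Counter]]
    terminations: dict[int, Counter]
    max_order: int

    def contexts(self, order: int = 1) -> list[str]:
        return sorted(self.counts.get(order, {}))

    def probabilities(self, context: str) -> dict[str, float]:
        """Termination-excluded target probabilities for a context."""
        order = len(context)
        targets = self.counts.get(order, {}).get(context)
        if not targets:
            return {}
        total = sum(targets.values())
        return {t: c / total for t, c in sorted(targets.items())}


@dataclass(frozen=True)
class LRTResult:
    g: float
    df: int
    pvalue: float


@dataclass
class BranchPoint:
    """A resolved context with its target transition statistics.

    ``context`` carries the predecessor when the history test split (e.g.
    ``"ad"``), the bare order-1 label when predecessors pooled.  ``targets``
    is ``[(label, count, probability)]`` with termination-excluded
    probabilities.  ``classification`` is ``"stereotyped"`` iff the maximum
    target probability strictly exceeds 95%, else ``"branch"``.
    """

    context: str
    targets: list[tuple[str, int, float]]
    n_occurrences: int
    n_transitions: int
    n_terminations: int
    classification: str
    split: bool
    lrt: LRTResult | None
    #: predecessor labels this (split) context covers; None when pooled
    predecessors: tuple[str, ...] | None = None
    bird_id: str = ""
    condition: str = ""

    @property
    def p_max(self) -> float:
        return max(p for _l, _c, p in self.targets)

    def probability(self, target: str) -> float | None:
        for lab, _c, p in self.targets:
            if lab == target:
                return p
        return None


def _fragments(rendition) -> list[list[str]]:
    if isinstance(rendition, str):
        return [list(rendition)]
    rendition = list(rendition)
    if not rendition:
        return [[]]
    if all(isinstance(x, str) and len(x) == 1 for x in rendition):
        # a flat list of single-character labels is one fragment
        return [rendition]
    return [list(f) for f in rendition]


def count_transitions(
    renditions: Iterable, max_context_order: int = 2
) -> TransitionTable:
    """Count adjacent transitions (and longer contexts up to
    ``max_context_order``) over a set of renditions.

    A rendition is a label string, a list of single-character labels, or a
    list of fragments (from :func:`exclude_repeats`); only the final
    fragment's last context increments termination counts.
    """
    counts: dict[int, dict[str, Counter]] = {
        k: defaultdict(Counter) for k in range(1, max_context_order + 1)
    }
    terms: dict[int, Counter] = {k: Counter() for k in range(1, max_context_order + 1)}
    for rend in renditions:
        frags = _fragments(rend)
        for fi, frag in enumerate(frags):
            labels = list(frag)
            terminal = fi == len(frags) - 1
            for order in range(1, max_context_order + 1):
                for i in range(len(labels) - order):
                    ctx = "".join(labels[i : i + order])
                    counts[order][ctx][labels[i + order]] += 1
                if terminal and len(labels) >= order:
                    terms[order]["".join(labels[-order:])] += 1
    return TransitionTable(
        {k: dict(v) for k, v in counts.items()}, terms, max_context_order
    )


def lrt_context_dependence(
    counts_by_context: Mapping[str, Mapping[str, int]],
) -> LRTResult:
    """Likelihood-ratio (G) test of whether target distributions differ
    across sequence contexts.

    ``G = 2 * sum obs * ln(obs / exp)`` with expectations from the pooled
    target distribution scaled to each context's total; zero observations
    contribute nothing; ``df = (n_contexts - 1) * (n_targets - 1)``.
    """
    contexts = [c for c, t in counts_by_context.items() if sum(t.values()) > 0]
    if len(contexts) < 2:
        raise ValueError("context-dependence test needs >= 2 non-empty contexts")
    targets = sorted({t for c in contexts for t in counts_by_context[c]})
    obs = np.array(
        [[counts_by_context[c].get(t, 0) for t in targets] for c in contexts],
        dtype=float,
    )
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row * col / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = float(2.0 * terms.sum())
    df = (len(contexts) - 1) * (len(targets) - 1)
    p = float(chi2.sf(g, df)) if df > 0 else 1.0
    return LRTResult(max(g, 0.0), df, p)


def resolve_contexts(
    table: TransitionTable,
    alpha: float = 0.05,
    min_occurrences: int = MIN_OCCURRENCES,
    stereotyped_threshold: float = STEREOTYPED_THRESHOLD,
    min_context_total: int = 5,
) -> list[BranchPoint]:
    """Resolve history dependence and build the branch-point list.

    For each order-1 context, target distributions are compared across its
    order-2 predecessor contexts (predecessors with fewer than
    ``min_context_total`` transitions are pooled into one sparse group
    first).  A significant G test splits the context per predecessor;
    otherwise predecessors pool.  Contexts with fewer than
    ``min_occurrences`` occurrences (transitions + terminations) are
    dropped, and the >95% rule classifies the survivors.
    """
    if table.max_order < 2:
        raise ValueError("resolve_contexts needs a table with max_context_order >= 2")
    out: list[BranchPoint] = []
    order1 = table.counts.get(1, {})
    order2 = table.counts.get(2, {})
    term1 = table.terminations.get(1, Counter())
    term2 = table.terminations.get(2, Counter())

    for ctx in sorted(order1):
        groups: dict[str, Counter] = {}
        accounted = Counter()
        for c2, targets in order2.items():
            if c2[1] == ctx:
                groups[c2[0]] = Counter(targets)
                accounted.update(targets)
        start = Counter(order1[ctx])
        start.subtract(accounted)
        start = Counter({t: c for t, c in start.items() if c > 0})
        if start:
            groups[START] = start

        # pool sparse predecessor groups before testing
        dense = {p: t for p, t in groups.items() if sum(t.values()) >= min_context_total}
        sparse_preds = [p for p, t in groups.items() if sum(t.values()) < min_context_total]
        test_groups = dict(dense)
        if sparse_preds:
            pooled_sparse = Counter()
            for pred in sparse_preds:
                pooled_sparse.update(groups[pred])
            if pooled_sparse:
                test_groups[OTHER] = pooled_sparse

        lrt = None
        split = False
        if len(test_groups) >= 2:
            lrt = lrt_context_dependence(test_groups)
            split = lrt.pvalue < alpha

        if split:
            pieces = []
            for pred, targets in sorted(test_groups.items()):
                label = pred + ctx
                if pred in (START, OTHER):
                    n_term = 0
                    preds = tuple(sparse_preds) if pred == OTHER else (START,)
                else:
                    n_term = term2.get(pred + ctx, 0)
                    preds = (pred,)
                pieces.append((label, targets, n_term, preds))
        else:
            pieces = [(ctx, Counter(order1[ctx]), term1.get(ctx, 0), None)]

        for label, targets, n_term, preds in pieces:
            n_trans = sum(targets.values())
            n_occ = n_trans + n_term
            if n_occ < min_occurrences or n_trans == 0:
                continue
            tgt_list = [
                (t, c, c / n_trans) for t, c in sorted(targets.items())
            ]
            p_max = max(p for _t, _c, p in tgt_list)
            out.append(
                BranchPoint(
                    context=label,
                    targets=tgt_list,
                    n_occurrences=n_occ,
                    n_transitions=n_trans,
                    n_terminations=n_term,
                    classification=(
                        "stereotyped" if p_max > stereotyped_threshold else "branch"
                    ),
                    split=split,
                    lrt=lrt,
                    predecessors=preds,
                )
            )
    return out


def exclude_repeats(renditions: Iterable) -> tuple[list[list[str]], set[str]]:
    """Flag labels repeated a variable number of times across renditions and
    carve their runs out of the analysis.

    A label whose maximal-run length varies across the corpus is flagged;
    transitions into, within, and out of flagged runs are excluded by
    splitting each rendition into fragments around those runs.  Fixed-length
    runs are kept verbatim.  Returns ``(fragmented renditions, flagged
    labels)``; each rendition becomes a list of label-list fragments that
    feeds :func:`count_transitions` directly.
    """
    rends = [list(r) for r in renditions]
    run_lengths: dict[str, set[int]] = defaultdict(set)
    for labels in rends:
        i = 0
        while i < len(labels):
            j = i
            while j < len(labels) and labels[j] == labels[i]:
                j += 1
            run_lengths[labels[i]].add(j - i)
            i = j
    flagged = {lab for lab, lengths in run_lengths.items() if len(lengths) > 1}

    out: list[list[list[str]]] = []
    for labels in rends:
        frags: list[list[str]] = []
        cur: list[str] = []
        i = 0
        while i < len(labels):
            j = i
            while j < len(labels) and labels[j] == labels[i]:
                j += 1
            if labels[i] in flagged:
                if cur:
                    frags.append(cur)
                    cur = []
            else:
                cur.extend(labels[i:j])
            i = j
        if cur:
            frags.append(cur)
        out.append(frags if frags else [[]])
    return out, flagged
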