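"""Covarying-pair evidence, layer decomposition, multilayer folding,
motif covariation support and control-based false-discovery estimates.

The primary evidence path is a tab-separated list of positive/negative
pairs with E-values produced by an external covariation analyzer.  A
simplified built-in statistic (average-product-corrected mutual
information, with empirical E-values from column-shuffled controls) is
available as an explicitly labeled stand-in; it approximates, but is not,
a full phylogenetically corrected covariation analysis.

Positive pairs are decomposed into layers, each the maximum-cardinality
mutually nested subset of what remains.  Layer 1 is folded with the
motif-extended grammar (forced pairs, forbidden negatives); later layers
use the simple stacking grammar and retain only helices containing at
least one of their covarying pairs, which is how pseudoknots and other
tertiary pairs enter the final structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .alignments import GAP_CHARS, MSA, NUC_INDEX, ColumnMap, ProbabilisticAlignment, shuffle_columns
from .fold import Constraints, MotifCall, ParseResult, cyk
from .grammar import Grammar

log = logging.getLogger(__name__)

DEFAULT_EVALUE_THRESHOLD = 0.05


@dataclass
class PairSet:
    """Covariation evidence in kept-column coordinates.

    ``positive`` holds (i, j, E-value) with E <= threshold; ``negative``
    holds (i, j) pairs with evidence against pairing.
    """

    positive: list[tuple[int, int, float]] = field(default_factory=list)
    negative: list[tuple[int, int]] = field(default_factory=list)
    threshold: float = DEFAULT_EVALUE_THRESHOLD

    def __post_init__(self):
        seen = set()
        for i, j, _e in self.positive:
            if i >= j:
                raise ValueError(f"pair ({i}, {j}) must have i < j")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair ({i}, {j})")
            seen.add((i, j))
        negs = set()
        for i, j in self.negative:
            if i >= j:
                raise ValueError(f"pair ({i}, {j}) must have i < j")
            if (i, j) in negs:
                raise ValueError(f"duplicate negative pair ({i}, {j})")
            negs.add((i, j))
        if {p[:2] for p in self.positive} & negs:
            raise ValueError("a pair is both positive and negative")

    @property
    def positive_pairs(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.positive}


def read_pairs(path, column_map: ColumnMap,
               threshold: float = DEFAULT_EVALUE_THRESHOLD) -> PairSet:
    """Read a pair TSV (columns: i, j, E-value, class) into kept coordinates.

    Coordinates in the file are 1-based original alignment columns; pairs
    touching gap-filtered columns are dropped with a warning.  Malformed
    rows and duplicates raise with the offending line number.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["i", "j", "evalue", "class"])
    except Exception as exc:
        raise ValueError(f"cannot parse pair file {path}: {exc}") from exc
    positive, negative = [], []
    for row_idx, row in df.iterrows():
        lineno = row_idx + 1
        try:
            i, j = int(row["i"]), int(row["j"])
            ev = float(row["evalue"])
            cls = str(row["class"]).strip().lower()
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
        if cls not in ("positive", "negative"):
            raise ValueError(f"{path}:{lineno}: class must be positive/negative")
        ki, kj = column_map.to_kept(i), column_map.to_kept(j)
        if ki is None or kj is None:
            log.warning("%s:%d: pair (%d, %d) touches a gap-filtered column; dropped",
                        path, lineno, i, j)
            continue
        if cls == "positive":
            positive.append((ki, kj, ev))
        else:
            negative.append((ki, kj))
    return PairSet(positive=positive, negative=negative, threshold=threshold)


# -------------------------------------------------------------------------
# stand-in covariation statistic

def _encode(msa: MSA, kept: np.ndarray) -> np.ndarray:
    """Integer-coded kept columns; gaps and ambiguity codes become -1."""
    out = np.full((msa.n_seq, len(kept)), -1, dtype=np.int8)
    for s, row in enumerate(msa.rows):
        for k, orig in enumerate(kept):
            ch = row[int(orig)]
            if ch in GAP_CHARS:
                continue
            idx = NUC_INDEX.get(ch)
            if idx is not None:
                out[s, k] = idx
    return out


def _apc_mi(coded: np.ndarray) -> np.ndarray:
    """Average-product-corrected mutual information over column pairs."""
    S, K = coded.shape
    mi = np.zeros((K, K))
    for i in range(K):
        ci = coded[:, i]
        for j in range(i + 1, K):
            cj = coded[:, j]
            ok = (ci >= 0) & (cj >= 0)
            n = int(ok.sum())
            if n < 2:
                continue
            joint = np.bincount((ci[ok] * 4 + cj[ok]).astype(int), minlength=16)
            joint = joint.reshape(4, 4) / n
            pi = joint.sum(axis=1)
            pj = joint.sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(joint > 0, joint / np.outer(pi, pj), 1.0)
                val = float(np.sum(np.where(joint > 0, joint * np.log(ratio), 0.0)))
            mi[i, j] = mi[j, i] = max(val, 0.0)
    row_mean = mi.sum(axis=1) / max(K - 1, 1)
    overall = mi.sum() / max(K * (K - 1), 1)
    if overall > 0:
        apc = np.outer(row_mean, row_mean) / overall
        mi = mi - apc
    np.fill_diagonal(mi, 0.0)
    return mi


def covariation_standin(
    pa: ProbabilisticAlignment, msa: MSA, n_shuffles: int = 100,
    seed: int = 0, threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> PairSet:
    """Approximate covariation analysis (not a phylogenetic method).

    Scores every kept-column pair with APC-corrected mutual information
    and assigns empirical E-values from the distribution of the maximum
    statistic over ``n_shuffles`` column-shuffled alignments.  Returns
    only positive pairs; negative-pair evidence requires the external
    analyzer path.
    """
    if msa.n_seq < 5:
        log.warning("stand-in covariation on %d sequences; results unreliable "
                    "below ~5", msa.n_seq)
    log.info("stand-in covariation statistic (APC mutual information); this "
             "approximates, and does not replace, a phylogenetic analysis")
    kept = pa.kept_columns
    coded = _encode(msa, kept)
    stat = _apc_mi(coded)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_shuffles)
    for t in range(n_shuffles):
        shuf = shuffle_columns(msa, int(rng.integers(2**31 - 1)))
        null_max[t] = _apc_mi(_encode(shuf, kept)).max()
    K = len(kept)
    positive = []
    for i in range(K):
        for j in range(i + 1, K):
            ev = (1 + int(np.sum(null_max >= stat[i, j]))) / (n_shuffles + 1)
            if ev <= threshold:
                positive.append((i, j, float(ev)))
    return PairSet(positive=positive, threshold=threshold)


# -------------------------------------------------------------------------
# layer decomposition

def max_nested_subset(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Maximum-cardinality mutually nested subset of ``pairs``.

    Interval dynamic program over pair endpoints; among equal-cardinality
    subsets the lexicographically smallest sorted pair list is returned,
    which makes the decomposition deterministic.
    """
    if not pairs:
        return []
    by_open: dict[int, list[int]] = {}
    for i, j in pairs:
        by_open.setdefault(i, []).append(j)
    lo = min(i for i, _ in pairs)
    hi = max(j for _, j in pairs)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> tuple[int, tuple]:
        if i > j:
            return (0, ())
        cand = [best(i + 1, j)]
        for k in sorted(by_open.get(i, [])):
            if k > j:
                continue
            c_in, p_in = best(i + 1, k - 1)
            c_out, p_out = best(k + 1, j)
            merged = tuple(sorted(((i, k),) + p_in + p_out))
            cand.append((1 + c_in + c_out, merged))
        # max count; ties -> lexicographically smallest pair tuple
        return max(cand, key=lambda cp: (cp[0], tuple(-x for p in cp[1] for x in p)))

    _count, chosen = best(lo, hi)
    best.cache_clear()
    return list(chosen)


def decompose_layers(pairset: PairSet) -> list[list[tuple[int, int]]]:
    """Split the positive pairs into layers of mutually nested pairs.

    Layer 1 is the maximum nested subset; the remainder is decomposed
    recursively until every positive pair is placed.
    """
    remaining = sorted(pairset.positive_pairs)
    layers = []
    while remaining:
        layer = max_nested_subset(remaining)
        if not layer:
            raise AssertionError("nested-subset search returned nothing")
        layers.append(sorted(layer))
        chosen = set(layer)
        remaining = [p for p in remaining if p not in chosen]
    return layers


# -------------------------------------------------------------------------
# multilayer folding

def find_helices(pairs) -> list[list[tuple[int, int]]]:
    """Maximal stacks of adjacent pairs; lone pairs count as helices."""
    pset = set(pairs)
    helices = []
    for i, j in sorted(pset):
        if (i - 1, j + 1) in pset:
            continue  # not outermost
        helix = [(i, j)]
        while (helix[-1][0] + 1, helix[-1][1] - 1) in pset:
            helix.append((helix[-1][0] + 1, helix[-1][1] - 1))
        helices.append(helix)
    return helices


def fold_multilayer(
    pa: ProbabilisticAlignment, main_grammar: Grammar, layer_grammar: Grammar,
    layers: list[list[tuple[int, int]]], negatives=(),
) -> ParseResult:
    """Fold layer 1 with the motif grammar and later layers with the
    stacking grammar.

    Layer 1 forces its nested covarying pairs and forbids the negatives.
    Each later layer forces its own pairs and additionally forbids every
    pair already placed; of its fold only helices containing at least one
    forced (covarying) pair are retained.  Overlaps between layers (a
    position paired in two layers) are reported in ``conflicts`` and left
    unresolved.
    """
    negatives = frozenset((int(i), int(j)) for i, j in negatives)
    layer1 = frozenset(map(tuple, layers[0])) if layers else frozenset()
    try:
        result = cyk(pa, main_grammar,
                     Constraints(forced_pairs=layer1, forbidden_pairs=negatives))
    except Exception as exc:
        raise type(exc)(f"layer 1: {exc}") from exc
    out_layers = [sorted(result.pairs)]
    placed = set(result.pairs)

    for idx, layer in enumerate(layers[1:], start=2):
        forced = frozenset(map(tuple, layer))
        forbidden = frozenset(negatives | placed) - forced
        try:
            lr = cyk(pa, layer_grammar,
                     Constraints(forced_pairs=forced, forbidden_pairs=forbidden))
        except Exception as exc:
            raise type(exc)(f"layer {idx} (pairs {sorted(forced)}): {exc}") from exc
        kept_pairs = []
        for helix in find_helices(lr.pairs):
            if any(p in forced for p in helix):
                kept_pairs.extend(helix)
        out_layers.append(sorted(kept_pairs))
        placed |= set(kept_pairs)

    # report positions paired in more than one layer
    conflicts = []
    seen_pos: dict[int, int] = {}
    for ln, layer in enumerate(out_layers, start=1):
        for i, j in layer:
            for p in (i, j):
                if p in seen_pos and seen_pos[p] != ln:
                    conflicts.append((p, seen_pos[p], ln))
                else:
                    seen_pos[p] = ln
    if conflicts:
        log.info("%d position(s) paired in more than one layer; left for "
                 "the user to assess", len(conflicts))
    return ParseResult(out_layers, result.motif_calls, result.log_prob,
                       conflicts=conflicts)


# -------------------------------------------------------------------------
# covariation support and FDR accounting

def _bounding_helices(call: MotifCall, helices) -> list[list[tuple[int, int]]]:
    s, e = call.span
    out = []
    for helix in helices:
        a, b = helix[0]       # outermost pair
        ai, bi = helix[-1]    # innermost pair
        if call.motif_class == "BS":
            # the two helices flanking the branch segment: any helix with
            # an outermost- or innermost-pair endpoint abutting the segment
            if {a, b, ai, bi} & {s - 1, e + 1}:
                out.append(helix)
            continue
        # closing helix: its innermost pair wraps the motif span
        if ai == s - 1 and bi == e + 1:
            out.append(helix)
        # enclosed helices: outermost pair inside the span
        elif s <= a and b <= e:
            out.append(helix)
    return out


def annotate_support(parse: ParseResult, pairset: PairSet) -> ParseResult:
    """Flag each motif call as covariation-supported.

    A motif is supported when at least one of its bounding helices (the
    helix closed by the loop's closing pair plus, for multibranch motifs,
    each enclosed helix; for branch segments the two flanking helices)
    contains one or more positive pairs.  Coordinates must be kept-column
    space on both sides.
    """
    if parse.one_based:
        raise ValueError("annotate_support expects kept-column coordinates")
    positives = pairset.positive_pairs
    helices = [h for layer in parse.layers for h in find_helices(layer)]
    calls = []
    for c in parse.motif_calls:
        bounding = _bounding_helices(c, helices)
        supported = any(p in positives for h in bounding for p in h)
        calls.append(MotifCall(c.name, c.variant_id, c.motif_class, c.attachment,
                               c.span, c.segments, c.log_score, supported))
    return ParseResult(parse.layers, calls, parse.log_prob,
                       one_based=parse.one_based, conflicts=list(parse.conflicts))


def fdr_report(
    n_real_supported: int, n_real_total: int,
    n_ctrl_supported: int, n_ctrl_total: int,
    evalue_threshold: float | None = None,
    n_ctrl_helices: int | None = None,
) -> dict:
    """False-discovery estimates from real and column-shuffled control runs.

    ``fdr_supported_pct`` = 100 * control supported / real supported;
    ``fdr_unsupported_pct`` compares the motifs lacking covariation
    support.  Zero denominators give ``None`` (undefined), not an
    exception.  When an E-value threshold and a control helix count are
    given, the expected number of null helices with a covarying pair
    (threshold * count) is included.
    """
    for name, value in (("n_real_supported", n_real_supported),
                        ("n_real_total", n_real_total),
                        ("n_ctrl_supported", n_ctrl_supported),
                        ("n_ctrl_total", n_ctrl_total)):
        if value < 0:
            raise ValueError(f"{name} must be >= 0")
    if n_real_supported > n_real_total or n_ctrl_supported > n_ctrl_total:
        raise ValueError("supported counts cannot exceed totals")

    def ratio(num: float, den: float) -> float | None:
        return 100.0 * num / den if den > 0 else None

    report = {
        "fdr_supported_pct": ratio(n_ctrl_supported, n_real_supported),
        "fdr_unsupported_pct": ratio(n_ctrl_total - n_ctrl_supported,
                                     n_real_total - n_real_supported),
        "n_real_supported": n_real_supported,
        "n_real_unsupported": n_real_total - n_real_supported,
        "n_ctrl_supported": n_ctrl_supported,
        "n_ctrl_unsupported": n_ctrl_total - n_ctrl_supported,
    }
    if evalue_threshold is not None and n_ctrl_helices is not None:
        report["expected_null_helices"] = evalue_threshold * n_ctrl_helices
    return report
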