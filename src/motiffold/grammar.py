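"""Folding grammars: RBG with explicit J3/J4 junctions, its 3D-motif
extension, and the simple stacking grammar used for pseudoknot layers.

The main grammar (``RBGJ3J4``) renders the classic RNA basic grammar with
three-way (J3) and four-way (J4) junctions singled out from higher-order
multiloops::

    S  -> a S | F0 S | eps
    F0 -> a F5 a' | a P a'            (pair emission)
    F5 -> a F5 a' | a P a'            (stacked-pair emission)
    P  -> m..m | m..m F0 | F0 m..m | m..m F0 m..m | J3 | J4 | JN
    J3 -> BB BB BT       J4 -> BB BB BB BT      JN -> BB BB BB M1 R
    M1 -> BB M1 | BB     BB -> m..m F0          BT, R -> m..m

``m..m`` is an unpaired run with a geometric length distribution over the
excess above the context minimum (3 for hairpin loops, 1 for bulge and
internal-loop strands, 0 for multiloop branches).  BB/BT are parameter-tied
to M1-branches/R in the plain grammar; they become distinct entities in the
motif-extended grammar, where the loop-bearing rules gain one alternative
per motif variant, with rule probability mass split off the generic rule by
class fraction and divided equally among the variants of the class
(maximum-entropy allocation).

Transition and emission parameters are trained by counting rule usages in
the unique derivations of annotated secondary structures (the grammar is
unambiguous, so each structure has exactly one derivation), with +1
pseudocounts.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .alignments import IUPAC, NUC_INDEX
from .motifs import MotifVariant
from .phmm import ProfileHMM, build_phmm

log = logging.getLogger(__name__)

NEG_INF = float("-inf")

#: rules per nonterminal of the main grammar
RBG_RULES: dict[str, tuple[str, ...]] = {
    "S": ("aS", "F0S", "end"),
    "F0": ("aF5a", "aPa"),
    "F5": ("aF5a", "aPa"),
    "P": ("hp", "bl", "br", "il", "J3", "J4", "JN"),
    "J3": ("generic",),
    "J4": ("generic",),
    "JN": ("generic",),
    "M1": ("more", "last"),
    "BB": ("generic",),
    "BT": ("generic",),
    "R": ("generic",),
}

#: rules of the simple stacking grammar used for layers >= 2
G6X_RULES: dict[str, tuple[str, ...]] = {
    "S6": ("LS", "L"),
    "L6": ("pair", "a"),
    "F6": ("pair", "LS"),
}

#: minimum unpaired-run length by context
RUN_MIN = {"hp": 3, "bulge": 1, "il": 1, "branch": 0}

#: default motif-class fractions (HL, BL, IL, J3, J4, BS)
DEFAULT_CLASS_FRACTIONS = {
    "HL": 0.4, "BL": 0.4, "IL": 0.5, "J3": 0.2, "J4": 0.2, "BS": 0.2,
}

#: default three-way / four-way / higher multiloop split of trained
#: multiloop mass (junction frequencies in diverse known structures)
DEFAULT_MULTILOOP_SPLIT = (0.51, 0.32, 0.17)

PARAM_SCHEMA_VERSION = 1


def _uniform_transitions(rules: dict[str, tuple[str, ...]]) -> dict[str, dict[str, float]]:
    return {nt: {r: 1.0 / len(rs) for r in rs} for nt, rs in rules.items()}


@dataclass
class ParamSet:
    """All probabilities of the folding grammars.

    ``transitions`` covers the main grammar, ``layer_transitions`` the
    pseudoknot-layer grammar.  Emission tables: ``emis_single`` (4,),
    ``emis_pair`` (4,4) and ``emis_stack`` (4,4,4,4) holding
    P(inner pair | enclosing pair).
    """

    transitions: dict[str, dict[str, float]] = field(
        default_factory=lambda: _uniform_transitions(RBG_RULES))
    layer_transitions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "S6": {"LS": 0.5, "L": 0.5},
            "L6": {"pair": 0.2, "a": 0.8},
            "F6": {"pair": 0.7, "LS": 0.3},
        })
    emis_single: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    emis_pair: np.ndarray = field(default_factory=lambda: np.full((4, 4), 1 / 16))
    emis_stack: np.ndarray = field(
        default_factory=lambda: np.full((4, 4, 4, 4), 1 / 16))
    q_loop: float = 0.7  # geometric excess parameter of unpaired runs
    f_class: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    epsilon: float = 1e-4
    insert_em: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    max_loop_run: int = 30      # cap on generic bulge/internal-loop strands
    motif_seg_extra: int = 8    # motif segment length cap = consensus + extra

    def validate(self) -> None:
        for table, rules in ((self.transitions, RBG_RULES),
                             (self.layer_transitions, G6X_RULES)):
            for nt, expected in rules.items():
                probs = table[nt]
                if set(probs) != set(expected):
                    raise ValueError(f"nonterminal {nt}: rules {set(probs)} != {set(expected)}")
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-9 or min(probs.values()) < 0:
                    raise ValueError(f"nonterminal {nt}: probabilities sum to {total}")
        for arr, shape in ((self.emis_single, (4,)), (self.emis_pair, (4, 4))):
            if abs(float(np.sum(arr)) - 1.0) > 1e-9:
                raise ValueError("emission table not normalized")
        stack = np.asarray(self.emis_stack).reshape(16, 16)
        if np.any(np.abs(stack.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("stacked emission table not normalized")
        if not 0 < self.q_loop < 1:
            raise ValueError("q_loop must be in (0, 1)")
        for cls, f in self.f_class.items():
            if not 0 <= f <= 1:
                raise ValueError(f"class fraction {cls}={f} outside [0, 1]")

    @property
    def multiloop_split(self) -> tuple[float, float, float]:
        p = self.transitions["P"]
        tot = p["J3"] + p["J4"] + p["JN"]
        if tot == 0:
            return (0.0, 0.0, 0.0)
        return (p["J3"] / tot, p["J4"] / tot, p["JN"] / tot)

    def set_multiloop_split(self, p_j3: float, p_j4: float, p_jn: float) -> None:
        """Redistribute the trained multiloop mass over J3/J4/higher."""
        if abs(p_j3 + p_j4 + p_jn - 1.0) > 1e-9:
            raise ValueError("multiloop split must sum to 1")
        p = self.transitions["P"]
        tot = p["J3"] + p["J4"] + p["JN"]
        p["J3"], p["J4"], p["JN"] = tot * p_j3, tot * p_j4, tot * p_jn

    def copy(self) -> "ParamSet":
        return ParamSet.from_dict(self.to_dict())

    def to_dict(self) -> dict:
        return {
            "schema_version": PARAM_SCHEMA_VERSION,
            "transitions": {nt: dict(r) for nt, r in self.transitions.items()},
            "layer_transitions": {nt: dict(r) for nt, r in self.layer_transitions.items()},
            "emis_single": self.emis_single.tolist(),
            "emis_pair": self.emis_pair.tolist(),
            "emis_stack": np.asarray(self.emis_stack).tolist(),
            "q_loop": self.q_loop,
            "f_class": dict(self.f_class),
            "epsilon": self.epsilon,
            "insert_em": self.insert_em.tolist(),
            "max_loop_run": self.max_loop_run,
            "motif_seg_extra": self.motif_seg_extra,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParamSet":
        if d.get("schema_version") != PARAM_SCHEMA_VERSION:
            raise ValueError(f"unsupported parameter schema {d.get('schema_version')}")
        return cls(
            transitions={nt: dict(r) for nt, r in d["transitions"].items()},
            layer_transitions={nt: dict(r) for nt, r in d["layer_transitions"].items()},
            emis_single=np.array(d["emis_single"]),
            emis_pair=np.array(d["emis_pair"]),
            emis_stack=np.array(d["emis_stack"]),
            q_loop=d["q_loop"],
            f_class=dict(d["f_class"]),
            epsilon=d["epsilon"],
            insert_em=np.array(d["insert_em"]),
            max_loop_run=d["max_loop_run"],
            motif_seg_extra=d["motif_seg_extra"],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParamSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def split_loop_probability(
    p_generic: float, f_class: float, n_motifs: int
) -> tuple[float, float]:
    """Split a generic loop-rule probability with a motif-class fraction.

    Returns ``(p_generic_kept, p_per_motif)`` with
    ``p_generic_kept = p_generic * (1 - f_class)`` and the remaining class
    mass divided equally over the ``n_motifs`` motifs; with no motifs the
    class mass returns to the generic rule.  Total mass is conserved.
    """
    if not 0 <= f_class <= 1:
        raise ValueError("f_class must be in [0, 1]")
    if n_motifs < 0:
        raise ValueError("n_motifs must be >= 0")
    if n_motifs == 0 or f_class == 0.0:
        return p_generic, 0.0
    return p_generic * (1.0 - f_class), p_generic * f_class / n_motifs


@dataclass
class MotifRule:
    """One motif alternative grafted onto a loop-bearing rule."""

    variant: MotifVariant
    log_prob: float
    #: ProfileHMMs per chain, aligned with ``variant.chains``
    phmm_chains: tuple[tuple[ProfileHMM, ...], ...]


class Grammar:
    """A concrete folding grammar: transitions in log space, emission
    tables, and (for the motif-extended grammar) motif rules grouped by
    the loop rule they extend."""

    def __init__(self, kind: str, paramset: ParamSet,
                 variants: list[MotifVariant] | None = None):
        paramset.validate()
        self.kind = kind
        self.paramset = paramset
        self.variants = variants or []
        trans = paramset.layer_transitions if kind == "G6X" else paramset.transitions
        with np.errstate(divide="ignore"):
            self.log_t = {
                (nt, rule): float(np.log(p)) if p > 0 else NEG_INF
                for nt, rules in trans.items() for rule, p in rules.items()
            }
            self.log_single = np.log(paramset.emis_single)
            self.log_pair = np.log(paramset.emis_pair)
            self.log_stack = np.log(np.asarray(paramset.emis_stack))
            self.log_q = math.log(paramset.q_loop)
            self.log_1mq = math.log1p(-paramset.q_loop)
        #: attachment point -> list of MotifRule
        self.motif_rules: dict[str, list[MotifRule]] = {
            k: [] for k in ("HL", "BL_left", "BL_right", "IL", "J3", "J4", "BS_BB", "BS_BT")
        }
        if self.variants:
            self._graft_motifs()

    # -- construction -----------------------------------------------------

    def _graft_motifs(self) -> None:
        ps = self.paramset
        by_attach: dict[str, list[MotifVariant]] = {}
        for v in self.variants:
            by_attach.setdefault(v.attachment, []).append(v)
        phmm_cache: dict[str, tuple[tuple[ProfileHMM, ...], ...]] = {}

        def chains_for(v: MotifVariant):
            if v.unique_id not in phmm_cache:
                phmm_cache[v.unique_id] = tuple(
                    tuple(build_phmm(cons, epsilon=ps.epsilon, insert_em=ps.insert_em)
                          for _, cons in chain)
                    for chain in v.chains
                )
            return phmm_cache[v.unique_id]

        def split(nt: str, rule: str, attach: str, slot: str, cls: str) -> None:
            vs = by_attach.get(attach, [])
            p_gen = math.exp(self.log_t[(nt, rule)]) if self.log_t[(nt, rule)] > NEG_INF else 0.0
            kept, per = split_loop_probability(p_gen, ps.f_class[cls], len(vs))
            with np.errstate(divide="ignore"):
                self.log_t[(nt, rule)] = float(np.log(kept)) if kept > 0 else NEG_INF
                log_per = float(np.log(per)) if per > 0 else NEG_INF
            for v in vs:
                self.motif_rules[slot].append(MotifRule(v, log_per, chains_for(v)))

        split("P", "hp", "HL", "HL", "HL")
        split("P", "bl", "BL_left", "BL_left", "BL")
        split("P", "br", "BL_right", "BL_right", "BL")
        split("P", "il", "IL", "IL", "IL")
        split("J3", "generic", "J3", "J3", "J3")
        split("J4", "generic", "J4", "J4", "J4")
        split("BB", "generic", "BS", "BS_BB", "BS")
        split("BT", "generic", "BS", "BS_BT", "BS")

    # -- introspection ----------------------------------------------------

    @property
    def nonterminal_count(self) -> int:
        if self.kind == "G6X":
            return len(G6X_RULES)
        return len(RBG_RULES) + len(self.variants)

    def run_log_prob(self, length: int, context: str) -> float:
        """Log probability of an unpaired run of ``length`` residues
        (length distribution only; residue emissions are scored per
        column by the engine)."""
        m = RUN_MIN[context]
        if length < m:
            return NEG_INF
        return self.log_1mq + (length - m) * self.log_q


def build_rbgj3j4(paramset: ParamSet) -> Grammar:
    """The main grammar without motif rules."""
    return Grammar("RBGJ3J4", paramset)


def build_r3d_grammar(
    rbgj3j4: Grammar, variants: list[MotifVariant],
    paramset: ParamSet | None = None,
) -> Grammar:
    """Extend the main grammar with one rule per motif variant.

    Loop-rule probabilities are split by class fraction and shared equally
    among the variants attaching at that rule; total rule mass leaving
    each loop rule is conserved.  Profile HMMs are built for every
    segment of every variant.
    """
    ps = paramset if paramset is not None else rbgj3j4.paramset
    log.info("building motif grammar with %d nonredundant variants", len(variants))
    return Grammar("RBGJ3J4-R3D", ps, variants=list(variants))


def build_layer_grammar(paramset: ParamSet) -> Grammar:
    """The simple stacking grammar used for folding layers >= 2:
    S6 -> L6 S6 | L6;  L6 -> a F6 a' | a;  F6 -> a F6 a' (stacked) | L6 S6.
    """
    return Grammar("G6X", paramset)


# -- structure annotation utilities ---------------------------------------

def parse_dotbracket(struct: str) -> set[tuple[int, int]]:
    """Nested dot-bracket (round or angle brackets) -> 0-based pair set."""
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for k, ch in enumerate(struct):
        if ch in "(<[":
            stack.append(k)
        elif ch in ")>]":
            if not stack:
                raise ValueError(f"unbalanced structure at column {k + 1}")
            pairs.add((stack.pop(), k))
        elif ch not in ".,:_-~":
            raise ValueError(f"unexpected structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced structure: unclosed bracket")
    return pairs


class _Counts:
    def __init__(self) -> None:
        self.trans = {nt: {r: 0 for r in rules} for nt, rules in RBG_RULES.items()}
        self.single = np.zeros(4)
        self.pair = np.zeros((4, 4))
        self.stack = np.zeros((4, 4, 4, 4))
        self.n_runs = 0
        self.run_excess = 0


def _residue_weights(ch: str) -> list[tuple[int, float]]:
    residues = IUPAC[ch]
    return [(NUC_INDEX[r], 1.0 / len(residues)) for r in residues]


def derivation_counts(seq: str, pairs, counts: _Counts) -> None:
    """Accumulate rule/emission counts of the unique derivation of a
    nested structure under the main grammar."""
    seq = seq.upper().replace("T", "U")
    partner: dict[int, int] = {}
    for i, j in pairs:
        if i >= j:
            raise ValueError("pairs must satisfy i < j")
        if i in partner or j in partner:
            raise ValueError("position in two pairs")
        partner[i] = j
        partner[j] = i
    # check nestedness
    plist = sorted((min(i, j), max(i, j)) for i, j in pairs)
    for a, b in plist:
        for c, d in plist:
            if a < c < b < d:
                raise ValueError("crossing pairs are not a valid nested structure")

    def count_single(k: int) -> None:
        for idx, w in _residue_weights(seq[k]):
            counts.single[idx] += w

    def count_pair(i: int, j: int) -> None:
        for ia, wa in _residue_weights(seq[i]):
            for ib, wb in _residue_weights(seq[j]):
                counts.pair[ia, ib] += wa * wb

    def count_stack(i: int, j: int, oi: int, oj: int) -> None:
        for ia, wa in _residue_weights(seq[i]):
            for ib, wb in _residue_weights(seq[j]):
                for oa, woa in _residue_weights(seq[oi]):
                    for ob, wob in _residue_weights(seq[oj]):
                        counts.stack[oa, ob, ia, ib] += wa * wb * woa * wob

    def count_run(i: int, j: int, context: str) -> None:
        # unpaired run covering columns [i, j)
        length = j - i
        m = RUN_MIN[context]
        if length < m:
            raise ValueError(f"{context} run of {length} < minimum {m}")
        counts.n_runs += 1
        counts.run_excess += length - m
        for k in range(i, j):
            count_single(k)

    def top_level_children(i: int, j: int) -> list[tuple[int, int]]:
        out = []
        k = i
        while k <= j:
            if k in partner and partner[k] > k:
                out.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return out

    def walk_S(i: int, j: int) -> None:  # span [i, j)
        k = i
        while k < j:
            if k in partner:
                counts.trans["S"]["F0S"] += 1
                walk_F0(k, partner[k])
                k = partner[k] + 1
            else:
                counts.trans["S"]["aS"] += 1
                count_single(k)
                k += 1
        counts.trans["S"]["end"] += 1

    def walk_F0(i: int, j: int) -> None:  # (i, j) is a pair
        count_pair(i, j)
        if partner.get(i + 1) == j - 1:
            counts.trans["F0"]["aF5a"] += 1
            walk_F5(i + 1, j - 1)
        else:
            counts.trans["F0"]["aPa"] += 1
            walk_P(i + 1, j - 1)

    def walk_F5(i: int, j: int) -> None:  # (i, j) is a stacked pair
        count_stack(i, j, i - 1, j + 1)
        if partner.get(i + 1) == j - 1:
            counts.trans["F5"]["aF5a"] += 1
            walk_F5(i + 1, j - 1)
        else:
            counts.trans["F5"]["aPa"] += 1
            walk_P(i + 1, j - 1)

    def walk_P(i: int, j: int) -> None:  # span [i, j] inclusive, j >= i
        children = top_level_children(i, j)
        k = len(children)
        if k == 0:
            counts.trans["P"]["hp"] += 1
            count_run(i, j + 1, "hp")
            return
        if k == 1:
            (a, b), = children
            left, right = a - i, j - b
            if left > 0 and right == 0:
                counts.trans["P"]["bl"] += 1
                count_run(i, a, "bulge")
            elif left == 0 and right > 0:
                counts.trans["P"]["br"] += 1
                count_run(b + 1, j + 1, "bulge")
            elif left > 0 and right > 0:
                counts.trans["P"]["il"] += 1
                count_run(i, a, "il")
                count_run(b + 1, j + 1, "il")
            else:
                raise ValueError("helix continuation must go through F5, not P")
            walk_F0(a, b)
            return
        # multiloop
        def walk_BB(prev_end: int, child: tuple[int, int]) -> None:
            counts.trans["BB"]["generic"] += 1
            count_run(prev_end, child[0], "branch")
            walk_F0(*child)

        if k == 2:
            counts.trans["P"]["J3"] += 1
            counts.trans["J3"]["generic"] += 1
        elif k == 3:
            counts.trans["P"]["J4"] += 1
            counts.trans["J4"]["generic"] += 1
        else:
            counts.trans["P"]["JN"] += 1
            counts.trans["JN"]["generic"] += 1
        pos = i
        n_bb = k if k <= 3 else k  # all children are BB branches
        for idx, child in enumerate(children):
            if k >= 4 and idx >= 3:
                counts.trans["M1"]["more" if idx < k - 1 else "last"] += 1
            walk_BB(pos, child)
            pos = child[1] + 1
        tail_nt = "R" if k >= 4 else "BT"
        counts.trans[tail_nt]["generic"] += 1
        count_run(pos, j + 1, "branch")

    walk_S(0, len(seq))


def train_by_counting(annotated: list[tuple[str, object]]) -> ParamSet:
    """Maximum-likelihood parameters (with +1 pseudocounts) from annotated
    structures.

    ``annotated`` holds ``(sequence, pairs)`` items where ``pairs`` is an
    iterable of 0-based (i, j) base pairs or a dot-bracket string.  The
    grammar is unambiguous, so each structure determines one derivation
    whose rule usages are counted.  An empty training set yields the
    pseudocount-only (uniform) parameters with a warning.
    """
    counts = _Counts()
    for seq, struct in annotated:
        pairs = parse_dotbracket(struct) if isinstance(struct, str) else set(struct)
        derivation_counts(seq, pairs, counts)
    if not annotated:
        log.warning("empty training set: returning pseudocount-only parameters")

    ps = ParamSet()
    for nt, rules in RBG_RULES.items():
        used = counts.trans[nt]
        total = sum(used.values()) + len(rules)
        ps.transitions[nt] = {r: (used[r] + 1) / total for r in rules}
    ps.emis_single = (counts.single + 1) / (counts.single.sum() + 4)
    ps.emis_pair = (counts.pair + 1) / (counts.pair.sum() + 16)
    stack = counts.stack.reshape(16, 16) + 1
    ps.emis_stack = (stack / stack.sum(axis=1, keepdims=True)).reshape(4, 4, 4, 4)
    # geometric excess parameter, lightly smoothed away from 0/1
    ps.q_loop = (counts.run_excess + 1) / (counts.run_excess + counts.n_runs + 2)
    ps.validate()
    return ps


def sample_parse(
    paramset: ParamSet, rng: np.random.Generator, max_len: int = 2000
) -> tuple[str, set[tuple[int, int]], dict[tuple[str, str], int]]:
    """Sample one derivation from the main grammar.

    Returns ``(sequence, pairs, rule_usage_counts)``.  Raises
    ``RuntimeError`` if the derivation exceeds ``max_len`` residues
    (callers resample).
    """
    trans = paramset.transitions
    used: dict[tuple[str, str], int] = {}
    seq: list[str] = []
    pairs: set[tuple[int, int]] = set()
    nucs = "ACGU"

    def pick(nt: str) -> str:
        rules = list(trans[nt])
        probs = np.array([trans[nt][r] for r in rules])
        rule = rules[rng.choice(len(rules), p=probs / probs.sum())]
        used[(nt, rule)] = used.get((nt, rule), 0) + 1
        return rule

    def emit_single() -> None:
        seq.append(nucs[rng.choice(4, p=paramset.emis_single)])
        if len(seq) > max_len:
            raise RuntimeError("sampled derivation too long")

    def emit_run(context: str) -> None:
        length = RUN_MIN[context] + rng.geometric(1.0 - paramset.q_loop) - 1
        for _ in range(length):
            emit_single()

    def gen_S() -> None:
        while True:
            rule = pick("S")
            if rule == "end":
                return
            if rule == "aS":
                emit_single()
            else:
                gen_F(None)

    def gen_F(outer: tuple[int, str] | None) -> None:
        # outer = (left column, right residue) of the enclosing pair, for
        # conditioning stacked emissions
        nt = "F0" if outer is None else "F5"
        rule = pick(nt)
        if outer is None:
            flat = rng.choice(16, p=paramset.emis_pair.ravel())
        else:
            oa = NUC_INDEX[seq[outer[0]]]
            ob = NUC_INDEX[outer[1]]
            cond = np.asarray(paramset.emis_stack)[oa, ob].ravel()
            flat = rng.choice(16, p=cond / cond.sum())
        i = len(seq)
        seq.append(nucs[flat // 4])
        right_char = nucs[flat % 4]
        if rule == "aF5a":
            gen_F((i, right_char))
        else:
            gen_P()
        j = len(seq)
        seq.append(right_char)
        pairs.add((i, j))
        if len(seq) > max_len:
            raise RuntimeError("sampled derivation too long")

    def gen_BB() -> None:
        used[("BB", "generic")] = used.get(("BB", "generic"), 0) + 1
        emit_run("branch")
        gen_F(None)

    def gen_P() -> None:
        rule = pick("P")
        if rule == "hp":
            emit_run("hp")
        elif rule == "bl":
            emit_run("bulge")
            gen_F(None)
        elif rule == "br":
            gen_F(None)
            emit_run("bulge")
        elif rule == "il":
            emit_run("il")
            gen_F(None)
            emit_run("il")
        elif rule in ("J3", "J4"):
            pick(rule)  # the single generic junction rule
            n = 2 if rule == "J3" else 3
            for _ in range(n):
                gen_BB()
            used[("BT", "generic")] = used.get(("BT", "generic"), 0) + 1
            emit_run("branch")
        else:  # JN
            pick("JN")
            for _ in range(3):
                gen_BB()
            while True:
                m_rule = pick("M1")
                gen_BB()
                if m_rule == "last":
                    break
            used[("R", "generic")] = used.get(("R", "generic"), 0) + 1
            emit_run("branch")

    gen_S()
    return "".join(seq), pairs, used


_TRAIN_CACHE: ParamSet | None = None


def load_training_structures() -> list[tuple[str, str]]:
    """The bundled (sequence, structure) training set; see the data file
    header for provenance."""
    text = resources.files("motiffold.data").joinpath(
        "train_structures_synthetic.txt").read_text()
    out = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        _name, seq, struct = line.split()
        if len(seq) != len(struct):
            raise ValueError(f"training record {_name}: sequence/structure length mismatch")
        out.append((seq, struct))
    return out


def default_params() -> ParamSet:
    """Default parameters: trained by counting on the bundled structure
    set, with the multiloop mass re-split to the junction frequencies
    observed in large curated structure collections (51% J3, 32% J4)."""
    global _TRAIN_CACHE
    if _TRAIN_CACHE is None:
        ps = train_by_counting(load_training_structures())
        ps.set_multiloop_split(*DEFAULT_MULTILOOP_SPLIT)
        ps.validate()
        _TRAIN_CACHE = ps
    return _TRAIN_CACHE.copy()
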