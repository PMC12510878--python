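"""Constrained CYK and inside algorithms over a probabilistic alignment.

The dynamic program fills one table per grammar nonterminal over half-open
column spans ``[i, j)`` of the kept columns.  Pair emissions mix the 4x4
joint column-pair frequencies with the grammar's pair table; unpaired and
motif-segment emissions mix the per-column 4-vectors; on an S=1 alignment
everything reduces to plain single-sequence scoring.

Covariation constraints enter as hard masks: a forced pair's two columns
may pair only with each other and may not be emitted unpaired (so every
finite-score derivation contains the pair); forbidden pairs and unpairable
positions score ``-inf`` as pair emissions.  If no derivation survives the
masks the fold raises :class:`InfeasibleError`.

``enumerate_derivations`` is a brute-force oracle that lists every
derivation of a small input with its log probability, pair set and motif
annotation; it shares only the grammar definition with the DP and is used
to verify both the max (CYK) and sum (inside) recursions and the grammar's
unambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignments import ColumnMap, ProbabilisticAlignment, point_mass_alignment
from .grammar import Grammar, MotifRule, RUN_MIN
from .phmm import SegmentScorer, forward

NEG_INF = float("-inf")


class InfeasibleError(RuntimeError):
    """No derivation satisfies the constraints."""


@dataclass
class Constraints:
    """Hard pairing constraints for one folding layer.

    ``forced_pairs`` must all appear (mutually nested within the layer);
    ``forbidden_pairs`` must not appear; ``unpairable`` positions may not
    pair at all.  Coordinates are kept-column indices, i < j.
    """

    forced_pairs: frozenset = frozenset()
    forbidden_pairs: frozenset = frozenset()
    unpairable: frozenset = frozenset()

    def __post_init__(self):
        self.forced_pairs = frozenset((int(i), int(j)) for i, j in self.forced_pairs)
        self.forbidden_pairs = frozenset((int(i), int(j)) for i, j in self.forbidden_pairs)
        self.unpairable = frozenset(int(p) for p in self.unpairable)
        seen: dict[int, tuple[int, int]] = {}
        for i, j in self.forced_pairs:
            if i >= j:
                raise ValueError(f"forced pair ({i}, {j}) must have i < j")
            for p in (i, j):
                if p in seen:
                    raise ValueError(f"position {p} in two forced pairs")
                seen[p] = (i, j)
        if self.forced_pairs & self.forbidden_pairs:
            raise InfeasibleError("a pair is both forced and forbidden")
        plist = sorted(self.forced_pairs)
        for a, b in plist:
            for c, d in plist:
                if a < c < b < d:
                    raise ValueError(
                        f"forced pairs ({a},{b}) and ({c},{d}) cross; "
                        "split them into separate layers")

    @property
    def forced_partner(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.forced_pairs:
            out[i] = j
            out[j] = i
        return out


@dataclass
class MotifCall:
    """One predicted 3D motif instance."""

    name: str
    variant_id: str
    motif_class: str
    attachment: str
    span: tuple[int, int]                       # inclusive ends
    segments: tuple[tuple[str, int, int], ...]  # (segment name, start, end) inclusive
    log_score: float
    supported: bool | None = None


@dataclass
class ParseResult:
    """Structure prediction: per-layer pair lists plus motif calls.

    Coordinates are kept-column indices until :meth:`mapped` converts them
    to 1-based original alignment columns (``one_based`` records which).
    """

    layers: list[list[tuple[int, int]]]
    motif_calls: list[MotifCall]
    log_prob: float
    one_based: bool = False
    conflicts: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return self.layers[0] if self.layers else []

    def all_pairs(self) -> list[tuple[int, int]]:
        return [p for layer in self.layers for p in layer]

    def mapped(self, colmap: ColumnMap) -> "ParseResult":
        if self.one_based:
            raise ValueError("already in original coordinates")
        layers = [
            sorted((colmap.to_original(i), colmap.to_original(j)) for i, j in layer)
            for layer in self.layers
        ]
        calls = []
        for c in self.motif_calls:
            segs = tuple(
                (n, colmap.to_original(s), colmap.to_original(e))
                for n, s, e in c.segments if s <= e
            )
            calls.append(MotifCall(
                c.name, c.variant_id, c.motif_class, c.attachment,
                (colmap.to_original(c.span[0]), colmap.to_original(c.span[1])),
                segs, c.log_score, c.supported))
        return ParseResult(layers, calls, self.log_prob, one_based=True,
                           conflicts=list(self.conflicts))


# -------------------------------------------------------------------------
# shared emission precomputation

class _Scores:
    """Per-input emission scores with the constraint masks applied."""

    def __init__(self, pa: ProbabilisticAlignment, grammar: Grammar,
                 constraints: Constraints):
        L = pa.L
        self.L = L
        self.grammar = grammar
        cols = pa.single
        forced = np.zeros(L, dtype=bool)
        partner = constraints.forced_partner
        for p in partner:
            if p < 0 or p >= L:
                raise ValueError(f"constraint position {p} outside alignment")
            forced[p] = True
        self.forced = forced
        self.cols = cols

        with np.errstate(divide="ignore"):
            u = np.log(cols @ grammar.paramset.emis_single)
        u[forced] = NEG_INF
        self.u = u
        bad = forced | ~np.isfinite(u)
        self.bad_prefix = np.concatenate(([0], np.cumsum(bad)))
        usafe = np.where(np.isfinite(u), u, 0.0)
        self.u_prefix = np.concatenate(([0.0], np.cumsum(usafe)))

        # steric floor: every pair encloses >= 3 columns (the terminal
        # hairpin loop), in all grammars; forced pairs are exempt
        min_enclosed = 3
        pair_t = grammar.paramset.emis_pair
        stack_t = np.asarray(grammar.paramset.emis_stack).reshape(16, 16)
        PS = np.full((L, L), NEG_INF)
        SS = np.full((L, L), NEG_INF)
        forbidden = constraints.forbidden_pairs
        unpairable = constraints.unpairable
        for i in range(L):
            for j in range(i + 1, L):
                if (i, j) in forbidden or i in unpairable or j in unpairable:
                    continue
                if partner.get(i, j) != j or partner.get(j, i) != i:
                    continue
                if j - i - 1 < min_enclosed and (i, j) not in constraints.forced_pairs:
                    continue
                F = pa.pair_freq(i, j)
                val = float(F.ravel() @ pair_t.ravel())
                PS[i, j] = math.log(val) if val > 0 else NEG_INF
                if i >= 1 and j <= L - 2:
                    Fout = pa.pair_freq(i - 1, j + 1)
                    sval = float(Fout.ravel() @ (stack_t @ F.ravel()))
                    SS[i, j] = math.log(sval) if sval > 0 else NEG_INF
        self.PS = PS
        self.SS = SS

        # run length log-probabilities per context, indexed by length
        self.runlen = {}
        for ctx, m in RUN_MIN.items():
            arr = np.full(L + 1, NEG_INF)
            for w in range(m, L + 1):
                arr[w] = grammar.run_log_prob(w, ctx)
            self.runlen[ctx] = arr

    def run(self, i: int, j: int, ctx: str) -> float:
        """Score of an unpaired run over columns [i, j)."""
        if self.bad_prefix[j] - self.bad_prefix[i] > 0:
            return NEG_INF
        return float(self.runlen[ctx][j - i] + self.u_prefix[j] - self.u_prefix[i])

    def run_vector(self, i: int, lmax: int, ctx: str) -> np.ndarray:
        """Vector over l = 0..lmax of run scores for columns [i, i+l)."""
        ls = np.arange(lmax + 1)
        out = self.runlen[ctx][ls] + (self.u_prefix[i + ls] - self.u_prefix[i])
        out = np.where(self.bad_prefix[i + ls] - self.bad_prefix[i] > 0, NEG_INF, out)
        return out

    def run_vector_end(self, j: int, lmax: int, ctx: str) -> np.ndarray:
        """Vector over l = 0..lmax of run scores for columns [j-l, j)."""
        ls = np.arange(lmax + 1)
        out = self.runlen[ctx][ls] + (self.u_prefix[j] - self.u_prefix[j - ls])
        out = np.where(self.bad_prefix[j] - self.bad_prefix[j - ls] > 0, NEG_INF, out)
        return out


class ChainScorer:
    """Best/summed segmentation of a span into an ordered pHMM chain."""

    def __init__(self, named_scorers: list[tuple[str, SegmentScorer]], mode: str):
        self.named = named_scorers
        self.mode = mode
        self.cap = sum(s.max_len for _, s in named_scorers)
        self._rows: dict[int, np.ndarray] = {}

    def _row(self, i: int) -> np.ndarray:
        row = self._rows.get(i)
        if row is not None:
            return row
        # dp over segments: cur[w] = score of covering [i, i+w)
        cur = np.full(self.cap + 1, NEG_INF)
        cur[0] = 0.0
        for _, scorer in self.named:
            nxt = np.full(self.cap + 1, NEG_INF)
            for w in range(self.cap + 1):
                if cur[w] == NEG_INF:
                    continue
                for d in range(scorer.max_len + 1):
                    if w + d > self.cap:
                        break
                    s = scorer.score(i + w, i + w + d)
                    if s == NEG_INF:
                        continue
                    tot = cur[w] + s
                    if self.mode == "max":
                        if tot > nxt[w + d]:
                            nxt[w + d] = tot
                    else:
                        nxt[w + d] = np.logaddexp(nxt[w + d], tot)
            cur = nxt
        self._rows[i] = cur
        return cur

    def score(self, i: int, j: int) -> float:
        w = j - i
        if w < 0 or w > self.cap:
            return NEG_INF
        return float(self._row(i)[w])

    def dense(self, L: int) -> np.ndarray:
        """(L+1, cap+1) array: ``out[i, w]`` scores columns [i, i+w)."""
        out = np.full((L + 1, self.cap + 1), NEG_INF)
        for i in range(L + 1):
            out[i] = self._row(i)
        return out

    def split(self, i: int, j: int) -> list[tuple[str, int, int]]:
        """Argmax segment boundaries (max mode) as half-open kept spans."""
        assert self.mode == "max"
        # dp with backpointers, restricted to total width j - i
        W = j - i
        n = len(self.named)
        dp = np.full((n + 1, W + 1), NEG_INF)
        bp = np.zeros((n + 1, W + 1), dtype=int)
        dp[0, 0] = 0.0
        for t, (_, scorer) in enumerate(self.named):
            for w in range(W + 1):
                if dp[t, w] == NEG_INF:
                    continue
                for d in range(min(scorer.max_len, W - w) + 1):
                    s = scorer.score(i + w, i + w + d)
                    if s == NEG_INF:
                        continue
                    tot = dp[t, w] + s
                    if tot > dp[t + 1, w + d]:
                        dp[t + 1, w + d] = tot
                        bp[t + 1, w + d] = d
        if dp[n, W] == NEG_INF:
            raise AssertionError("chain split requested on -inf span")
        out = []
        w = W
        for t in range(n, 0, -1):
            d = bp[t, w]
            out.append((self.named[t - 1][0], i + w - d, i + w))
            w -= d
        return list(reversed(out))


# -------------------------------------------------------------------------
# the DP engine

def _reduce(mode: str, values: np.ndarray) -> float:
    if len(values) == 0:
        return NEG_INF
    if mode == "max":
        return float(np.max(values))
    return float(np.logaddexp.reduce(values))


class _Engine:
    """Fills the DP tables; in max mode records backpointers."""

    def __init__(self, pa: ProbabilisticAlignment, grammar: Grammar,
                 constraints: Constraints | None, mode: str):
        self.pa = pa
        self.grammar = grammar
        self.constraints = constraints or Constraints()
        self.mode = mode
        self.sc = _Scores(pa, grammar, self.constraints)
        self.L = pa.L
        self.bp: dict[tuple[str, int, int], tuple] = {}
        self._build_motif_scorers()
        if grammar.kind == "G6X":
            self._fill_g6x()
        else:
            self._fill_main()

    # -- motif machinery --------------------------------------------------

    def _build_motif_scorers(self):
        g = self.grammar
        extra = g.paramset.motif_seg_extra
        blocked = self.sc.forced
        self.chain: dict[str, ChainScorer] = {}      # linear chains (HL/BL/IL sides)
        self.segsc: dict[tuple[str, int], SegmentScorer] = {}  # junction/BS segments

        self.chain_arr: dict[str, np.ndarray] = {}
        self.seg_arr: dict[tuple[str, int], np.ndarray] = {}
        L = self.sc.L

        def seg_scorer(phmm):
            return SegmentScorer(phmm, self.sc.cols, phmm.length + extra, blocked)

        for slot in ("HL", "BL_left", "BL_right"):
            for k, mr in enumerate(g.motif_rules[slot]):
                scorers = [
                    (name, seg_scorer(ph))
                    for (name, _), ph in zip(mr.variant.chains[0], mr.phmm_chains[0])
                ]
                key = f"{slot}:{k}"
                self.chain[key] = ChainScorer(scorers, self.mode)
                self.chain_arr[key] = self.chain[key].dense(L)
        for k, mr in enumerate(g.motif_rules["IL"]):
            for side in (0, 1):
                scorers = [
                    (name, seg_scorer(ph))
                    for (name, _), ph in zip(mr.variant.chains[side], mr.phmm_chains[side])
                ]
                key = f"IL:{k}:{side}"
                self.chain[key] = ChainScorer(scorers, self.mode)
                self.chain_arr[key] = self.chain[key].dense(L)
        for slot in ("J3", "J4"):
            for k, mr in enumerate(g.motif_rules[slot]):
                for t, chain in enumerate(mr.phmm_chains):
                    key = (f"{slot}:{k}", t)
                    self.segsc[key] = seg_scorer(chain[0])
                    self.seg_arr[key] = self.segsc[key].dense()
        for slot in ("BS_BB", "BS_BT"):
            for k, mr in enumerate(g.motif_rules[slot]):
                key = (f"{slot}:{k}", 0)
                self.segsc[key] = seg_scorer(mr.phmm_chains[0][0])
                self.seg_arr[key] = self.segsc[key].dense()

    # -- cell helpers ------------------------------------------------------

    def _cell(self, name: str, i: int, j: int,
              scalars: list[tuple[float, tuple]],
              vectors: list[tuple[np.ndarray, object]]) -> float:
        """Combine candidates; in max mode store the winning backpointer.

        ``scalars`` are (score, decision) pairs; ``vectors`` are
        (score_vector, decision_builder) pairs where the builder maps the
        argmax index to a decision tuple.
        """
        best = NEG_INF
        if self.mode == "max":
            decision = None
            for s, d in scalars:
                if s > best:
                    best, decision = s, d
            for vec, builder in vectors:
                if len(vec) == 0:
                    continue
                k = int(np.argmax(vec))
                if vec[k] > best:
                    best, decision = float(vec[k]), builder(k)
            if decision is not None and best > NEG_INF:
                self.bp[(name, i, j)] = decision
            return best
        parts = [s for s, _ in scalars if s > NEG_INF]
        for vec, _ in vectors:
            if len(vec):
                parts.append(_reduce("sum", vec))
        return _reduce("sum", np.array(parts)) if parts else NEG_INF

    def _bifurcate(self, A: np.ndarray, B: np.ndarray, i: int, j: int,
                   kmin: int, kmax: int) -> np.ndarray:
        """Vector over split k in [kmin, kmax] of A[i,k] + B[k,j]."""
        if kmax < kmin:
            return np.zeros(0)
        return A[i, kmin:kmax + 1] + B[kmin:kmax + 1, j]

    # -- main grammar ------------------------------------------------------

    def _fill_main(self):
        L = self.L
        g = self.grammar
        sc = self.sc
        t = g.log_t
        cap = g.paramset.max_loop_run
        shape = (L + 1, L + 1)
        T = {nt: np.full(shape, NEG_INF)
             for nt in ("S", "F0", "F5", "P", "J3", "J4", "JN",
                        "M1", "BB", "BT", "R", "X2", "X3", "MR",
                        "JN2", "JN1")}
        self.T = T
        # junction motif helper tables: per variant, V_t and U_t
        self.jmotif: dict[tuple[str, str, int], np.ndarray] = {}
        for slot in ("J3", "J4"):
            for k, mr in enumerate(g.motif_rules[slot]):
                n = len(mr.phmm_chains)
                for tt in range(1, n):
                    self.jmotif[(f"{slot}:{k}", "V", tt)] = np.full(shape, NEG_INF)
                    self.jmotif[(f"{slot}:{k}", "U", tt)] = np.full(shape, NEG_INF)

        for i in range(L + 1):
            T["S"][i, i] = t[("S", "end")]
            # empty multiloop tails carry the zero-length run probability;
            # branch-segment motifs require at least one column
            T["BT"][i, i] = t[("BT", "generic")] + sc.run(i, i, "branch")
            T["R"][i, i] = t[("R", "generic")] + sc.run(i, i, "branch")

        for w in range(1, L + 1):
            for i in range(L - w + 1):
                j = i + w
                self._fill_cell_main(i, j, T, t, sc, cap)

        self.root = float(T["S"][0, L])

    def _fill_cell_main(self, i, j, T, t, sc, cap):
        g = self.grammar
        w = j - i

        # F5: pair (i, j-1) with stacked emission
        if w >= 3:
            ss = sc.SS[i, j - 1]
            if ss > NEG_INF:
                T["F5"][i, j] = ss + self._cell(
                    "F5", i, j,
                    [(t[("F5", "aF5a")] + T["F5"][i + 1, j - 1], ("aF5a",)),
                     (t[("F5", "aPa")] + T["P"][i + 1, j - 1], ("aPa",))], [])
            ps = sc.PS[i, j - 1]
            if ps > NEG_INF:
                T["F0"][i, j] = ps + self._cell(
                    "F0", i, j,
                    [(t[("F0", "aF5a")] + T["F5"][i + 1, j - 1], ("aF5a",)),
                     (t[("F0", "aPa")] + T["P"][i + 1, j - 1], ("aPa",))], [])

        # BB -> m..m F0 (+ BS motifs); F0 needs width >= 3
        if w >= 3:
            lmax = w - 3
            runs = sc.run_vector(i, lmax, "branch")
            vecs = [(t[("BB", "generic")] + runs + T["F0"][i + np.arange(lmax + 1), j],
                     lambda l: ("generic", l))]
            for k, mr in enumerate(self.grammar.motif_rules["BS_BB"]):
                arr = self.seg_arr[(f"BS_BB:{k}", 0)]
                lcap = min(lmax, arr.shape[1] - 1)
                if lcap >= 1:
                    seg = arr[i, 1:lcap + 1]
                    vecs.append((mr.log_prob + seg + T["F0"][i + np.arange(1, lcap + 1), j],
                                 (lambda kk: lambda l: ("motif", kk, l + 1))(k)))
            T["BB"][i, j] = self._cell("BB", i, j, [], vecs)

        # BT / R: unpaired runs (+ BS motif at BT)
        scalars = [(t[("BT", "generic")] + sc.run(i, j, "branch"), ("generic",))]
        for k, mr in enumerate(self.grammar.motif_rules["BS_BT"]):
            arr = self.seg_arr[(f"BS_BT:{k}", 0)]
            s = float(arr[i, w]) if w < arr.shape[1] else NEG_INF
            scalars.append((mr.log_prob + s, ("motif", k)))
        T["BT"][i, j] = self._cell("BT", i, j, scalars, [])
        T["R"][i, j] = t[("R", "generic")] + sc.run(i, j, "branch")

        # M1 -> BB M1 | BB
        vec = self._bifurcate(T["BB"], T["M1"], i, j, i + 3, j - 3)
        T["M1"][i, j] = self._cell(
            "M1", i, j,
            [(t[("M1", "last")] + T["BB"][i, j], ("last",))],
            [(t[("M1", "more")] + vec, lambda k: ("more", i + 3 + k))])

        # X2 = BB BT ; X3 = BB X2 ; MR = M1 R ; JN2 = BB MR ; JN1 = BB JN2
        for name, A, B, kmin_off in (
            ("X2", "BB", "BT", 3), ("X3", "BB", "X2", 3),
            ("MR", "M1", "R", 3), ("JN2", "BB", "MR", 3), ("JN1", "BB", "JN2", 3),
        ):
            vec = self._bifurcate(T[A], T[B], i, j, i + kmin_off, j)
            T[name][i, j] = self._cell(name, i, j, [],
                                       [(vec, (lambda off: lambda k: (i + off + k,))(kmin_off))])

        # junction motif helpers (right-to-left chains)
        for slot in ("J3", "J4"):
            for k, mr in enumerate(self.grammar.motif_rules[slot]):
                key = f"{slot}:{k}"
                n = len(mr.phmm_chains)
                for tt in range(n - 1, 0, -1):
                    U = self.jmotif[(key, "U", tt)]
                    V = self.jmotif[(key, "V", tt)]
                    # U_t[i,j] = comb_k F0[i,k] + V_{t+1}[k,j]
                    nxt = (self.jmotif[(key, "V", tt + 1)] if tt + 1 < n else None)
                    if nxt is None:
                        # V_n is the bare last segment score
                        arr = self.seg_arr[(key, n - 1)]
                        if j >= i + 3:
                            ks = np.arange(i + 3, j + 1)
                            ws = j - ks
                            segv = np.where(ws <= arr.shape[1] - 1,
                                            arr[ks, np.minimum(ws, arr.shape[1] - 1)],
                                            NEG_INF)
                            vec = T["F0"][i, i + 3:j + 1] + segv
                        else:
                            vec = np.zeros(0)
                    else:
                        vec = self._bifurcate(T["F0"], nxt, i, j, i + 3, j)
                    U[i, j] = self._cell(f"U:{key}:{tt}", i, j, [],
                                         [(vec, lambda kk: (i + 3 + kk,))])
                    # V_t[i,j] = comb_l seg_t(i, i+l) + U_t[i+l, j]
                    arr = self.seg_arr[(key, tt - 1)]
                    lcap = min(arr.shape[1] - 1, w)
                    vv = arr[i, :lcap + 1] + U[i:i + lcap + 1, j]
                    V[i, j] = self._cell(f"V:{key}:{tt}", i, j, [],
                                         [(vv, lambda l: (l,))])

        # J3 / J4 / JN
        vec = self._bifurcate(T["BB"], T["X2"], i, j, i + 3, j)
        scal = []
        for k, mr in enumerate(self.grammar.motif_rules["J3"]):
            scal.append((mr.log_prob + self.jmotif[(f"J3:{k}", "V", 1)][i, j],
                         ("motif", k)))
        T["J3"][i, j] = self._cell(
            "J3", i, j, scal,
            [(t[("J3", "generic")] + vec, lambda k: ("generic", i + 3 + k))])

        vec = self._bifurcate(T["BB"], T["X3"], i, j, i + 3, j)
        scal = []
        for k, mr in enumerate(self.grammar.motif_rules["J4"]):
            scal.append((mr.log_prob + self.jmotif[(f"J4:{k}", "V", 1)][i, j],
                         ("motif", k)))
        T["J4"][i, j] = self._cell(
            "J4", i, j, scal,
            [(t[("J4", "generic")] + vec, lambda k: ("generic", i + 3 + k))])

        vec = self._bifurcate(T["BB"], T["JN1"], i, j, i + 3, j)
        T["JN"][i, j] = self._cell(
            "JN", i, j, [],
            [(t[("JN", "generic")] + vec, lambda k: ("generic", i + 3 + k))])

        # P
        scalars = [(t[("P", "hp")] + sc.run(i, j, "hp"), ("hp",)),
                   (t[("P", "J3")] + T["J3"][i, j], ("J3",)),
                   (t[("P", "J4")] + T["J4"][i, j], ("J4",)),
                   (t[("P", "JN")] + T["JN"][i, j], ("JN",))]
        vectors = []
        if w >= 4:
            lmax = min(w - 3, cap)
            runs = sc.run_vector(i, lmax, "bulge")[1:]
            ls = np.arange(1, lmax + 1)
            vectors.append((t[("P", "bl")] + runs + T["F0"][i + ls, j],
                            lambda l: ("bl", l + 1)))
            runs_r = sc.run_vector_end(j, lmax, "bulge")[1:]
            vectors.append((t[("P", "br")] + runs_r + T["F0"][i, j - ls],
                            lambda l: ("br", l + 1)))
        if w >= 5:
            m = min(w - 4, cap)
            ls = np.arange(1, m + 1)
            runs_l = sc.run_vector(i, m, "il")[1:]
            runs_r = sc.run_vector_end(j, m, "il")[1:]
            # combinations with l1 + l2 > w - 3 hit an impossible (thin) F0
            # cell and score -inf on their own
            mat = (runs_l[:, None] + runs_r[None, :]
                   + T["F0"][(i + ls)[:, None], (j - ls)[None, :]])
            vectors.append((
                t[("P", "il")] + mat.ravel(),
                (lambda mm: lambda f: ("il", f // mm + 1, f % mm + 1))(m)))
        for k, mr in enumerate(self.grammar.motif_rules["HL"]):
            arr = self.chain_arr[f"HL:{k}"]
            s = float(arr[i, w]) if w < arr.shape[1] else NEG_INF
            scalars.append((mr.log_prob + s, ("HL", k)))
        for k, mr in enumerate(self.grammar.motif_rules["BL_left"]):
            arr = self.chain_arr[f"BL_left:{k}"]
            lcap = min(arr.shape[1] - 1, w - 3)
            if lcap >= 1:
                seg = arr[i, 1:lcap + 1]
                vectors.append((mr.log_prob + seg + T["F0"][i + np.arange(1, lcap + 1), j],
                                (lambda kk: lambda l: ("BL_left", kk, l + 1))(k)))
        for k, mr in enumerate(self.grammar.motif_rules["BL_right"]):
            arr = self.chain_arr[f"BL_right:{k}"]
            lcap = min(arr.shape[1] - 1, w - 3)
            if lcap >= 1:
                ls = np.arange(1, lcap + 1)
                seg = arr[j - ls, ls]
                vectors.append((mr.log_prob + seg + T["F0"][i, j - ls],
                                (lambda kk: lambda l: ("BL_right", kk, l + 1))(k)))
        for k, mr in enumerate(self.grammar.motif_rules["IL"]):
            arrL = self.chain_arr[f"IL:{k}:0"]
            arrR = self.chain_arr[f"IL:{k}:1"]
            l1cap = min(arrL.shape[1] - 1, w - 3)
            l2cap = min(arrR.shape[1] - 1, w - 3)
            if l1cap < 0 or l2cap < 0:
                continue
            ls1 = np.arange(l1cap + 1)
            ls2 = np.arange(l2cap + 1)
            mat = (arrL[i, :l1cap + 1][:, None] + arrR[j - ls2, ls2][None, :]
                   + T["F0"][(i + ls1)[:, None], (j - ls2)[None, :]])
            vectors.append((
                mr.log_prob + mat.ravel(),
                (lambda kk, nn: lambda f: ("IL", kk, f // nn, f % nn))(k, l2cap + 1)))
        T["P"][i, j] = self._cell("P", i, j, scalars, vectors)

        # S
        vec = self._bifurcate(T["F0"], T["S"], i, j, i + 3, j)
        T["S"][i, j] = self._cell(
            "S", i, j,
            [(t[("S", "aS")] + sc.u[i] + T["S"][i + 1, j], ("aS",))],
            [(t[("S", "F0S")] + vec, lambda k: ("F0S", i + 3 + k))])

    # -- layer grammar -----------------------------------------------------

    def _fill_g6x(self):
        L = self.L
        sc = self.sc
        t = self.grammar.log_t
        shape = (L + 1, L + 1)
        T = {nt: np.full(shape, NEG_INF) for nt in ("S6", "L6", "F6")}
        self.T = T
        for w in range(1, L + 1):
            for i in range(L - w + 1):
                j = i + w
                if w == 1:
                    T["L6"][i, j] = t[("L6", "a")] + sc.u[i]
                    self.bp[("L6", i, j)] = ("a",)
                elif sc.PS[i, j - 1] > NEG_INF:
                    T["L6"][i, j] = t[("L6", "pair")] + sc.PS[i, j - 1] + T["F6"][i + 1, j - 1]
                    self.bp[("L6", i, j)] = ("pair",)
                # F6: inside of a pair
                scalars = []
                if w >= 2 and sc.SS[i, j - 1] > NEG_INF:
                    scalars.append((t[("F6", "pair")] + sc.SS[i, j - 1] + T["F6"][i + 1, j - 1],
                                    ("pair",)))
                vec = self._bifurcate(T["L6"], T["S6"], i, j, i + 1, j - 1)
                T["F6"][i, j] = self._cell(
                    "F6", i, j, scalars,
                    [(t[("F6", "LS")] + vec, lambda k: ("LS", i + 1 + k))])
                # S6 -> L S | L
                vec = self._bifurcate(T["L6"], T["S6"], i, j, i + 1, j - 1)
                T["S6"][i, j] = self._cell(
                    "S6", i, j,
                    [(t[("S6", "L")] + T["L6"][i, j], ("L",))],
                    [(t[("S6", "LS")] + vec, lambda k: ("LS", i + 1 + k))])
        self.root = float(T["S6"][0, L]) if L else NEG_INF

    # -- traceback ---------------------------------------------------------

    def traceback(self) -> ParseResult:
        assert self.mode == "max"
        if not np.isfinite(self.root):
            raise InfeasibleError("no derivation satisfies the constraints")
        pairs: list[tuple[int, int]] = []
        calls: list[MotifCall] = []
        if self.grammar.kind == "G6X":
            self._tb_g6x("S6", 0, self.L, pairs)
        else:
            self._tb("S", 0, self.L, pairs, calls)
        pairs.sort()
        return ParseResult([pairs], calls, self.root)

    def _decision(self, nt: str, i: int, j: int) -> tuple:
        d = self.bp.get((nt, i, j))
        if d is None:
            raise InfeasibleError(f"traceback through impossible cell {nt}[{i},{j}]")
        return d

    def _motif_call(self, slot: str, k: int, segments, span, log_score) -> MotifCall:
        mr = self.grammar.motif_rules[slot][k]
        v = mr.variant
        segs = tuple((nm, s, e - 1) for nm, s, e in segments if e > s)
        return MotifCall(v.name, v.unique_id, v.motif_class, v.attachment,
                         (span[0], span[1] - 1), segs, log_score)

    def _tb_junction_motif(self, slot: str, k: int, i: int, j: int,
                           pairs, calls) -> None:
        key = f"{slot}:{k}"
        mr = self.grammar.motif_rules[slot][k]
        n = len(mr.phmm_chains)
        segnames = [chain[0][0] for chain in mr.variant.chains]
        segments = []
        span = (i, j)
        pos = i
        for tt in range(1, n):
            (l,) = self._decision(f"V:{key}:{tt}", pos, j)
            segments.append((segnames[tt - 1], pos, pos + l))
            pos += l
            (kk,) = self._decision(f"U:{key}:{tt}", pos, j)
            if tt + 1 < n:
                self._tb("F0", pos, kk, pairs, calls)
                pos = kk
            else:
                self._tb("F0", pos, kk, pairs, calls)
                segments.append((segnames[n - 1], kk, j))
                pos = j
        score = self.jmotif[(key, "V", 1)][span[0], span[1]]
        calls.append(self._motif_call(slot, k, segments, span, float(score)))

    def _tb(self, nt: str, i: int, j: int, pairs, calls) -> None:
        T = self.T
        t = self.grammar.log_t
        if nt == "S":
            if i == j:
                return
            d = self._decision("S", i, j)
            if d[0] == "aS":
                self._tb("S", i + 1, j, pairs, calls)
            else:
                self._tb("F0", i, d[1], pairs, calls)
                self._tb("S", d[1], j, pairs, calls)
        elif nt in ("F0", "F5"):
            pairs.append((i, j - 1))
            d = self._decision(nt, i, j)
            child = "F5" if d[0] == "aF5a" else "P"
            self._tb(child, i + 1, j - 1, pairs, calls)
        elif nt == "P":
            d = self._decision("P", i, j)
            tag = d[0]
            if tag == "hp":
                return
            if tag == "bl":
                self._tb("F0", i + d[1], j, pairs, calls)
            elif tag == "br":
                self._tb("F0", i, j - d[1], pairs, calls)
            elif tag == "il":
                self._tb("F0", i + d[1], j - d[2], pairs, calls)
            elif tag in ("J3", "J4", "JN"):
                self._tb(tag, i, j, pairs, calls)
            elif tag == "HL":
                k = d[1]
                ch = self.chain[f"HL:{k}"]
                segs = ch.split(i, j)
                calls.append(self._motif_call("HL", k, segs, (i, j),
                                              float(ch.score(i, j))))
            elif tag in ("BL_left", "BL_right"):
                k, l = d[1], d[2]
                ch = self.chain[f"{tag}:{k}"]
                if tag == "BL_left":
                    span = (i, i + l)
                    self._tb("F0", i + l, j, pairs, calls)
                else:
                    span = (j - l, j)
                    self._tb("F0", i, j - l, pairs, calls)
                calls.append(self._motif_call(tag, k, ch.split(*span), span,
                                              float(ch.score(*span))))
            elif tag == "IL":
                k, l1, l2 = d[1], d[2], d[3]
                chL = self.chain[f"IL:{k}:0"]
                chR = self.chain[f"IL:{k}:1"]
                segs = chL.split(i, i + l1) + chR.split(j - l2, j)
                self._tb("F0", i + l1, j - l2, pairs, calls)
                calls.append(self._motif_call(
                    "IL", k, segs, (i, j),
                    float(chL.score(i, i + l1) + chR.score(j - l2, j))))
        elif nt in ("J3", "J4"):
            d = self._decision(nt, i, j)
            if d[0] == "motif":
                self._tb_junction_motif(nt, d[1], i, j, pairs, calls)
            else:
                k = d[1]
                self._tb("BB", i, k, pairs, calls)
                self._tb("X2" if nt == "J3" else "X3", k, j, pairs, calls)
        elif nt == "JN":
            d = self._decision("JN", i, j)
            self._tb("BB", i, d[1], pairs, calls)
            self._tb("JN1", d[1], j, pairs, calls)
        elif nt in ("X2", "X3", "MR", "JN2", "JN1"):
            (k,) = self._decision(nt, i, j)
            left, right = {
                "X2": ("BB", "BT"), "X3": ("BB", "X2"), "MR": ("M1", "R"),
                "JN2": ("BB", "MR"), "JN1": ("BB", "JN2"),
            }[nt]
            self._tb(left, i, k, pairs, calls)
            self._tb(right, k, j, pairs, calls)
        elif nt == "M1":
            d = self._decision("M1", i, j)
            if d[0] == "last":
                self._tb("BB", i, j, pairs, calls)
            else:
                self._tb("BB", i, d[1], pairs, calls)
                self._tb("M1", d[1], j, pairs, calls)
        elif nt == "BB":
            d = self._decision("BB", i, j)
            if d[0] == "generic":
                self._tb("F0", i + d[1], j, pairs, calls)
            else:
                k, l = d[1], d[2]
                scorer = self.segsc[(f"BS_BB:{k}", 0)]
                calls.append(self._motif_call(
                    "BS_BB", k, [("S1", i, i + l)], (i, i + l),
                    float(scorer.score(i, i + l))))
                self._tb("F0", i + l, j, pairs, calls)
        elif nt == "BT":
            d = self.bp.get(("BT", i, j), ("generic",))
            if d[0] == "motif":
                k = d[1]
                scorer = self.segsc[(f"BS_BT:{k}", 0)]
                calls.append(self._motif_call(
                    "BS_BT", k, [("S1", i, j)], (i, j),
                    float(scorer.score(i, j))))
        elif nt == "R":
            return
        else:
            raise AssertionError(f"unknown nonterminal {nt}")

    def _tb_g6x(self, nt: str, i: int, j: int, pairs) -> None:
        if nt == "S6":
            d = self._decision("S6", i, j)
            if d[0] == "L":
                self._tb_g6x("L6", i, j, pairs)
            else:
                self._tb_g6x("L6", i, d[1], pairs)
                self._tb_g6x("S6", d[1], j, pairs)
        elif nt == "L6":
            d = self._decision("L6", i, j)
            if d[0] == "pair":
                pairs.append((i, j - 1))
                self._tb_g6x("F6", i + 1, j - 1, pairs)
        elif nt == "F6":
            d = self._decision("F6", i, j)
            if d[0] == "pair":
                pairs.append((i, j - 1))
                self._tb_g6x("F6", i + 1, j - 1, pairs)
            else:
                self._tb_g6x("L6", i, d[1], pairs)
                self._tb_g6x("S6", d[1], j, pairs)


# -------------------------------------------------------------------------
# public entry points

def cyk(pa: ProbabilisticAlignment, grammar: Grammar,
        constraints: Constraints | None = None) -> ParseResult:
    """Maximum-probability derivation respecting the constraints."""
    eng = _Engine(pa, grammar, constraints, "max")
    return eng.traceback()


def inside(pa: ProbabilisticAlignment, grammar: Grammar,
           constraints: Constraints | None = None) -> float:
    """Log of the summed probability of all derivations (>= the CYK score)."""
    eng = _Engine(pa, grammar, constraints, "sum")
    if not np.isfinite(eng.root):
        raise InfeasibleError("no derivation satisfies the constraints")
    return eng.root


def fold_sequence(seq: str, grammar: Grammar,
                  constraints: Constraints | None = None) -> ParseResult:
    """Fold a literal sequence (an S=1 point-mass alignment)."""
    pa, _ = point_mass_alignment(seq)
    return cyk(pa, grammar, constraints)


# -------------------------------------------------------------------------
# brute-force enumeration oracle

@dataclass(frozen=True)
class Derivation:
    """One complete derivation: its log probability, base pairs, and
    canonical motif annotation (variant, span, segment spans)."""

    log_prob: float
    pairs: frozenset
    annots: tuple


def annotation_of(call: MotifCall) -> tuple:
    """Canonical annotation tuple of a motif call (for comparing parses)."""
    return (call.attachment, call.variant_id, call.span, call.segments)


def parse_key(result: ParseResult) -> tuple:
    """(pair set, sorted annotations) identity of a single-layer parse."""
    return (frozenset(result.pairs),
            tuple(sorted(annotation_of(c) for c in result.motif_calls)))


def enumerate_derivations(
    pa: ProbabilisticAlignment, grammar: Grammar,
    constraints: Constraints | None = None,
) -> list[Derivation]:
    """Every derivation of the input, by explicit recursive enumeration.

    Exponential; intended for inputs of length <= ~10 as an independent
    oracle for the CYK (max), inside (sum) and unambiguity properties.
    Emission scores are recomputed here from their definitions rather
    than taken from the DP engine.
    """
    constraints = constraints or Constraints()
    L = pa.L
    g = grammar
    ps = g.paramset
    t = g.log_t
    cols = pa.single
    partner = constraints.forced_partner
    forced = [bool(partner.get(i) is not None) for i in range(L)]

    def logf(x: float) -> float:
        return math.log(x) if x > 0 else NEG_INF

    def u(i: int) -> float:
        if forced[i]:
            return NEG_INF
        return logf(float(cols[i] @ ps.emis_single))

    def pairsc(i: int, j: int) -> float:  # pair on columns (i, j) inclusive
        if (i, j) in constraints.forbidden_pairs:
            return NEG_INF
        if i in constraints.unpairable or j in constraints.unpairable:
            return NEG_INF
        if partner.get(i, j) != j or partner.get(j, i) != i:
            return NEG_INF
        min_enc = 3
        if j - i - 1 < min_enc and (i, j) not in constraints.forced_pairs:
            return NEG_INF
        F = pa.pair_freq(i, j)
        return logf(float(np.sum(F * ps.emis_pair)))

    def stacksc(i: int, j: int) -> float:
        base = pairsc(i, j)
        if base == NEG_INF:
            return NEG_INF
        F = pa.pair_freq(i, j)
        Fout = pa.pair_freq(i - 1, j + 1)
        stack = np.asarray(ps.emis_stack)
        total = 0.0
        for c in range(4):
            for d in range(4):
                total += Fout[c, d] * float(np.sum(stack[c, d] * F))
        return logf(total)

    def run(i: int, j: int, ctx: str) -> float:
        if any(forced[k] for k in range(i, j)):
            return NEG_INF
        s = g.run_log_prob(j - i, ctx)
        for k in range(i, j):
            s += u(k)
        return s

    def seg_ok(i: int, j: int) -> bool:
        return not any(forced[k] for k in range(i, j))

    def seg_score(phmm, i: int, j: int, cap: int) -> float:
        if j - i > cap or not seg_ok(i, j):
            return NEG_INF
        return forward(phmm, cols[i:j])

    extra = ps.motif_seg_extra

    def chain_enums(chain_phmms, seg_names, i, j):
        """All segmentations of [i, j) into the chain; yields
        (logp, ((name, s, e_inclusive), ...)) with empty segments dropped."""
        out = []

        def rec(idx, pos, acc_lp, acc_segs):
            if idx == len(chain_phmms):
                if pos == j:
                    out.append((acc_lp, tuple(acc_segs)))
                return
            phmm = chain_phmms[idx]
            cap = phmm.length + extra
            for e in range(pos, min(j, pos + cap) + 1):
                s = seg_score(phmm, pos, e, cap)
                if s == NEG_INF:
                    continue
                segs = acc_segs + ([(seg_names[idx], pos, e - 1)] if e > pos else [])
                rec(idx + 1, e, acc_lp + s, segs)

        rec(0, i, 0.0, [])
        return out

    memo: dict[tuple, list] = {}

    def combine(list_a, list_b):
        return [
            (la + lb, pa_ | pb, aa + ab)
            for la, pa_, aa in list_a for lb, pb, ab in list_b
        ]

    def lift(lp: float, pairs=frozenset(), annots=()) -> list:
        return [(lp, pairs, annots)] if lp > NEG_INF else []

    def derive(nt: str, i: int, j: int) -> list:
        key = (nt, i, j)
        if key in memo:
            return memo[key]
        w = j - i
        out: list = []
        if nt == "S":
            if w == 0:
                out = lift(t[("S", "end")])
            else:
                if u(i) > NEG_INF:
                    out += [(t[("S", "aS")] + u(i) + lp, p, a)
                            for lp, p, a in derive("S", i + 1, j)]
                for k in range(i + 3, j + 1):
                    out += [(t[("S", "F0S")] + lp, p, a)
                            for lp, p, a in combine(derive("F0", i, k), derive("S", k, j))]
        elif nt in ("F0", "F5"):
            if w >= 3:
                em = pairsc(i, j - 1) if nt == "F0" else stacksc(i, j - 1)
                if em > NEG_INF:
                    pr = frozenset([(i, j - 1)])
                    for rule, child in (("aF5a", "F5"), ("aPa", "P")):
                        out += [(t[(nt, rule)] + em + lp, p | pr, a)
                                for lp, p, a in derive(child, i + 1, j - 1)]
        elif nt == "P":
            out += lift(t[("P", "hp")] + run(i, j, "hp"))
            cap = ps.max_loop_run
            for l in range(1, min(w - 3, cap) + 1):
                r = run(i, i + l, "bulge")
                if r > NEG_INF:
                    out += [(t[("P", "bl")] + r + lp, p, a)
                            for lp, p, a in derive("F0", i + l, j)]
                r = run(j - l, j, "bulge")
                if r > NEG_INF:
                    out += [(t[("P", "br")] + r + lp, p, a)
                            for lp, p, a in derive("F0", i, j - l)]
            for l1 in range(1, min(w - 4, cap) + 1):
                r1 = run(i, i + l1, "il")
                if r1 == NEG_INF:
                    continue
                for l2 in range(1, min(w - 3 - l1, cap) + 1):
                    r2 = run(j - l2, j, "il")
                    if r2 == NEG_INF:
                        continue
                    out += [(t[("P", "il")] + r1 + r2 + lp, p, a)
                            for lp, p, a in derive("F0", i + l1, j - l2)]
            for junc in ("J3", "J4", "JN"):
                out += [(t[("P", junc)] + lp, p, a)
                        for lp, p, a in derive(junc, i, j)]
            for k, mr in enumerate(g.motif_rules["HL"]):
                names = [nm for nm, _ in mr.variant.chains[0]]
                for lp, segs in chain_enums(mr.phmm_chains[0], names, i, j):
                    out.append((mr.log_prob + lp, frozenset(),
                                (("HL", mr.variant.unique_id, (i, j - 1), segs),)))
            for slot, left_side in (("BL_left", True), ("BL_right", False)):
                for k, mr in enumerate(g.motif_rules[slot]):
                    names = [nm for nm, _ in mr.variant.chains[0]]
                    ch_cap = sum(p.length + extra for p in mr.phmm_chains[0])
                    for l in range(1, min(w - 3, ch_cap) + 1):
                        s0, e0 = (i, i + l) if left_side else (j - l, j)
                        for lp, segs in chain_enums(mr.phmm_chains[0], names, s0, e0):
                            helix = derive("F0", i + l, j) if left_side else derive("F0", i, j - l)
                            ann = ((slot, mr.variant.unique_id, (s0, e0 - 1), segs),)
                            out += [(mr.log_prob + lp + hlp, hp, ha + ann)
                                    for hlp, hp, ha in helix]
            for k, mr in enumerate(g.motif_rules["IL"]):
                namesL = [nm for nm, _ in mr.variant.chains[0]]
                namesR = [nm for nm, _ in mr.variant.chains[1]]
                capL = sum(p.length + extra for p in mr.phmm_chains[0])
                capR = sum(p.length + extra for p in mr.phmm_chains[1])
                for l1 in range(0, min(w - 3, capL) + 1):
                    for l2 in range(0, min(w - 3 - l1, capR) + 1):
                        for lpL, segsL in chain_enums(mr.phmm_chains[0], namesL, i, i + l1):
                            for lpR, segsR in chain_enums(mr.phmm_chains[1], namesR, j - l2, j):
                                ann = (("IL", mr.variant.unique_id, (i, j - 1),
                                        segsL + segsR),)
                                out += [
                                    (mr.log_prob + lpL + lpR + hlp, hp, ha + ann)
                                    for hlp, hp, ha in derive("F0", i + l1, j - l2)
                                ]
        elif nt in ("J3", "J4"):
            n_br = 2 if nt == "J3" else 3
            def gen_generic(pos, left, acc):
                if left == 0:
                    tail = derive("BT", pos, j)
                    return [(lp + tl, p | tp, a + ta)
                            for lp, p, a in acc for tl, tp, ta in tail]
                res = []
                for k in range(pos + 3, j + 1):
                    bb = derive("BB", pos, k)
                    if not bb:
                        continue
                    nxt = [(lp + bl, p | bp_, a + ba)
                           for lp, p, a in acc for bl, bp_, ba in bb]
                    if nxt:
                        res += gen_generic(k, left - 1, nxt)
                return res
            out += [(t[(nt, "generic")] + lp, p, a)
                    for lp, p, a in gen_generic(i, n_br, [(0.0, frozenset(), ())])]
            for k, mr in enumerate(g.motif_rules[nt]):
                n = len(mr.phmm_chains)
                names = [chain[0][0] for chain in mr.variant.chains]

                def gen_motif(tt, pos, acc):
                    phmm = mr.phmm_chains[tt][0]
                    cap = phmm.length + extra
                    res = []
                    if tt == n - 1:
                        s = seg_score(phmm, pos, j, cap)
                        if s > NEG_INF:
                            seg = [(names[tt], pos, j - 1)] if j > pos else []
                            res += [(lp + s, p, a + tuple(seg)) for lp, p, a in acc]
                        return res
                    for l in range(0, min(cap, j - pos) + 1):
                        s = seg_score(phmm, pos, pos + l, cap)
                        if s == NEG_INF:
                            continue
                        seg = [(names[tt], pos, pos + l - 1)] if l else []
                        withseg = [(lp + s, p, a + tuple(seg)) for lp, p, a in acc]
                        for kk in range(pos + l + 3, j + 1):
                            f0 = derive("F0", pos + l, kk)
                            if not f0:
                                continue
                            nxt = [(lp + fl, p | fp, a + fa)
                                   for lp, p, a in withseg for fl, fp, fa in f0]
                            res += gen_motif(tt + 1, kk, nxt)
                    return res

                for lp, p, a in gen_motif(0, i, [(0.0, frozenset(), ())]):
                    # loose 3-tuples in `a` are this motif's segment spans;
                    # completed (4-tuple) annotations belong to nested motifs
                    segs = tuple(x for x in a if len(x) == 3)
                    rest = tuple(x for x in a if len(x) == 4)
                    out.append((mr.log_prob + lp, p,
                                rest + ((nt, mr.variant.unique_id, (i, j - 1), segs),)))
        elif nt == "JN":
            # JN -> BB BB BB M1 R with M1 a chain of >= 1 further BBs;
            # every M1 branch adds t(M1, more) except the last, t(M1, last)
            def gen_chain(pos, n_done, acc):
                res = []
                for k in range(pos + 3, j + 1):
                    bb = derive("BB", pos, k)
                    if not bb:
                        continue
                    for last in ((False,) if n_done < 3 else (False, True)):
                        tr = 0.0
                        if n_done >= 3:
                            tr = t[("M1", "last")] if last else t[("M1", "more")]
                        nxt = [(lp + tr + bl, p | bp_, a + ba)
                               for lp, p, a in acc for bl, bp_, ba in bb]
                        if not nxt:
                            continue
                        if last:
                            tail = derive("R", k, j)
                            res += [(lp + tl, p | tp, a + ta)
                                    for lp, p, a in nxt for tl, tp, ta in tail]
                        else:
                            res += gen_chain(k, n_done + 1, nxt)
                return res
            out += [(t[("JN", "generic")] + lp, p, a)
                    for lp, p, a in gen_chain(i, 0, [(0.0, frozenset(), ())])]
        elif nt == "BB":
            for l in range(0, max(0, w - 3) + 1):
                r = run(i, i + l, "branch")
                if r > NEG_INF:
                    out += [(t[("BB", "generic")] + r + lp, p, a)
                            for lp, p, a in derive("F0", i + l, j)]
            for k, mr in enumerate(g.motif_rules["BS_BB"]):
                phmm = mr.phmm_chains[0][0]
                cap = phmm.length + extra
                for l in range(1, min(cap, w - 3) + 1):
                    s = seg_score(phmm, i, i + l, cap)
                    if s == NEG_INF:
                        continue
                    ann = ((mr.variant.attachment, mr.variant.unique_id, (i, i + l - 1),
                            (("S1", i, i + l - 1),)),)
                    out += [(mr.log_prob + s + lp, p, a + ann)
                            for lp, p, a in derive("F0", i + l, j)]
        elif nt == "BT":
            out += lift(t[("BT", "generic")] + run(i, j, "branch"))
            if w >= 1:
                for k, mr in enumerate(g.motif_rules["BS_BT"]):
                    phmm = mr.phmm_chains[0][0]
                    s = seg_score(phmm, i, j, phmm.length + extra)
                    if s > NEG_INF:
                        out.append((mr.log_prob + s, frozenset(),
                                    ((mr.variant.attachment, mr.variant.unique_id, (i, j - 1),
                                      (("S1", i, j - 1),)),)))
        elif nt == "R":
            out = lift(t[("R", "generic")] + run(i, j, "branch"))
        elif nt == "S6":
            opts = []
            opts += [(t[("S6", "L")] + lp, p, a) for lp, p, a in derive("L6", i, j)]
            for k in range(i + 1, j):
                opts += [(t[("S6", "LS")] + lp, p, a)
                         for lp, p, a in combine(derive("L6", i, k), derive("S6", k, j))]
            out = opts
        elif nt == "L6":
            if w == 1:
                out = lift(t[("L6", "a")] + u(i))
            elif w >= 2:
                em = pairsc(i, j - 1)
                if em > NEG_INF:
                    pr = frozenset([(i, j - 1)])
                    out = [(t[("L6", "pair")] + em + lp, p | pr, a)
                           for lp, p, a in derive("F6", i + 1, j - 1)]
        elif nt == "F6":
            if w >= 2:
                em = stacksc(i, j - 1)
                if em > NEG_INF:
                    pr = frozenset([(i, j - 1)])
                    out += [(t[("F6", "pair")] + em + lp, p | pr, a)
                            for lp, p, a in derive("F6", i + 1, j - 1)]
            out2 = []
            out2 += [(t[("F6", "LS")] + lp, p, a)
                     for k in range(i + 1, j)
                     for lp, p, a in combine(derive("L6", i, k), derive("S6", k, j))]
            out += out2
        else:
            raise AssertionError(nt)
        memo[key] = out
        return out

    start = "S6" if g.kind == "G6X" else "S"
    return [Derivation(lp, p, tuple(sorted(a)))
            for lp, p, a in derive(start, 0, L)]


# -------------------------------------------------------------------------
# derivation rescoring

def score_structure(pa: ProbabilisticAlignment, grammar: Grammar,
                    result: ParseResult,
                    constraints: Constraints | None = None) -> float:
    """Log probability of the unique derivation with the given pairs and
    motif calls (kept-column coordinates).

    The grammar is unambiguous, so a (pair set, motif annotation)
    combination determines one derivation; this walks it and sums the
    transition, emission, run and profile-HMM scores.  Used to verify that
    a traceback rescores to the CYK optimum.
    """
    if result.one_based:
        raise ValueError("score_structure expects kept-column coordinates")
    if grammar.kind == "G6X":
        raise ValueError("score_structure supports the main grammars only")
    constraints = constraints or Constraints()
    sc = _Scores(pa, grammar, constraints)
    t = grammar.log_t
    cols = pa.single
    L = pa.L

    partner: dict[int, int] = {}
    for i, j in result.pairs:
        partner[i] = j
        partner[j] = i

    by_key: dict[tuple, MotifCall] = {}
    for c in result.motif_calls:
        by_key[(c.attachment, c.span)] = c

    rule_of: dict[tuple[str, str], MotifRule] = {}
    for slot, rules in grammar.motif_rules.items():
        for mr in rules:
            rule_of[(slot, mr.variant.unique_id)] = mr

    def chain_at(mr: MotifRule, chain_idx: int, s: int, e: int,
                 call: MotifCall) -> float:
        names = [nm for nm, _ in mr.variant.chains[chain_idx]]
        seg_map = {nm: (s0, e0) for nm, s0, e0 in call.segments if nm in names}
        cursor = s
        lp = 0.0
        for name, phmm in zip(names, mr.phmm_chains[chain_idx]):
            if name in seg_map:
                s0, e0 = seg_map[name]
                if s0 != cursor:
                    raise ValueError(f"segment {name} does not abut at {cursor}")
                lp += forward(phmm, cols[s0:e0 + 1])
                cursor = e0 + 1
            else:
                lp += forward(phmm, cols[cursor:cursor])
        if cursor != e:
            raise ValueError("motif segments do not cover the recorded span")
        return lp

    def children_of(i: int, j: int) -> list[tuple[int, int]]:
        out = []
        k = i
        while k < j:
            if k in partner and partner[k] > k:
                out.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return out

    def walk_S(i: int, j: int) -> float:
        lp = 0.0
        k = i
        while k < j:
            if k in partner:
                lp += t[("S", "F0S")] + walk_F(k, partner[k], False)
                k = partner[k] + 1
            else:
                lp += t[("S", "aS")] + sc.u[k]
                k += 1
        return lp + t[("S", "end")]

    def walk_F(i: int, j: int, stacked: bool) -> float:
        nt = "F5" if stacked else "F0"
        em = sc.SS[i, j] if stacked else sc.PS[i, j]
        if partner.get(i + 1) == j - 1:
            return em + t[(nt, "aF5a")] + walk_F(i + 1, j - 1, True)
        return em + t[(nt, "aPa")] + walk_P(i + 1, j)

    def walk_branches(i: int, j: int, children, junction: str) -> float:
        # generic junction: BB per child, then BT (J3/J4) or M1/R (JN)
        lp = 0.0
        pos = i
        k = len(children)
        for idx, (a, b) in enumerate(children):
            if junction == "JN" and idx >= 3:
                lp += t[("M1", "more" if idx < k - 1 else "last")]
            call = by_key.get(("BS", (pos, a - 1))) if a > pos else None
            if call is not None:
                mr = rule_of[("BS_BB", call.variant_id)]
                lp += mr.log_prob + forward(mr.phmm_chains[0][0], cols[pos:a])
            else:
                lp += t[("BB", "generic")] + sc.run(pos, a, "branch")
            lp += walk_F(a, b, False)
            pos = b + 1
        if junction == "JN":
            lp += t[("R", "generic")] + sc.run(pos, j, "branch")
        else:
            call = by_key.get(("BS", (pos, j - 1))) if j > pos else None
            if call is not None:
                mr = rule_of[("BS_BT", call.variant_id)]
                lp += mr.log_prob + forward(mr.phmm_chains[0][0], cols[pos:j])
            else:
                lp += t[("BT", "generic")] + sc.run(pos, j, "branch")
        return lp

    def walk_P(i: int, j: int) -> float:  # span [i, j)
        children = children_of(i, j)
        k = len(children)
        span = (i, j - 1)
        for att in ("HL", "IL", "J3", "J4"):
            call = by_key.get((att, span))
            if call is None:
                continue
            if att == "HL":
                mr = rule_of[("HL", call.variant_id)]
                return mr.log_prob + chain_at(mr, 0, i, j, call)
            if att == "IL":
                (a, b), = children
                mr = rule_of[("IL", call.variant_id)]
                return (mr.log_prob + chain_at(mr, 0, i, a, call)
                        + chain_at(mr, 1, b + 1, j, call) + walk_F(a, b, False))
            # junction motif: segments fill the gaps between the helices
            mr = rule_of[(att, call.variant_id)]
            lp = t[("P", att)] + mr.log_prob
            pos = i
            for idx, (a, b) in enumerate(children):
                lp += forward(mr.phmm_chains[idx][0], cols[pos:a])
                lp += walk_F(a, b, False)
                pos = b + 1
            lp += forward(mr.phmm_chains[len(children)][0], cols[pos:j])
            return lp
        if k == 1:
            (a, b), = children
            if a > i:
                call = next(
                    (c for c in result.motif_calls
                     if c.attachment == "BL_left" and c.span == (i, a - 1)), None)
                if call is not None and b == j - 1:
                    mr = rule_of[("BL_left", call.variant_id)]
                    return mr.log_prob + chain_at(mr, 0, i, a, call) + walk_F(a, b, False)
            if b < j - 1:
                call = next(
                    (c for c in result.motif_calls
                     if c.attachment == "BL_right" and c.span == (b + 1, j - 1)), None)
                if call is not None and a == i:
                    mr = rule_of[("BL_right", call.variant_id)]
                    return (mr.log_prob + chain_at(mr, 0, b + 1, j, call)
                            + walk_F(a, b, False))
        if k == 0:
            return t[("P", "hp")] + sc.run(i, j, "hp")
        if k == 1:
            (a, b), = children
            left, right = a - i, (j - 1) - b
            if left and not right:
                return t[("P", "bl")] + sc.run(i, a, "bulge") + walk_F(a, b, False)
            if right and not left:
                return (t[("P", "br")] + sc.run(b + 1, j, "bulge")
                        + walk_F(a, b, False))
            return (t[("P", "il")] + sc.run(i, a, "il") + sc.run(b + 1, j, "il")
                    + walk_F(a, b, False))
        if k == 2:
            return (t[("P", "J3")] + t[("J3", "generic")]
                    + walk_branches(i, j, children, "J3"))
        if k == 3:
            return (t[("P", "J4")] + t[("J4", "generic")]
                    + walk_branches(i, j, children, "J4"))
        return (t[("P", "JN")] + t[("JN", "generic")]
                + walk_branches(i, j, children, "JN"))

    return walk_S(0, L)
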