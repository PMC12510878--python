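"""Profile HMMs over motif consensus segments.

Each motif sequence segment (a loop, a correlated stem strand, a junction
branch) is modeled by a small profile HMM built from its IUPAC consensus
string.  States emit on transition: a begin state, one match state per
consensus position, one insert state per inter-position slot (including
the flanks) and deletion bypasses.  The model is a proper distribution
over strings of any length, so its forward score can be dropped directly
into a folding grammar as a normalized segment emission.

Parameterization
----------------
Match emissions: a consensus class of size ``c`` (e.g. R has c=2) gives
each in-class residue ``(1 - (4-c)*eps)/c`` and each out-of-class residue
``eps`` (default ``1e-4``); so a single-residue position U scores
``p(U) = 0.9997`` and an R position scores ``p(A) = p(G) = 0.4999``.

Transitions: a single geometric self-insert parameter ``q`` (shared by
all insert slots) and a per-position delete probability ``d`` are solved
in closed form so that the expected emitted length is
``L_c + min(0.1 * L_c, 1.5)`` — motif instances slightly exceed their
consensus length on average.  An empty consensus keeps an expected extra
length of 0.5 so that insertions remain reachable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignments import IUPAC, NUC_INDEX

#: extra expected length per consensus position, and its cap
LENGTH_EXCESS_PER_POSITION = 0.1
LENGTH_EXCESS_MAX = 1.5
EMPTY_CONSENSUS_EXCESS = 0.5

DEFAULT_EPSILON = 1e-4
DEFAULT_DELETE_PROB = 0.05

NEG_INF = float("-inf")


def match_emission(code: str, epsilon: float) -> np.ndarray:
    """Emission 4-vector of one consensus position given its IUPAC code."""
    residues = IUPAC.get(code)
    if residues is None:
        raise ValueError(f"invalid consensus character {code!r}")
    c = len(residues)
    vec = np.full(4, epsilon)
    vec[[NUC_INDEX[r] for r in residues]] = (1.0 - (4 - c) * epsilon) / c
    return vec


def expected_excess(length: int) -> float:
    if length == 0:
        return EMPTY_CONSENSUS_EXCESS
    return min(LENGTH_EXCESS_PER_POSITION * length, LENGTH_EXCESS_MAX)


@dataclass
class ProfileHMM:
    consensus: str
    epsilon: float
    match_em: np.ndarray     # (L_c, 4)
    insert_em: np.ndarray    # (4,)
    q: float                 # geometric self-insert probability
    d: float                 # per-position delete probability

    @property
    def length(self) -> int:
        return len(self.consensus)

    def to_dict(self) -> dict:
        return {
            "consensus": self.consensus,
            "epsilon": self.epsilon,
            "match_emissions": self.match_em.tolist(),
            "insert_emission": self.insert_em.tolist(),
            "self_insert_q": self.q,
            "delete_d": self.d,
        }


def build_phmm(
    consensus: str,
    epsilon: float = DEFAULT_EPSILON,
    insert_em: np.ndarray | None = None,
    delete_prob: float = DEFAULT_DELETE_PROB,
) -> ProfileHMM:
    """Build the profile HMM of a consensus string (empty allowed)."""
    consensus = consensus.upper().replace("T", "U")
    L = len(consensus)
    match = np.array([match_emission(ch, epsilon) for ch in consensus]).reshape(L, 4)
    if insert_em is None:
        insert_em = np.full(4, 0.25)
    insert_em = np.asarray(insert_em, dtype=float)
    # E[len] = L(1-d) + (L+1) q/(1-q)  ==  L + excess
    excess = expected_excess(L)
    ratio = (excess + L * delete_prob) / (L + 1)
    q = ratio / (1.0 + ratio)
    return ProfileHMM(consensus=consensus, epsilon=epsilon, match_em=match,
                      insert_em=insert_em, q=q, d=delete_prob)


def expected_length(phmm: ProfileHMM) -> float:
    """Analytic expected emitted length from the transition probabilities."""
    L, q, d = phmm.length, phmm.q, phmm.d
    return L * (1.0 - d) + (L + 1) * q / (1.0 - q)


def _as_columns(segment) -> np.ndarray:
    """Accept a literal sequence or an (w, 4) array of column distributions."""
    if isinstance(segment, str):
        cols = np.zeros((len(segment), 4))
        for k, ch in enumerate(segment.upper().replace("T", "U")):
            residues = IUPAC[ch]
            for r in residues:
                cols[k, NUC_INDEX[r]] = 1.0 / len(residues)
        return cols
    cols = np.asarray(segment, dtype=float)
    if cols.ndim != 2 or cols.shape[1] != 4:
        raise ValueError("segment must be a string or an (w, 4) array")
    return cols


def forward_profile(phmm: ProfileHMM, cols: np.ndarray) -> np.ndarray:
    """Forward log-probabilities of every prefix of ``cols``.

    Returns a vector ``out`` with ``out[w]`` the log probability that the
    model emits exactly the first ``w`` columns, for ``0 <= w <= len(cols)``.
    Column emissions are mixed over the per-column nucleotide distribution:
    ``P(o) = sum_a p_o(a) P(a)``; a one-hot column reduces to the plain
    residue emission.
    """
    w_max = len(cols)
    Lc = phmm.length
    with np.errstate(divide="ignore"):
        log_q = np.log(phmm.q)
        log_1mq = np.log1p(-phmm.q)
        log_d = np.log(phmm.d) if Lc else NEG_INF
        log_1md = np.log1p(-phmm.d)
        e_ins = np.log(cols @ phmm.insert_em) if w_max else np.zeros(0)
        e_match = (
            np.log(cols @ phmm.match_em.T) if (w_max and Lc) else np.zeros((w_max, Lc))
        )

    # f[m]: log prob of having consumed m columns, just arrived at current slot
    f = np.full(w_max + 1, NEG_INF)
    f[0] = 0.0
    for t in range(Lc + 1):
        # geometric insert closure within slot t
        h = np.array(f)
        for m in range(1, w_max + 1):
            h[m] = np.logaddexp(h[m], h[m - 1] + log_q + e_ins[m - 1])
        g = h + log_1mq  # leave slot t
        if t == Lc:
            return g
        nxt = np.full(w_max + 1, NEG_INF)
        for m in range(w_max + 1):
            best = g[m] + log_d  # delete position t+1
            if m > 0:
                best = np.logaddexp(best, g[m - 1] + log_1md + e_match[m - 1, t])
            nxt[m] = best
        f = nxt
    raise AssertionError("unreachable")


def forward(phmm: ProfileHMM, segment) -> float:
    """Log probability that the model emits exactly ``segment``.

    ``segment`` may be a literal sequence or an (w, 4) array of alignment
    column distributions (a slice of a probabilistic alignment); the empty
    segment is allowed and scores the all-delete/no-insert paths.
    """
    cols = _as_columns(segment)
    return float(forward_profile(phmm, cols)[len(cols)])


def sample(phmm: ProfileHMM, rng: np.random.Generator) -> str:
    """Sample one emitted string from the model."""
    out = []
    nucs = "ACGU"
    for t in range(phmm.length + 1):
        while rng.random() < phmm.q:
            out.append(nucs[rng.choice(4, p=phmm.insert_em)])
        if t < phmm.length:
            if rng.random() >= phmm.d:
                out.append(nucs[rng.choice(4, p=phmm.match_em[t])])
    return "".join(out)


class SegmentScorer:
    """Cached forward scores of one pHMM over spans of a column matrix.

    ``score(i, j)`` is the forward log probability of kept columns
    ``[i, j)``; spans longer than ``max_len`` or containing a masked
    (must-pair) column score ``-inf``.
    """

    def __init__(self, phmm: ProfileHMM, cols: np.ndarray,
                 max_len: int, blocked: np.ndarray | None = None):
        self.phmm = phmm
        self.cols = cols
        self.max_len = max_len
        L = len(cols)
        self.blocked = np.zeros(L, dtype=bool) if blocked is None else blocked
        self._rows: dict[int, np.ndarray] = {}

    def score(self, i: int, j: int) -> float:
        w = j - i
        if w < 0 or w > self.max_len:
            return NEG_INF
        row = self._rows.get(i)
        if row is None:
            stop = min(i + self.max_len, len(self.cols))
            blk = np.flatnonzero(self.blocked[i:stop])
            if len(blk):
                stop = i + int(blk[0])  # spans may not cross a blocked column
            row = forward_profile(self.phmm, self.cols[i:stop])
            self._rows[i] = row
        if w >= len(row):
            return NEG_INF
        return float(row[w])

    def dense(self) -> np.ndarray:
        """(L+1, max_len+1) array of span scores: ``out[i, w]`` scores
        columns [i, i+w); -inf outside the alignment or across a blocked
        column."""
        L = len(self.cols)
        out = np.full((L + 1, self.max_len + 1), NEG_INF)
        for i in range(L + 1):
            row = self._rows.get(i)
            if row is None:
                stop = min(i + self.max_len, L)
                blk = np.flatnonzero(self.blocked[i:stop])
                if len(blk):
                    stop = i + int(blk[0])
                row = forward_profile(self.phmm, self.cols[i:stop])
                self._rows[i] = row
            out[i, :len(row)] = row
        return out
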