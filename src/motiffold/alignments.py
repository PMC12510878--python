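"""Alignment I/O and the probabilistic-sequence representation.

An RNA alignment is folded here not row by row but as a single
*probabilistic sequence*: per kept column a 4-vector of nucleotide
frequencies, and per column pair a joint 4x4 frequency table.  Columns
dominated by gaps (more than ``gap_max``, default 75%) are removed before
folding; a :class:`ColumnMap` records the bijection back to the original
alignment coordinates (1-based in all user-facing output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO

log = logging.getLogger(__name__)

GAP_CHARS = set("-._~")
NUCS = "ACGU"
NUC_INDEX = {c: i for i, c in enumerate(NUCS)}

#: IUPAC nucleotide codes mapped to the set of residues they stand for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


class AlignmentFormatError(ValueError):
    """Raised for malformed alignment input (ragged rows, empty file, ...)."""


def _normalize_row(row: str) -> str:
    return row.upper().replace("T", "U")


@dataclass
class MSA:
    """A multiple sequence alignment over {A,C,G,U, IUPAC codes, gaps}.

    Rows are normalized on construction: upper case, T -> U.
    """

    sequence_ids: list[str]
    rows: list[str]
    ss_cons: str | None = None
    gc_lines: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rows = [_normalize_row(r) for r in self.rows]
        if not self.rows:
            raise AlignmentFormatError("alignment has no sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"ragged alignment rows: lengths {sorted(lengths)}")
        if len(self.sequence_ids) != len(self.rows):
            raise AlignmentFormatError("sequence_ids and rows differ in count")
        for row in self.rows:
            for ch in row:
                if ch not in IUPAC and ch not in GAP_CHARS:
                    raise AlignmentFormatError(f"invalid residue character {ch!r}")
        if self.ss_cons is not None and len(self.ss_cons) != self.length:
            raise AlignmentFormatError("SS_cons length differs from alignment length")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_seq(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        """Characters of 0-based column ``j``, one per sequence."""
        return "".join(row[j] for row in self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MSA):
            return NotImplemented
        return (
            self.sequence_ids == other.sequence_ids
            and self.rows == other.rows
            and self.ss_cons == other.ss_cons
        )


def read_stockholm(path) -> MSA:
    """Read a Stockholm 1.0 alignment; captures ``#=GC SS_cons`` if present."""
    try:
        aln = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse Stockholm file {path}: {exc}") from exc
    ss = aln.column_annotations.get("secondary_structure")
    gc = {
        key.split(":", 1)[1]: val
        for key, val in aln.column_annotations.items()
        if key.startswith("GC:")
    }
    return MSA(
        sequence_ids=[rec.id for rec in aln],
        rows=[str(rec.seq) for rec in aln],
        ss_cons=ss,
        gc_lines=gc,
    )


def read_fasta(path) -> MSA:
    """Read a FASTA file as an alignment (single sequences give S=1)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no sequences in {path}")
    return MSA(sequence_ids=[r.id for r in records], rows=[str(r.seq) for r in records])


def write_stockholm(msa: MSA, path) -> None:
    """Write Stockholm 1.0 with SS_cons and any extra #=GC annotation lines."""
    name_w = max(len(i) for i in msa.sequence_ids)
    name_w = max(name_w, max((len("#=GC " + k) for k in msa.gc_lines), default=0),
                 len("#=GC SS_cons") if msa.ss_cons else 0) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n\n")
        for sid, row in zip(msa.sequence_ids, msa.rows):
            fh.write(f"{sid:<{name_w}}{row}\n")
        if msa.ss_cons is not None:
            fh.write(f"{'#=GC SS_cons':<{name_w}}{msa.ss_cons}\n")
        for key, val in msa.gc_lines.items():
            fh.write(f"{'#=GC ' + key:<{name_w}}{val}\n")
        fh.write("//\n")


@dataclass
class ColumnMap:
    """Bijection between kept-column index (0-based) and original column.

    ``kept[k]`` is the 0-based original column of kept column ``k``.  All
    user-facing coordinates are 1-based original alignment columns.
    """

    kept: np.ndarray  # 0-based original columns, strictly increasing

    def __post_init__(self) -> None:
        self.kept = np.asarray(self.kept, dtype=int)
        if len(self.kept) and np.any(np.diff(self.kept) <= 0):
            raise ValueError("kept columns must be strictly increasing")
        self._inv = {int(orig): k for k, orig in enumerate(self.kept)}

    def __len__(self) -> int:
        return len(self.kept)

    def to_original(self, k: int) -> int:
        """1-based original column of kept column ``k``."""
        return int(self.kept[k]) + 1

    def to_kept(self, orig_1based: int) -> int | None:
        """Kept index of a 1-based original column, or None if dropped."""
        return self._inv.get(orig_1based - 1)


def _column_distribution(chars: str, weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted residue frequency 4-vector of one column plus its gap fraction.

    Gaps are excluded from the counts; ambiguity codes spread their weight
    uniformly over their residue set.
    """
    counts = np.zeros(4)
    gap_w = 0.0
    for ch, w in zip(chars, weights):
        if ch in GAP_CHARS:
            gap_w += w
            continue
        residues = IUPAC[ch]
        for r in residues:
            counts[NUC_INDEX[r]] += w / len(residues)
    total_w = float(weights.sum())
    gap_fraction = gap_w / total_w
    if counts.sum() == 0.0:
        return np.full(4, 0.25), gap_fraction
    return counts / counts.sum(), gap_fraction


class ProbabilisticAlignment:
    """Per-column nucleotide frequencies of an alignment, the object folded.

    ``single[k]`` is the 4-vector of kept column ``k``; :meth:`pair_freq`
    returns joint 4x4 frequencies computed lazily (and memoized) from the
    sequences that carry a residue at *both* columns.
    """

    def __init__(self, msa: MSA, kept: np.ndarray, single: np.ndarray,
                 gap_fraction: np.ndarray, weights: np.ndarray):
        self.msa = msa
        self.kept_columns = kept
        self.single = single
        self.gap_fraction = gap_fraction
        self.weights = weights
        self._pair_cache: dict[tuple[int, int], np.ndarray] = {}

    @property
    def L(self) -> int:
        return len(self.kept_columns)

    def pair_freq(self, i: int, j: int) -> np.ndarray:
        """Joint 4x4 frequency of kept columns ``i < j``.

        Computed over sequences non-gapped at both columns; if no sequence
        qualifies, falls back to the product of the single marginals.
        """
        if i >= j:
            raise ValueError("pair_freq requires i < j in kept coordinates")
        key = (i, j)
        if key in self._pair_cache:
            return self._pair_cache[key]
        ci = self.msa.column(int(self.kept_columns[i]))
        cj = self.msa.column(int(self.kept_columns[j]))
        joint = np.zeros((4, 4))
        for a, b, w in zip(ci, cj, self.weights):
            if a in GAP_CHARS or b in GAP_CHARS:
                continue
            ra, rb = IUPAC[a], IUPAC[b]
            wab = w / (len(ra) * len(rb))
            for x in ra:
                for y in rb:
                    joint[NUC_INDEX[x], NUC_INDEX[y]] += wab
        if joint.sum() == 0.0:
            joint = np.outer(self.single[i], self.single[j])
        else:
            joint = joint / joint.sum()
        self._pair_cache[key] = joint
        return joint


def build_probabilistic_alignment(
    msa: MSA, gap_max: float = 0.75, weights: np.ndarray | None = None
) -> tuple[ProbabilisticAlignment, ColumnMap]:
    """Build the probabilistic sequence of ``msa``.

    Columns with gap fraction > ``gap_max`` are dropped.  ``weights`` are
    per-sequence weights (uniform by default).
    """
    if not 0 < gap_max <= 1:
        raise ValueError("gap_max must be in (0, 1]")
    if weights is None:
        weights = np.ones(msa.n_seq)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (msa.n_seq,) or np.any(weights < 0) or weights.sum() == 0:
            raise ValueError("weights must be nonnegative, one per sequence")

    singles, gap_fracs, kept = [], [], []
    for j in range(msa.length):
        p, gf = _column_distribution(msa.column(j), weights)
        gap_fracs.append(gf)
        if gf <= gap_max:
            kept.append(j)
            singles.append(p)
            if gf == 1.0:
                log.warning(
                    "column %d is all gaps but retained by gap_max=%.2f; "
                    "treated as uniform", j + 1, gap_max,
                )
    colmap = ColumnMap(np.array(kept, dtype=int))
    pa = ProbabilisticAlignment(
        msa,
        kept=colmap.kept,
        single=np.array(singles).reshape(len(kept), 4),
        gap_fraction=np.array(gap_fracs),
        weights=weights,
    )
    return pa, colmap


def point_mass_alignment(seq: str) -> tuple[ProbabilisticAlignment, ColumnMap]:
    """Wrap a single (ungapped) sequence as an S=1 probabilistic alignment."""
    msa = MSA(sequence_ids=["seq"], rows=[seq])
    return build_probabilistic_alignment(msa, gap_max=1.0)


def shuffle_columns(msa: MSA, seed: int) -> MSA:
    """Permute the residues within each column, independently per column.

    The multiset of characters of every column is conserved exactly; this
    destroys covariation while preserving per-column base composition, the
    null used for control predictions and false-discovery estimates.
    """
    rng = np.random.default_rng(seed)
    cols = []
    for j in range(msa.length):
        chars = list(msa.column(j))
        rng.shuffle(chars)
        cols.append(chars)
    rows = ["".join(cols[j][s] for j in range(msa.length)) for s in range(msa.n_seq)]
    return MSA(
        sequence_ids=list(msa.sequence_ids),
        rows=rows,
        ss_cons=msa.ss_cons,
        gc_lines=dict(msa.gc_lines),
    )
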