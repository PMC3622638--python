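"""Transcript matching and accuracy metrics.

Predicted transcripts are compared to true ones through a compression-style
code: the cost of describing a true transcript ``T`` (sequence plus
expression) given a predicted transcript ``P`` is

    |gamma(d + 1)| + |editsencoded(T, P)| + |gamma(f(e(T) - e(P)))|

where ``d`` is the Levenshtein distance, ``gamma`` is the Elias-gamma
prefix-free code for positive integers, ``f`` maps signed integers
bijectively onto positive ones, and ``editsencoded`` spells out a minimal
edit script turning ``P`` into ``T``: for every edit, the run of identities
since the previous edit as ``gamma(run + 1)``, a 2-bit edit type
(substitution 00, insertion 01, deletion 10) and a 2-bit symbol
(A=00, C=01, G=10, T=11) for substitutions and insertions.  Deletions carry
no symbol and no trailing run is coded.

Truth and prediction sets are padded with empty zero-expression transcripts
to equal size and matched by an exact minimum-weight perfect matching on
this code length.  A matched pair is a true positive when its *bitscore*
(edit code length divided by the cost of describing ``T`` from nothing —
roughly, how little the prediction helps; can exceed 1) and its relative
expression difference ``|e(P) - e(T)| / e(T)`` both fall under the chosen
thresholds; precision, recall and F-measure follow.  Expression
thresholding can be disabled (sequence-only mode) by passing ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Transcript",
    "MatchPair",
    "MatchReport",
    "PRF",
    "gamma",
    "gamma_len",
    "f_bij",
    "edit_script",
    "edits_encoded_bits",
    "edit_code_length",
    "bitscore",
    "pair_cost",
    "match",
    "prf",
    "read_transcripts",
    "write_transcripts",
]

_SYMBOL_BITS = {"A": "00", "C": "01", "G": "10", "T": "11"}
_EDIT_BITS = {"sub": "00", "ins": "01", "del": "10"}


@dataclass(frozen=True)
class Transcript:
    """A nucleotide sequence with an expression level.

    Empty sequences with zero expression serve as padding in the bipartite
    matching; real transcripts have nonempty sequences over ACGT.
    """

    sequence: str
    expression: float
    name: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT symbols in sequence: {sorted(bad)}")
        if self.expression < 0:
            raise ValueError("expression must be nonnegative")


# ---------------------------------------------------------------------------
# integer codes


def gamma(x: int) -> str:
    """Elias-gamma code: ``len(bin(x)) - 1`` zeros followed by ``bin(x)``."""
    if x < 1:
        raise ValueError("gamma is defined for positive integers only")
    b = bin(x)[2:]
    return "0" * (len(b) - 1) + b


def gamma_len(x: int) -> int:
    """``|gamma(x)| = 2 * floor(log2 x) + 1`` without building the string."""
    if x < 1:
        raise ValueError("gamma is defined for positive integers only")
    return 2 * (x.bit_length() - 1) + 1


def f_bij(x: int) -> int:
    """Bijection {0, 1, -1, 2, -2, ...} -> {1, 2, 3, 4, 5, ...}."""
    return 2 * x if x > 0 else 2 * (-x) + 1


# ---------------------------------------------------------------------------
# edit distance and edit-script coding


def _edit_matrix(src: str, dst: str) -> np.ndarray:
    """Full Levenshtein DP table (rows: src prefix, cols: dst prefix)."""
    a = np.frombuffer(src.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(dst.encode("ascii"), dtype=np.uint8)
    n, m = len(a), len(b)
    D = np.empty((n + 1, m + 1), dtype=np.int32)
    D[0] = np.arange(m + 1)
    if n == 0:
        return D
    jidx = np.arange(m + 1, dtype=np.int32)
    tmp = np.empty(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        if m:
            diag = D[i - 1, :-1] + (a[i - 1] != b)
            base = np.minimum(D[i - 1, 1:] + 1, diag)
            tmp[0] = i
            tmp[1:] = base
        else:
            tmp[0] = i
        # fold in insertions (left-to-right dependency) via a cumulative min
        D[i] = jidx + np.minimum.accumulate(tmp - jidx)
    return D


def edit_script(src: str, dst: str) -> list[tuple[str, str]]:
    """Minimal edit script turning ``src`` into ``dst``.

    Returns ``(op, symbol)`` pairs in left-to-right order, ``op`` in
    {match, sub, ins, del}; the symbol is the target character (empty for
    deletions).  Among co-optimal scripts the traceback prefers
    match > substitution > deletion > insertion, so the script — and any
    code length derived from it — is deterministic.
    """
    D = _edit_matrix(src, dst)
    i, j = len(src), len(dst)
    ops: list[tuple[str, str]] = []
    while i > 0 or j > 0:
        d = D[i, j]
        if i > 0 and j > 0 and src[i - 1] == dst[j - 1] and D[i - 1, j - 1] == d:
            ops.append(("match", dst[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and j > 0 and D[i - 1, j - 1] + 1 == d:
            ops.append(("sub", dst[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and D[i - 1, j] + 1 == d:
            ops.append(("del", ""))
            i -= 1
        else:
            ops.append(("ins", dst[j - 1]))
            j -= 1
    ops.reverse()
    return ops


def edits_encoded_bits(truth_seq: str, pred_seq: str) -> int:
    """Bit length of ``editsencoded`` for describing truth given prediction."""
    bits = 0
    gap = 0
    for op, _sym in edit_script(pred_seq, truth_seq):
        if op == "match":
            gap += 1
            continue
        bits += gamma_len(gap + 1) + 2  # run of identities + edit type
        if op != "del":
            bits += 2  # substituted / inserted symbol
        gap = 0
    return bits


def edit_code_length(truth: Transcript, pred: Transcript) -> tuple[int, int]:
    """Levenshtein distance ``d`` and bits of ``gamma(d+1) editsencoded``."""
    d = int(_edit_matrix(pred.sequence, truth.sequence)[-1, -1])
    bits = gamma_len(d + 1) + edits_encoded_bits(truth.sequence, pred.sequence)
    return d, bits


def bitscore(truth: Transcript, pred: Transcript) -> float:
    """Edit code length normalized by the cost of coding truth from nothing."""
    if not truth.sequence:
        raise ValueError("bitscore is undefined for an empty truth sequence")
    _, bits = edit_code_length(truth, pred)
    denom = gamma_len(len(truth.sequence) + 1) + edits_encoded_bits(truth.sequence, "")
    return bits / denom


def pair_cost(truth: Transcript, pred: Transcript) -> int:
    """Matching edge cost: edit code plus coded expression difference."""
    _, bits = edit_code_length(truth, pred)
    delta = int(round(truth.expression)) - int(round(pred.expression))
    return bits + gamma_len(f_bij(delta))


# ---------------------------------------------------------------------------
# bipartite matching and metrics


@dataclass(frozen=True)
class MatchPair:
    truth_index: int
    pred_index: int
    truth_real: bool
    pred_real: bool
    distance: int
    code_bits: int
    cost: int
    bitscore: float | None  # None when the truth side is padding
    rel_expr_diff: float | None  # None when the truth side is padding


@dataclass
class MatchReport:
    pairs: list[MatchPair]
    n_truth: int
    n_pred: int
    total_cost: int


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f_measure: float
    tp: int
    fp: int
    fn: int


_PADDING = Transcript("", 0)


def match(truth: Sequence[Transcript], pred: Sequence[Transcript]) -> MatchReport:
    """Exact minimum-weight perfect matching of truth against prediction.

    Both sides are padded with empty zero-expression transcripts to equal
    size; the per-prediction index term of the code cancels across any
    perfect matching and is omitted.
    """
    n = max(len(truth), len(pred), 1)
    ts = list(truth) + [_PADDING] * (n - len(truth))
    ps = list(pred) + [_PADDING] * (n - len(pred))
    cost = np.empty((n, n), dtype=np.int64)
    bits_cache = np.empty((n, n, 2), dtype=np.int64)
    for i, t in enumerate(ts):
        for k, p in enumerate(ps):
            d, bits = edit_code_length(t, p)
            bits_cache[i, k] = (d, bits)
            delta = int(round(t.expression)) - int(round(p.expression))
            cost[i, k] = bits + gamma_len(f_bij(delta))
    rows, cols = linear_sum_assignment(cost)
    pairs: list[MatchPair] = []
    for i, k in zip(rows, cols):
        t, p = ts[i], ps[k]
        t_real, p_real = i < len(truth), k < len(pred)
        d, bits = int(bits_cache[i, k, 0]), int(bits_cache[i, k, 1])
        bs = rel = None
        if t_real and t.sequence:
            denom = gamma_len(len(t.sequence) + 1) + edits_encoded_bits(t.sequence, "")
            bs = bits / denom
            if t.expression > 0:
                rel = abs(p.expression - t.expression) / t.expression
            else:
                rel = 0.0 if p.expression == 0 else float("inf")
        pairs.append(MatchPair(i, k, t_real, p_real, d, bits,
                               int(cost[i, k]), bs, rel))
    return MatchReport(pairs=pairs, n_truth=len(truth), n_pred=len(pred),
                       total_cost=int(cost[rows, cols].sum()))


def prf(report: MatchReport, expr_threshold: float | None,
        bitscore_threshold: float) -> PRF:
    """Precision/recall/F at the given thresholds.

    A true positive is a matched real-vs-real pair with bitscore at most
    ``bitscore_threshold`` and, unless ``expr_threshold`` is ``None``,
    relative expression difference at most ``expr_threshold``.
    """
    if bitscore_threshold < 0 or (expr_threshold is not None and expr_threshold < 0):
        raise ValueError("thresholds must be nonnegative")
    tp = 0
    for pair in report.pairs:
        if not (pair.truth_real and pair.pred_real):
            continue
        if pair.bitscore is None or pair.bitscore > bitscore_threshold:
            continue
        if expr_threshold is not None and (
            pair.rel_expr_diff is None or pair.rel_expr_diff > expr_threshold
        ):
            continue
        tp += 1
    fp = report.n_pred - tp
    fn = report.n_truth - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    return PRF(precision, recall, f, tp, fp, fn)


# ---------------------------------------------------------------------------
# file interfaces: FASTA sequences + TSV expression levels


def read_transcripts(fasta: str | Path, expr_tsv: str | Path) -> list[Transcript]:
    from Bio import SeqIO

    expr: dict[str, float] = {}
    with Path(expr_tsv).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, value = line.split("\t")
            expr[name] = float(value)
    out = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id not in expr:
            raise ValueError(f"no expression level for transcript {rec.id}")
        out.append(Transcript(str(rec.seq).upper(), expr[rec.id], name=rec.id))
    return out


def write_transcripts(transcripts: Iterable[Transcript], fasta: str | Path,
                      expr_tsv: str | Path) -> None:
    transcripts = list(transcripts)
    with Path(fasta).open("w") as fh:
        for i, t in enumerate(transcripts):
            name = t.name or f"tx{i + 1}"
            fh.write(f">{name}\n{t.sequence}\n")
    with Path(expr_tsv).open("w") as fh:
        for i, t in enumerate(transcripts):
            name = t.name or f"tx{i + 1}"
            fh.write(f"{name}\t{t.expression:g}\n")
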