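"""Greedy identity clustering and cross-set redundancy tabulation.

This is a transparent stand-in for cd-hit / cdhit-est: sequences are
processed longest-first and each joins the first existing cluster whose
representative it matches at >= the identity threshold, else founds a new
cluster.  Identity follows the cd-hit convention: identical aligned
positions in the best local alignment divided by the length of the shorter
sequence.  A shared-k-mer prefilter (word sizes 8 for nucleotide, 5 for
protein, mirroring cd-hit's -n) may skip obviously unrelated pairs at
thresholds >= 0.95; it is advisory only and never decides correctness.

The local aligner is an affine-gap Smith-Waterman (match +1, mismatch -2,
gap open 2, gap extend 1; a gap of length g costs 2 + g).  'X' and 'N'
never score as matches and never count as identical positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

MATCH = 1.0
MISMATCH = -2.0
GAP_OPEN = 2.0   # charged once per gap, on top of the per-residue extension
GAP_EXTEND = 1.0

WORD_SIZE_NT = 8
WORD_SIZE_AA = 5

_AMBIGUOUS = frozenset("XN")


@dataclass
class SWResult:
    """Best local alignment of a (query) vs b (subject)."""

    score: float
    identities: int
    aln_length: int          # alignment columns, gaps included
    query_start: int         # 0-based half-open on a
    query_end: int
    subject_start: int       # 0-based half-open on b
    subject_end: int


def smith_waterman(a: str, b: str) -> SWResult:
    """Affine-gap local alignment by the Gotoh recurrence.

    The horizontal gap state is computed with a running-maximum scan, so the
    DP is vectorised along the subject axis.  Ties are resolved toward the
    smallest (query_end, subject_end) cell and a diagonal > up > left
    traceback preference, which is deterministic.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    b_arr = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    amb = np.isin(b_arr, np.frombuffer(b"XN", dtype=np.uint8))

    NEG = -1e30
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)   # gap in subject (vertical move)
    Iy = np.full((n + 1, m + 1), NEG)   # gap in query (horizontal move)
    j_idx = np.arange(m + 1, dtype=float)

    for i in range(1, n + 1):
        ai = ord(a[i - 1])
        sub = np.where((b_arr == ai) & ~amb & (ai not in (88, 78)), MATCH, MISMATCH)
        prev_best = np.maximum(np.maximum(M[i - 1, :-1], Ix[i - 1, :-1]),
                               Iy[i - 1, :-1])
        M[i, 1:] = np.maximum(0.0, prev_best + sub)
        Ix[i, :] = np.maximum(M[i - 1, :] - GAP_OPEN - GAP_EXTEND,
                              Ix[i - 1, :] - GAP_EXTEND)
        # Iy[i, j] = max_{k<j} M[i, k] - GAP_OPEN - (j-k)*GAP_EXTEND
        run = np.maximum.accumulate(M[i, :] + j_idx * GAP_EXTEND)
        Iy[i, 1:] = run[:-1] - GAP_OPEN - j_idx[1:] * GAP_EXTEND

    # best cell: maximum of M; np.argmax returns the row-major first maximum,
    # i.e. smallest query_end then subject_end
    flat = int(np.argmax(M))
    i, j = divmod(flat, m + 1)
    score = float(M[i, j])
    if score <= 0.0:
        return SWResult(0.0, 0, 0, 0, 0, 0, 0)

    qe, se = i, j
    identities = 0
    aln_length = 0
    state = "M"
    while True:
        if state == "M":
            ca, cb = a[i - 1], b[j - 1]
            is_match = ca == cb and ca not in _AMBIGUOUS
            if is_match:
                identities += 1
            aln_length += 1
            prev = M[i, j] - (MATCH if is_match else MISMATCH)
            i, j = i - 1, j - 1
            if prev < 1e-9:
                break  # local alignment start
            if abs(M[i, j] - prev) < 1e-9:
                state = "M"
            elif abs(Ix[i, j] - prev) < 1e-9:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            aln_length += 1
            val = Ix[i, j]
            i -= 1
            if abs(M[i, j] - GAP_OPEN - GAP_EXTEND - val) < 1e-9:
                state = "M"
            else:
                state = "Ix"
        else:  # Iy
            aln_length += 1
            val = Iy[i, j]
            j -= 1
            if abs(M[i, j] - GAP_OPEN - GAP_EXTEND - val) < 1e-9:
                state = "M"
            else:
                state = "Iy"
    return SWResult(score, identities, aln_length, i, qe, j, se)


def pairwise_identity(a: str, b: str, alphabet: str = "nucleotide") -> float:
    """cd-hit-style identity: identical aligned positions / shorter length."""
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    res = smith_waterman(a, b)
    return res.identities / min(len(a), len(b))


@dataclass
class SequenceCluster:
    """A representative plus its members at a stated identity threshold."""

    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    threshold: float = 0.95

    @property
    def size(self) -> int:
        return 1 + len(self.member_ids)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def greedy_cluster(
    records: Sequence[tuple[str, str]],
    threshold: float = 0.95,
    word_size: int | None = None,
    alphabet: str = "nucleotide",
    use_prefilter: bool = True,
) -> list[SequenceCluster]:
    """Greedy incremental clustering, longest sequence first.

    ``records`` is a sequence of (id, sequence) pairs.  Each sequence joins
    the first existing cluster (creation order) whose representative
    identity is >= ``threshold``, else it founds a new cluster; since
    sequences are processed longest-first, representatives are always the
    longest member.  The k-mer prefilter only applies at thresholds >= 0.95.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if word_size is None:
        word_size = WORD_SIZE_NT if alphabet == "nucleotide" else WORD_SIZE_AA
    if word_size < 1:
        raise ValueError("word_size must be >= 1")
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in clustering input")

    order = sorted(range(len(records)), key=lambda k: (-len(records[k][1]), k))
    prefilter = use_prefilter and threshold >= 0.95

    clusters: list[SequenceCluster] = []
    rep_seqs: list[str] = []
    rep_kmers: list[set[str]] = []
    for idx in order:
        sid, seq = records[idx]
        km = _kmers(seq, word_size) if prefilter else None
        placed = False
        for c, rseq, rkm in zip(clusters, rep_seqs, rep_kmers):
            if km is not None and not (km & rkm):
                continue
            if pairwise_identity(seq, rseq, alphabet) >= threshold:
                c.member_ids.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster(sid, [], threshold))
            rep_seqs.append(seq)
            rep_kmers.append(km if km is not None else set())
    return clusters


def redundant_count(clusters: Iterable[SequenceCluster]) -> int:
    """Sequences beyond one representative per cluster (N - #clusters)."""
    return sum(len(c.member_ids) for c in clusters)


@dataclass
class RedundancyReport:
    """Redundant/similar-sequence counts per set combination and threshold.

    'Redundant' means non-representative members for a single set, and, for
    a combination of sets, sequences belonging to pooled clusters that mix
    at least two source sets.
    """

    thresholds: list[float]
    counts: dict[tuple[tuple[str, ...], float], int]

    def get(self, combination: Sequence[str], threshold: float) -> int:
        return self.counts[(tuple(combination), threshold)]

    def to_tsv(self) -> str:
        lines = ["combination\tthreshold\tredundant_count"]
        for (combo, thr), n in self.counts.items():
            lines.append(f"{'-'.join(combo)}\t{thr:g}\t{n}")
        return "\n".join(lines) + "\n"


def cross_set_redundancy(
    sets: Mapping[str, Sequence[tuple[str, str]]],
    thresholds: Sequence[float],
    alphabet: str = "protein",
    combinations: Sequence[Sequence[str]] | None = None,
) -> RedundancyReport:
    """Single-set redundancy and multi-set similarity at several thresholds.

    By default every non-empty combination of the named sets is reported
    (singles, pairs, ..., all), mirroring a multi-database comparison table.
    """
    if not sets:
        raise ValueError("need at least one named set")
    names = list(sets)
    if combinations is None:
        combinations = [
            combo
            for r in range(1, len(names) + 1)
            for combo in itertools.combinations(names, r)
        ]
    for combo in combinations:
        for name in combo:
            if name not in sets:
                raise ValueError(f"unknown set name {name!r}")

    counts: dict[tuple[tuple[str, ...], float], int] = {}
    for thr in thresholds:
        for combo in combinations:
            combo = tuple(combo)
            if len(combo) == 1:
                clusters = greedy_cluster(
                    list(sets[combo[0]]), thr, alphabet=alphabet
                )
                counts[(combo, thr)] = redundant_count(clusters)
            else:
                pooled = [
                    (f"{name}::{sid}", seq)
                    for name in combo
                    for sid, seq in sets[name]
                ]
                clusters = greedy_cluster(pooled, thr, alphabet=alphabet)
                total = 0
                for c in clusters:
                    members = [c.representative_id, *c.member_ids]
                    sources = {mid.split("::", 1)[0] for mid in members}
                    if len(sources) >= 2:
                        total += len(members)
                counts[(combo, thr)] = total
    return RedundancyReport(list(thresholds), counts)


def write_clstr(clusters: Sequence[SequenceCluster], path) -> None:
    """cd-hit ``.clstr``-like text output."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, c in enumerate(clusters):
            fh.write(f">Cluster {i}\n")
            fh.write(f"0\t{c.representative_id} *\n")
            for j, mid in enumerate(c.member_ids, start=1):
                fh.write(f"{j}\t{mid} at >={c.threshold:.0%}\n")
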