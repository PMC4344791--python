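"""Independent oracles shared by the unit and acceptance suites.

These deliberately avoid the implementation paths they check: the Viterbi
oracle enumerates every legal state path; the clustering oracle replays the
greedy order over a brute-force all-pairs identity matrix; the alignment
oracle is biopython's PairwiseAligner.
"""

import math

import numpy as np
from Bio import Align

from wheattf.hmm import AA_INDEX, ProfileHMM
from wheattf.redundancy import pairwise_identity


def brute_force_viterbi(profile: ProfileHMM, protein: str) -> float:
    """Exhaustive enumeration of every legal local state path."""
    L = profile.L
    n = len(protein)
    bg = profile.background

    def lo_match(j, i):
        e = profile.match_emissions[j, AA_INDEX[protein[i]]]
        return -math.inf if e == 0 else math.log2(e / bg[AA_INDEX[protein[i]]])

    def lo_insert(i):
        e = profile.insert_emissions[AA_INDEX[protein[i]]]
        return -math.inf if e == 0 else math.log2(e / bg[AA_INDEX[protein[i]]])

    def lt(j, key):
        idx = {"MM": 0, "MI": 1, "MD": 2, "IM": 3, "II": 4,
               "DM": 5, "DD": 6}[key]
        t = profile.transitions[j, idx]
        return -math.inf if t == 0 else math.log2(t)

    best = -math.inf

    def extend(state, j, i, score):
        nonlocal best
        if state == "M":
            best = max(best, score)  # free exit from any match state
        if i < n and j + 1 < L:
            s = score + lt(j, state + "M") + lo_match(j + 1, i)
            if s > -math.inf:
                extend("M", j + 1, i + 1, s)
        if i < n and state in ("M", "I"):
            s = score + lt(j, state + "I") + lo_insert(i)
            if s > -math.inf:
                extend("I", j, i + 1, s)
        if j + 1 < L and state in ("M", "D"):
            s = score + lt(j, state + "D")
            if s > -math.inf:
                extend("D", j + 1, i, s)

    for j0 in range(L):
        for i0 in range(n):
            s0 = lo_match(j0, i0)
            if s0 > -math.inf:
                extend("M", j0, i0 + 1, s0)
    return best


def random_profile(rng, L) -> ProfileHMM:
    match = rng.dirichlet(np.ones(20), size=L)
    m_out = rng.dirichlet(np.ones(3), size=L)
    i_out = rng.dirichlet(np.ones(2), size=L)
    d_out = rng.dirichlet(np.ones(2), size=L)
    transitions = np.hstack([m_out, i_out, d_out])
    bg = rng.dirichlet(np.ones(20) * 50)
    return ProfileHMM(
        family="toy",
        match_emissions=match,
        insert_emissions=bg.copy(),
        transitions=transitions,
        background=bg,
    )


def brute_force_replay(records, threshold):
    """All-pairs identity matrix + the same greedy order, no prefilter."""
    order = sorted(range(len(records)), key=lambda k: (-len(records[k][1]), k))
    clusters = []
    for idx in order:
        sid, seq = records[idx]
        for c in clusters:
            if pairwise_identity(seq, c[1]) >= threshold:
                c[2].append(sid)
                break
        else:
            clusters.append((sid, seq, []))
    return [(rep, tuple(members)) for rep, _, members in clusters]


def biopython_local_score(a: str, b: str) -> float:
    """Affine-gap local alignment score via an independent aligner."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    return aligner.score(a, b)
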