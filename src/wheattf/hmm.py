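"""Per-family profile HMMs: build from seed alignments, Viterbi local scan,
Gumbel E-value calibration.

The model is a deliberately small profile HMM ("Plan7-lite"): match states
with position-specific emissions, insert states sharing a single background
emission distribution, delete states, and Smith-Waterman-style local
entry/exit (free entry into any match state, free exit from any match
state; flanking residues are emitted by the background and cancel out of
the log-odds).  There is no multi-hit (J) state: one best domain per
protein per family, which is all a presence/absence family call needs.

Scores are log-odds in bits: log2(path probability / background probability
of the aligned residues).  E-values come from a Gumbel distribution fitted
to Viterbi scores of random background-composed proteins by the method of
moments, so a hit's E-value is the expected number of equally good chance
hits in a database of N scanned proteins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .orf import ProteinCandidate

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS = frozenset("-.")

#: transition order: M->M, M->I, M->D, I->M, I->I, D->M, D->D
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)

EULER_GAMMA = 0.5772156649015329
NEG_INF = -1e30


@dataclass(frozen=True)
class SeedAlignment:
    """A gapped protein multiple alignment for one family."""

    family: str
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("seed alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("all alignment rows must have equal length")
        for r in self.rows:
            bad = set(r) - set(AMINO_ACIDS) - GAP_CHARS
            if bad:
                raise ValueError(f"invalid alignment characters {sorted(bad)!r}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass
class ProfileHMM:
    """A per-family scoring model over L match states.

    ``match_emissions`` is (L, 20), ``insert_emissions`` (20,) shared across
    insert states, ``transitions`` (L, 7) in the order M->M, M->I, M->D,
    I->M, I->I, D->M, D->D (row j governs moves out of position j),
    ``background`` (20,).  ``gumbel_mu``/``gumbel_lambda`` are set by
    :func:`calibrate_evalue`.
    """

    family: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray
    gumbel_mu: float | None = None
    gumbel_lambda: float | None = None

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.L < 1:
            raise ValueError("profile needs at least one match state")
        tol = 1e-9
        if np.any(np.abs(self.match_emissions.sum(axis=1) - 1.0) > tol):
            raise ValueError("match emission rows must sum to 1")
        if abs(self.insert_emissions.sum() - 1.0) > tol:
            raise ValueError("insert emissions must sum to 1")
        if abs(self.background.sum() - 1.0) > tol:
            raise ValueError("background must sum to 1")
        t = self.transitions
        for idxs, name in (
            ((T_MM, T_MI, T_MD), "M"),
            ((T_IM, T_II), "I"),
            ((T_DM, T_DD), "D"),
        ):
            if np.any(np.abs(t[:, list(idxs)].sum(axis=1) - 1.0) > tol):
                raise ValueError(f"{name}-state outgoing transitions must sum to 1")
        if self.gumbel_lambda is not None and self.gumbel_lambda <= 0:
            raise ValueError("gumbel_lambda must be > 0")

    @property
    def L(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def calibrated(self) -> bool:
        return self.gumbel_mu is not None and self.gumbel_lambda is not None

    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": 1,
                "family": self.family,
                "match_emissions": self.match_emissions.tolist(),
                "insert_emissions": self.insert_emissions.tolist(),
                "transitions": self.transitions.tolist(),
                "background": self.background.tolist(),
                "gumbel_mu": self.gumbel_mu,
                "gumbel_lambda": self.gumbel_lambda,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ProfileHMM":
        d = json.loads(text)
        if d.get("format_version") != 1:
            raise ValueError("unsupported profile format version")
        return cls(
            family=d["family"],
            match_emissions=np.array(d["match_emissions"]),
            insert_emissions=np.array(d["insert_emissions"]),
            transitions=np.array(d["transitions"]),
            background=np.array(d["background"]),
            gumbel_mu=d["gumbel_mu"],
            gumbel_lambda=d["gumbel_lambda"],
        )


@dataclass(frozen=True)
class DomainHit:
    """One best-domain hit of a protein against a family profile."""

    protein_id: str
    family: str
    bit_score: float
    e_value: float
    ali_start: int
    ali_end: int

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not (0 <= self.ali_start < self.ali_end):
            raise ValueError("need 0 <= ali_start < ali_end")


def build_profile(
    seed: SeedAlignment,
    gap_fraction_max: float = 0.5,
    pseudocount: float = 1.0,
) -> ProfileHMM:
    """Estimate a profile from a seed alignment with Laplace-style smoothing.

    Match columns are those with gap fraction < ``gap_fraction_max``; match
    emissions are (count + pseudocount) / (non-gap count + 20*pseudocount);
    transition probabilities come from the observed per-row state paths,
    pooled over positions, with the same additive smoothing.  Insert
    emissions equal the (smoothed) overall residue frequency of the seed.
    """
    if not (0.0 < gap_fraction_max < 1.0):
        raise ValueError("gap_fraction_max must be in (0, 1)")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    n_rows = len(seed.rows)
    n_cols = seed.n_columns
    is_gap = np.array(
        [[c in GAP_CHARS for c in row] for row in seed.rows], dtype=bool
    )
    gap_frac = is_gap.mean(axis=0)
    match_cols = np.where(gap_frac < gap_fraction_max)[0]
    L = len(match_cols)
    if L == 0:
        raise ValueError("no column passes the gap-fraction threshold")

    # background: overall residue frequency, smoothed
    bg_counts = np.full(20, pseudocount)
    for row in seed.rows:
        for c in row:
            if c not in GAP_CHARS:
                bg_counts[AA_INDEX[c]] += 1
    background = bg_counts / bg_counts.sum()

    match_em = np.full((L, 20), pseudocount)
    for k, col in enumerate(match_cols):
        for row in seed.rows:
            c = row[col]
            if c not in GAP_CHARS:
                match_em[k, AA_INDEX[c]] += 1
    match_em /= match_em.sum(axis=1, keepdims=True)

    # observed state paths: M/D at match columns, I at insert columns
    match_set = set(match_cols.tolist())
    t_counts = np.zeros(7)
    for row in seed.rows:
        path: list[str] = []
        for col in range(n_cols):
            if col in match_set:
                path.append("D" if row[col] in GAP_CHARS else "M")
            elif row[col] not in GAP_CHARS:
                path.append("I")
        for s0, s1 in zip(path, path[1:]):
            key = s0 + s1
            idx = {
                "MM": T_MM, "MI": T_MI, "MD": T_MD,
                "IM": T_IM, "II": T_II,
                "DM": T_DM, "DD": T_DD,
            }.get(key)
            if idx is not None:  # I->D / D->I not modelled; skipped
                t_counts[idx] += 1

    t = np.empty(7)
    for idxs in ((T_MM, T_MI, T_MD), (T_IM, T_II), (T_DM, T_DD)):
        idxs = list(idxs)
        sub = t_counts[idxs] + pseudocount
        t[idxs] = sub / sub.sum()
    transitions = np.tile(t, (L, 1))

    return ProfileHMM(
        family=seed.family,
        match_emissions=match_em,
        insert_emissions=background.copy(),
        transitions=transitions,
        background=background,
    )


def _log_odds_tables(profile: ProfileHMM):
    # zero probabilities (legal in hand-built profiles) map to -inf safely
    with np.errstate(divide="ignore"):
        lm = np.log2(profile.match_emissions / profile.background)   # (L, 20)
        li = np.log2(profile.insert_emissions / profile.background)  # (20,)
        lt = np.log2(profile.transitions)                            # (L, 7)
    lt = np.where(np.isfinite(lt), lt, NEG_INF)
    lm = np.where(np.isfinite(lm), lm, NEG_INF)
    li = np.where(np.isfinite(li), li, NEG_INF)
    return lm, li, lt


def viterbi_score(
    profile: ProfileHMM, protein: str
) -> tuple[float, int, int]:
    """Best local log-odds path score in bits, plus the aligned span.

    Entry into any match state and exit from any match state are free;
    residues outside the span are background-emitted and contribute zero.
    Returns ``(bit_score, ali_start, ali_end)`` with 0-based half-open
    protein coordinates of the aligned region.
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    L = profile.L
    n = len(protein)
    lm, li, lt = _log_odds_tables(profile)
    # unknown residues (X): zero log-odds for emission
    xi = np.array([AA_INDEX.get(c, -1) for c in protein])

    tMM, tMI, tMD = lt[:, T_MM], lt[:, T_MI], lt[:, T_MD]
    tIM, tII = lt[:, T_IM], lt[:, T_II]
    tDM, tDD = lt[:, T_DM], lt[:, T_DD]
    C = np.concatenate([[0.0], np.cumsum(tDD[:-1])])  # C[j] = sum_{u<j} tDD[u]

    VM = np.full((n + 1, L), NEG_INF)
    VI = np.full((n + 1, L), NEG_INF)
    VD = np.full((n + 1, L), NEG_INF)

    for i in range(1, n + 1):
        em = lm[:, xi[i - 1]] if xi[i - 1] >= 0 else np.zeros(L)
        prevM, prevI, prevD = VM[i - 1], VI[i - 1], VD[i - 1]
        best_prev = np.full(L, 0.0)  # free entry
        cont = np.full(L, NEG_INF)
        cont[1:] = np.maximum(
            np.maximum(prevM[:-1] + tMM[:-1], prevI[:-1] + tIM[:-1]),
            prevD[:-1] + tDM[:-1],
        )
        VM[i] = em + np.maximum(best_prev, cont)
        VI[i] = (li[xi[i - 1]] if xi[i - 1] >= 0 else 0.0) + np.maximum(
            prevM + tMI, prevI + tII
        )
        # VD[i, j] = max_{k<j} VM[i, k] + tMD[k] + sum_{k<u<j} tDD[u]
        B = VM[i, :-1] + tMD[:-1] - C[1:]
        VD[i, 1:] = np.maximum.accumulate(B) + C[1:]

    flat = int(np.argmax(VM[1:]))
    i_star, j_star = divmod(flat, L)
    i_star += 1
    score = float(VM[i_star, j_star])
    ali_end = i_star  # half-open
    ali_start = _traceback_start(
        VM, VI, VD, lm, li, lt, C, xi, i_star, j_star
    )
    return score, ali_start, ali_end


def _traceback_start(VM, VI, VD, lm, li, lt, C, xi, i, j) -> int:
    """Walk the optimal path back to the free-entry cell; return its 0-based
    protein index (the first aligned residue)."""
    tol = 1e-6
    state = "M"
    while True:
        if state == "M":
            em = lm[j, xi[i - 1]] if xi[i - 1] >= 0 else 0.0
            prev = VM[i, j] - em
            if prev < tol and prev > -tol:
                return i - 1  # free entry here
            pi, pj = i - 1, j - 1
            if pj >= 0:
                if abs(VM[pi, pj] + lt[pj, T_MM] - prev) < tol:
                    i, j, state = pi, pj, "M"
                    continue
                if abs(VI[pi, pj] + lt[pj, T_IM] - prev) < tol:
                    i, j, state = pi, pj, "I"
                    continue
                if abs(VD[pi, pj] + lt[pj, T_DM] - prev) < tol:
                    i, j, state = pi, pj, "D"
                    continue
            return i - 1  # entry (numerically indistinct)
        elif state == "I":
            em = li[xi[i - 1]] if xi[i - 1] >= 0 else 0.0
            prev = VI[i, j] - em
            pi = i - 1
            if abs(VM[pi, j] + lt[j, T_MI] - prev) < tol:
                i, state = pi, "M"
            else:
                i, state = pi, "I"
        else:  # D: does not consume a residue
            pj = j - 1
            if abs(VM[i, pj] + lt[pj, T_MD] - VD[i, j]) < tol:
                j, state = pj, "M"
            else:
                j, state = pj, "D"


def calibrate_evalue(
    profile: ProfileHMM,
    n_random: int = 200,
    mean_len: int = 100,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """Fit a Gumbel to Viterbi scores of random background proteins.

    Method of moments: lambda = pi / (sigma * sqrt(6)),
    mu = mean - EulerGamma / lambda.  Sets and returns (mu, lambda).
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100 for a stable fit")
    rng = np.random.default_rng(rng_seed)
    scores = np.empty(n_random)
    for k in range(n_random):
        seq = "".join(
            rng.choice(list(AMINO_ACIDS), size=mean_len, p=profile.background)
        )
        scores[k], _, _ = viterbi_score(profile, seq)
    sigma = float(scores.std())
    if sigma < 1e-12:
        raise ValueError("degenerate score variance; cannot calibrate")
    lam = math.pi / (sigma * math.sqrt(6.0))
    mu = float(scores.mean()) - EULER_GAMMA / lam
    profile.gumbel_mu = mu
    profile.gumbel_lambda = lam
    return mu, lam


def evalue(profile: ProfileHMM, bit_score: float, n_database: int) -> float:
    """Expected chance hits scoring >= bit_score in n_database sequences."""
    if not profile.calibrated:
        raise ValueError(f"profile {profile.family!r} is not calibrated")
    e = n_database * math.exp(
        -profile.gumbel_lambda * (bit_score - profile.gumbel_mu)
    )
    return min(max(e, 0.0), float(n_database))


def scan(
    proteins: Sequence[ProteinCandidate],
    profiles: Iterable[ProfileHMM],
    e_max: float = 0.01,
) -> list[DomainHit]:
    """Scan every protein against every profile; keep hits with E < e_max.

    The database size N for the E-value is the number of scanned proteins.
    Hits are sorted by (protein_id, e_value, family).
    """
    proteins = list(proteins)
    profiles = list(profiles)
    for p in profiles:
        if not p.calibrated:
            raise ValueError(f"profile {p.family!r} is not calibrated")
    n_db = len(proteins)
    hits: list[DomainHit] = []
    for cand in proteins:
        for prof in profiles:
            score, s, e = viterbi_score(prof, cand.protein)
            ev = evalue(prof, score, n_db)
            if ev < e_max:
                hits.append(
                    DomainHit(cand.source_id, prof.family, score, ev, s, e)
                )
    hits.sort(key=lambda h: (h.protein_id, h.e_value, h.family))
    return hits


def read_seed_alignment(path, family: str | None = None) -> SeedAlignment:
    """Read an aligned FASTA (or Stockholm: .sto/.stk) seed alignment.

    The family name defaults to the file stem.
    """
    from pathlib import Path

    from Bio import AlignIO

    path = Path(path)
    fmt = "stockholm" if path.suffix in (".sto", ".stk") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    rows = tuple(str(rec.seq).upper() for rec in aln)
    return SeedAlignment(family or path.stem, rows)


def write_seed_alignment(seed: SeedAlignment, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, row in enumerate(seed.rows, start=1):
            fh.write(f">{seed.family}_{i}\n{row}\n")


def hits_to_tsv(hits: Sequence[DomainHit]) -> str:
    lines = ["protein_id\tfamily\tbit_score\te_value\tali_start\tali_end"]
    for h in hits:
        lines.append(
            f"{h.protein_id}\t{h.family}\t{h.bit_score:.3f}\t"
            f"{h.e_value:.3g}\t{h.ali_start}\t{h.ali_end}"
        )
    return "\n".join(lines) + "\n"
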