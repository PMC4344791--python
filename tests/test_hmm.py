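import math

import numpy as np
import pytest

from wheattf.hmm import (
    AMINO_ACIDS,
    AA_INDEX,
    DomainHit,
    ProfileHMM,
    SeedAlignment,
    build_profile,
    calibrate_evalue,
    evalue,
    read_seed_alignment,
    scan,
    viterbi_score,
    write_seed_alignment,
)
from wheattf.orf import ProteinCandidate, best_protein


from _oracles import brute_force_viterbi, random_profile


def test_viterbi_equals_exhaustive_enumeration():
    rng = np.random.default_rng(17)
    n_checked = 0
    for p in range(5):
        profile = random_profile(rng, L=int(rng.integers(2, 5)))
        for q in range(20):
            protein = "".join(rng.choice(list(AMINO_ACIDS),
                                         size=int(rng.integers(1, 7))))
            got, s, e = viterbi_score(profile, protein)
            expected = brute_force_viterbi(profile, protein)
            assert got == pytest.approx(expected, abs=1e-6)
            assert 0 <= s < e <= len(protein)
            n_checked += 1
    assert n_checked == 100


# ------------------------------------------------------------------- build

def test_match_emission_smoothing_formula():
    seed = SeedAlignment("F", ("K", "K", "K"))
    profile = build_profile(seed, pseudocount=1.0)
    assert profile.L == 1
    assert profile.match_emissions[0, AA_INDEX["K"]] == pytest.approx(4 / 23)
    # every other residue gets the bare pseudocount
    assert profile.match_emissions[0, AA_INDEX["A"]] == pytest.approx(1 / 23)


def test_majority_gap_column_excluded():
    seed = SeedAlignment("F", ("KA-", "KC-", "KDE"))
    profile = build_profile(seed, gap_fraction_max=0.5)
    assert profile.L == 2  # third column is 2/3 gaps


def test_all_gap_alignment_is_error():
    seed = SeedAlignment("F", ("--", "--", "AA"))
    with pytest.raises(ValueError, match="gap-fraction"):
        build_profile(seed, gap_fraction_max=0.3)


def test_built_profiles_normalize(tiny_seeds):
    seeds, _, _ = tiny_seeds
    for seed in seeds.values():
        p = build_profile(seed)
        assert np.allclose(p.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert p.insert_emissions.sum() == pytest.approx(1.0, abs=1e-9)
        t = p.transitions
        assert np.allclose(t[:, :3].sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(t[:, 3:5].sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(t[:, 5:].sum(axis=1), 1.0, atol=1e-9)


def test_profile_json_round_trip(tiny_seeds):
    seeds, _, _ = tiny_seeds
    p = build_profile(next(iter(seeds.values())))
    calibrate_evalue(p, rng_seed=5)
    q = ProfileHMM.from_json(p.to_json())
    assert q.family == p.family
    assert np.allclose(q.match_emissions, p.match_emissions)
    assert q.gumbel_mu == p.gumbel_mu


def test_seed_alignment_file_round_trip(tmp_path, tiny_seeds):
    seeds, _, _ = tiny_seeds
    seed = next(iter(seeds.values()))
    write_seed_alignment(seed, tmp_path / "fam.afa")
    back = read_seed_alignment(tmp_path / "fam.afa", family=seed.family)
    assert back.rows == seed.rows


# ----------------------------------------------------------------- viterbi

def test_consensus_score_closed_form():
    # deterministic profile: one-hot emissions, M->M = 1, uniform background
    consensus = "KWD"
    L = len(consensus)
    match = np.zeros((L, 20))
    for j, c in enumerate(consensus):
        match[j, AA_INDEX[c]] = 1.0
    transitions = np.tile([1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0], (L, 1))
    profile = ProfileHMM("F", match, np.full(20, 0.05), transitions,
                         np.full(20, 0.05))
    score, s, e = viterbi_score(profile, consensus)
    assert score == pytest.approx(L * math.log2(20))
    assert (s, e) == (0, 3)


def test_flanking_residues_do_not_change_score(tiny_seeds):
    seeds, _, consensus = tiny_seeds
    name = next(iter(seeds))
    p = build_profile(seeds[name])
    core = consensus[name]
    s0, a0, b0 = viterbi_score(p, core)
    rng = np.random.default_rng(0)
    flank = "".join(rng.choice(list(AMINO_ACIDS), size=10))
    s1, a1, b1 = viterbi_score(p, flank + core + flank)
    assert s1 == pytest.approx(s0, abs=1e-6)
    assert (b1 - a1) == (b0 - a0)


def test_empty_protein_rejected(tiny_seeds):
    seeds, _, _ = tiny_seeds
    p = build_profile(next(iter(seeds.values())))
    with pytest.raises(ValueError):
        viterbi_score(p, "")


# ------------------------------------------------------------- calibration

def test_evalue_monotone_and_closed_form(tiny_seeds):
    seeds, _, _ = tiny_seeds
    p = build_profile(next(iter(seeds.values())))
    mu, lam = calibrate_evalue(p, n_random=150, mean_len=60, rng_seed=11)
    assert lam > 0
    # E at the location parameter with N=1 is exactly 1
    assert evalue(p, mu, 1) == pytest.approx(1.0)
    scores = np.linspace(mu - 5, mu + 20, 30)
    es = [evalue(p, s, 100) for s in scores]
    assert all(a >= b for a, b in zip(es, es[1:]))
    assert all(0 <= e <= 100 for e in es)


def test_calibration_deterministic(tiny_seeds):
    seeds, _, _ = tiny_seeds
    p1 = build_profile(next(iter(seeds.values())))
    p2 = build_profile(next(iter(seeds.values())))
    assert calibrate_evalue(p1, rng_seed=3) == calibrate_evalue(p2, rng_seed=3)


def test_calibration_self_consistency(tiny_seeds):
    """P(random score > s*) for the Gumbel's 1% point is ~1% empirically."""
    seeds, _, _ = tiny_seeds
    p = build_profile(next(iter(seeds.values())))
    mu, lam = calibrate_evalue(p, n_random=300, mean_len=60, rng_seed=11)
    s_star = mu + math.log(100.0) / lam   # per-sequence tail prob 0.01
    rng = np.random.default_rng(12)
    n, hits = 500, 0
    for _ in range(n):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=60, p=p.background))
        s, _, _ = viterbi_score(p, seq)
        if s > s_star:
            hits += 1
    # binomial 95% band around p=0.01 at n=500, widened for Gumbel
    # approximation error of the method-of-moments fit
    assert 0 <= hits / n <= 0.035


def test_degenerate_variance_is_error():
    # a flat single-state profile scores every protein identically
    match = np.full((1, 20), 0.05)
    transitions = np.array([[1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0]])
    p = ProfileHMM("F", match, np.full(20, 0.05), transitions,
                   np.full(20, 0.05))
    with pytest.raises(ValueError, match="degenerate"):
        calibrate_evalue(p, n_random=100, mean_len=20, rng_seed=0)


def test_uncalibrated_profile_cannot_scan(tiny_seeds):
    seeds, _, _ = tiny_seeds
    p = build_profile(next(iter(seeds.values())))
    cand = ProteinCandidate("x", "ACDEFGHIKLMNPQRSTVWY" * 2, 1, 0, 120)
    with pytest.raises(ValueError, match="not calibrated"):
        scan([cand], [p])


# -------------------------------------------------------------------- scan

def test_scan_empty_input(tiny_seeds):
    seeds, _, _ = tiny_seeds
    p = build_profile(next(iter(seeds.values())))
    calibrate_evalue(p, rng_seed=1)
    assert scan([], [p]) == []


def test_scan_finds_planted_families(planted_corpus):
    truth = planted_corpus.truth.by_id()
    profiles = []
    for k, name in enumerate(sorted(planted_corpus.seeds)):
        p = build_profile(planted_corpus.seeds[name])
        calibrate_evalue(p, rng_seed=100 + k)
        profiles.append(p)
    cands = []
    expected = {}
    for rec in planted_corpus.est_records:
        row = truth[rec.id]
        if row.true_family and row.is_duplicate_of is None:
            cands.append(best_protein(rec, 30))
            expected[rec.id] = row.true_family
    hits = scan(cands, profiles, e_max=0.01)
    by_protein = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    for pid, fam in expected.items():
        assert pid in by_protein, f"planted TF {pid} not detected"
        top = min(by_protein[pid], key=lambda h: h.e_value)
        assert top.family == fam


def test_scan_background_false_positive_rate(tiny_seeds):
    seeds, _, _ = tiny_seeds
    profiles = []
    for k, name in enumerate(sorted(seeds)):
        p = build_profile(seeds[name])
        calibrate_evalue(p, rng_seed=50 + k)
        profiles.append(p)
    rng = np.random.default_rng(23)
    cands = [
        ProteinCandidate(
            f"bg{i}",
            "".join(rng.choice(list(AMINO_ACIDS), size=80)),
            1, 0, 240,
        )
        for i in range(100)
    ]
    hits = scan(cands, profiles, e_max=0.01)
    # expectation is ~1 chance hit per profile at E<0.01 with N=100;
    # allow generous stochastic headroom without tolerating breakage
    per_family = {}
    for h in hits:
        per_family[h.family] = per_family.get(h.family, 0) + 1
    assert all(v <= 8 for v in per_family.values())


def test_hit_ordering_and_validation(tiny_seeds):
    seeds, _, consensus = tiny_seeds
    profiles = []
    for k, name in enumerate(sorted(seeds)):
        p = build_profile(seeds[name])
        calibrate_evalue(p, rng_seed=60 + k)
        profiles.append(p)
    cands = [
        ProteinCandidate("z", consensus[sorted(seeds)[0]], 1, 0, 60),
        ProteinCandidate("a", consensus[sorted(seeds)[1]], 1, 0, 60),
    ]
    hits = scan(cands, profiles)
    assert [h.protein_id for h in hits] == sorted(h.protein_id for h in hits)
    with pytest.raises(ValueError):
        DomainHit("p", "F", 10.0, -0.1, 0, 5)
    with pytest.raises(ValueError):
        DomainHit("p", "F", 10.0, 0.001, 5, 5)


# -------------------------------------------- independent HMMER cross-check

def test_planted_families_agree_with_hmmer(planted_corpus):
    """HMMER (via pyhmmer), built from the same seed alignments, assigns the
    same family to every planted TF protein as our scanner."""
    pyhmmer = pytest.importorskip("pyhmmer")

    abc = pyhmmer.easel.Alphabet.amino()
    bg = pyhmmer.plan7.Background(abc)
    builder = pyhmmer.plan7.Builder(abc)
    hmms = []
    for name, seed in sorted(planted_corpus.seeds.items()):
        msa = pyhmmer.easel.TextMSA(
            name=name.encode(),
            sequences=[
                pyhmmer.easel.TextSequence(name=f"{name}_{i}".encode(),
                                           sequence=row)
                for i, row in enumerate(seed.rows)
            ],
        )
        hmm, _, _ = builder.build_msa(msa.digitize(abc), bg)
        hmms.append(hmm)

    truth = planted_corpus.truth.by_id()
    seqs = []
    expected = {}
    for rec in planted_corpus.est_records:
        row = truth[rec.id]
        if row.true_family and row.is_duplicate_of is None:
            cand = best_protein(rec, 30)
            seqs.append(
                pyhmmer.easel.TextSequence(
                    name=rec.id.encode(), sequence=cand.protein
                ).digitize(abc)
            )
            expected[rec.id] = row.true_family
    block = pyhmmer.easel.DigitalSequenceBlock(abc, seqs)

    def _name(x):
        return x.decode() if isinstance(x, bytes) else x

    best = {}
    for hmm in hmms:
        pipeline = pyhmmer.plan7.Pipeline(abc, background=bg)
        for hit in pipeline.search_hmm(hmm, block):
            pid = _name(hit.name)
            if pid not in best or hit.score > best[pid][1]:
                best[pid] = (_name(hmm.name), hit.score)
    for pid, fam in expected.items():
        assert pid in best, f"HMMER found no hit for {pid}"
        assert best[pid][0] == fam
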