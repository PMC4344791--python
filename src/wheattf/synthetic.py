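"""Synthetic EST corpora with planted ground truth.

The generator emulates the real inputs of the pipeline end to end: per-
family seed alignments over conserved protein cores, family rules
(required/forbidden domains), EST transcripts carrying a back-translated
(possibly mutated) copy of a family domain inside random UTR context,
near-identical duplicates that redundancy clustering will remove,
libraries spanning every stage/tissue category, and two planted
validation scenarios:

* ``blast_update`` — a near-identical, longer subject EST from a different
  library category; the matched-sequence criteria make it flip a planted
  specific TF to unspecific.
* ``filtered_recovery`` — a duplicate from a different category that only
  survives in the clustering's filtered-out set; its category must be
  recovered onto the representative.

Every emitted EST has exactly one row in the truth table, which encodes
the *final* (post-update, post-recovery) presence vectors, so an end-to-end
pipeline run can be compared against it bit for bit.

Design notes: transcripts are built as frame +1 codon streams (random
non-stop UTR codons around the domain), so the planted ORF is the longest
stop-free stretch by construction; back-translation uses one fixed codon
per amino acid so family recovery does not depend on codon-usage
randomness; nucleotide-level mutations are resampled if they would create
an in-frame stop, keeping planted ORFs intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import (
    STAGE_ORDER,
    TISSUE_ORDER,
    ESTRecord,
    LibraryAnnotation,
    StageCategory,
    TissueCategory,
)
from .families import FamilyRule
from .hmm import AMINO_ACIDS, SeedAlignment

# one fixed codon per amino acid (a common-codon table); keeps
# back-translation deterministic and unambiguous
BACK_TRANSLATION = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}
_STOPS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic corpus."""

    n_families: int = 3
    seed_sequences_per_family: int = 30
    n_tf_transcripts: int = 30
    n_background: int = 20
    duplicate_rate: float = 0.2
    duplicate_identity: float = 0.97
    n_libraries_per_category: int = 1
    planted_specific_fraction: float = 0.8
    mutation_rate_domain: float = 0.03
    rng_seed: int = 0
    n_blast_update: int = 1
    n_filtered_recovery: int = 1
    core_length: int = 50          # amino acids per family domain
    utr_codons_min: int = 10
    utr_codons_max: int = 20

    def __post_init__(self) -> None:
        for name in ("n_families", "seed_sequences_per_family",
                     "n_tf_transcripts", "n_background",
                     "n_libraries_per_category", "n_blast_update",
                     "n_filtered_recovery"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("duplicate_rate", "planted_specific_fraction",
                     "mutation_rate_domain"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.95 <= self.duplicate_identity <= 1.0):
            raise ValueError("duplicate_identity must be in [0.95, 1.0]")


@dataclass(frozen=True)
class TruthRow:
    est_id: str
    true_family: str | None
    true_stage_presence: tuple[int, ...]   # final, post-update/recovery
    true_tissue_presence: tuple[int, ...]
    is_duplicate_of: str | None
    planted_scenario: str                  # plain | blast_update | filtered_recovery
    planted_peptide: str | None


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)

    def by_id(self) -> dict[str, TruthRow]:
        return {r.est_id: r for r in self.rows}

    def to_tsv(self) -> str:
        lines = [
            "est_id\ttrue_family\tstage_presence\ttissue_presence\t"
            "is_duplicate_of\tplanted_scenario\tplanted_peptide"
        ]
        for r in self.rows:
            lines.append(
                "\t".join(
                    [
                        r.est_id,
                        r.true_family or ".",
                        "".join(map(str, r.true_stage_presence)),
                        "".join(map(str, r.true_tissue_presence)),
                        r.is_duplicate_of or ".",
                        r.planted_scenario,
                        r.planted_peptide or ".",
                    ]
                )
            )
        return "\n".join(lines) + "\n"


@dataclass
class SyntheticCorpus:
    """Everything a pipeline run needs, plus the planted truth."""

    est_records: list[ESTRecord]
    library_annotations: list[LibraryAnnotation]
    seeds: dict[str, SeedAlignment]
    rules: list[FamilyRule]
    truth: TruthTable
    subject_records: list[ESTRecord]   # validation subjects (not corpus ESTs)


# ---------------------------------------------------------------- families

def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _peptide_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / min(len(a), len(b))


def _make_family_cores(rng: np.random.Generator, cfg: SyntheticConfig) -> list[str]:
    """Family consensus cores with pairwise identity <= 0.40."""
    cores: list[str] = []
    attempts = 0
    while len(cores) < cfg.n_families:
        cand = _random_peptide(rng, cfg.core_length)
        if all(_peptide_identity(cand, c) <= 0.40 for c in cores):
            cores.append(cand)
        attempts += 1
        if attempts > 200 * cfg.n_families:
            raise ValueError(
                "cannot generate enough mutually divergent family cores "
                f"at core length {cfg.core_length}"
            )
    return cores


def generate_family_seeds(
    config: SyntheticConfig,
) -> tuple[dict[str, SeedAlignment], list[FamilyRule], dict[str, str]]:
    """Per-family seed alignments, rules, and consensus core peptides.

    Each alignment has >= 60% fully conserved columns (70% of core columns
    are frozen), two low-occupancy insert columns to exercise gap handling,
    and a rule requiring that family's domain while forbidding all others.
    Deterministic for a fixed config.
    """
    if config.n_families < 1:
        raise ValueError("n_families must be >= 1")
    if config.seed_sequences_per_family < 2:
        raise ValueError("seed_sequences_per_family must be >= 2")
    rng = np.random.default_rng(config.rng_seed)
    cores = _make_family_cores(rng, config)

    seeds: dict[str, SeedAlignment] = {}
    names = [f"FAM{i + 1:02d}" for i in range(config.n_families)]
    for name, core in zip(names, cores):
        L = len(core)
        n_var = int(0.30 * L)
        var_cols = set(rng.choice(L, size=n_var, replace=False).tolist())
        rows = []
        for _ in range(config.seed_sequences_per_family):
            chars = list(core)
            for col in var_cols:
                chars[col] = str(rng.choice(list(AMINO_ACIDS)))
            rows.append("".join(chars))
        # two insert columns (majority-gap) at fixed interior offsets
        ins_at = (L // 3, 2 * L // 3)
        aug = []
        for k, row in enumerate(rows):
            chars = list(row)
            for off, pos in enumerate(sorted(ins_at, reverse=True)):
                occupant = k == (off % len(rows))  # one row per insert column
                chars.insert(pos, str(rng.choice(list(AMINO_ACIDS)))
                             if occupant else "-")
            aug.append("".join(chars))
        seeds[name] = SeedAlignment(name, tuple(aug))

    rules = [
        FamilyRule.make(name, [[name]], [o for o in names if o != name])
        for name in names
    ]
    consensus = dict(zip(names, cores))
    return seeds, rules, consensus


# --------------------------------------------------------------- libraries

_INFORMATIVE_STAGES = STAGE_ORDER[:6]
_INFORMATIVE_TISSUES = TISSUE_ORDER[:6]

# raw labels that the corpus keyword tables recognise
_STAGE_LABEL = {
    StageCategory.DORMANT_SEED: "dormant seed",
    StageCategory.GERMINATING_SEED: "germinating seed",
    StageCategory.SEEDLING: "Seedling",
    StageCategory.VEGETATIVE: "vegetative",
    StageCategory.REPRODUCTIVE: "Reproductive",
    StageCategory.RIPENING: "ripening",
}
_TISSUE_LABEL = {
    TissueCategory.CROWN: "crown",
    TissueCategory.FLOWER: "inflorescence",
    TissueCategory.LEAF: "leaf",
    TissueCategory.ROOT: "root",
    TissueCategory.SEED: "seed",
    TissueCategory.STEM: "stem",
}


def _make_libraries(cfg: SyntheticConfig) -> tuple[
    list[LibraryAnnotation],
    dict[tuple[StageCategory, TissueCategory], str],
    dict[str, tuple[StageCategory, TissueCategory]],
    str,
]:
    """A stage x tissue grid of informative libraries plus one catch-all."""
    annotations: list[LibraryAnnotation] = []
    grid: dict[tuple[StageCategory, TissueCategory], str] = {}
    libmap: dict[str, tuple[StageCategory, TissueCategory]] = {}
    for s in _INFORMATIVE_STAGES:
        for t in _INFORMATIVE_TISSUES:
            for k in range(cfg.n_libraries_per_category):
                lib_id = f"LIB_{s.value}_{t.value}_{k}"
                annotations.append(
                    LibraryAnnotation(lib_id, _STAGE_LABEL[s], _TISSUE_LABEL[t])
                )
                libmap[lib_id] = (s, t)
                if k == 0:
                    grid[(s, t)] = lib_id
    catchall = "LIB_CATCHALL"
    annotations.append(LibraryAnnotation(catchall, "mixed", "cell culture"))
    libmap[catchall] = (StageCategory.UNCLEAR, TissueCategory.OTHER)
    return annotations, grid, libmap, catchall


# -------------------------------------------------------------- sequences

def back_translate(peptide: str) -> str:
    return "".join(BACK_TRANSLATION[a] for a in peptide)


def _mutate_peptide(rng: np.random.Generator, peptide: str, rate: float) -> str:
    chars = list(peptide)
    for i in range(len(chars)):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != chars[i]]
            chars[i] = str(rng.choice(choices))
    return "".join(chars)


def _random_utr(rng: np.random.Generator, cfg: SyntheticConfig) -> str:
    n = int(rng.integers(cfg.utr_codons_min, cfg.utr_codons_max + 1))
    return "".join(rng.choice(_NON_STOP_CODONS, size=n))


def _mutate_nt(
    rng: np.random.Generator,
    seq: str,
    n_mut: int,
    protected: set[int],
) -> str:
    """Substitute n_mut positions, avoiding ``protected`` indices and never
    creating an in-frame (+1) stop codon."""
    chars = list(seq)
    allowed = [i for i in range(len(chars)) if i not in protected]
    if n_mut > len(allowed):
        raise ValueError("not enough mutable positions")
    positions = rng.choice(len(allowed), size=n_mut, replace=False)
    for p in positions:
        i = allowed[int(p)]
        codon_start = (i // 3) * 3
        for base in rng.permutation([b for b in "ACGT" if b != chars[i]]):
            old = chars[i]
            chars[i] = str(base)
            codon = "".join(chars[codon_start : codon_start + 3])
            if len(codon) < 3 or codon not in _STOPS:
                break
            chars[i] = old
    return "".join(chars)


# ------------------------------------------------------------------ corpus

def generate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate a full synthetic corpus with planted truth.

    Raises on contradictory configs (e.g. planted specific TFs requested
    with no informative libraries, or more scenario TFs than specific TFs).
    """
    rng = np.random.default_rng(config.rng_seed)
    seeds, rules, consensus = generate_family_seeds(config)
    names = list(seeds)

    annotations, grid, libmap, catchall_lib = _make_libraries(config)
    if config.n_libraries_per_category == 0 and (
        config.planted_specific_fraction > 0 and config.n_tf_transcripts > 0
    ):
        raise ValueError(
            "planted_specific_fraction > 0 requires informative libraries"
        )

    n_specific = round(config.planted_specific_fraction * config.n_tf_transcripts)
    n_scenarios = config.n_blast_update + config.n_filtered_recovery
    if config.n_tf_transcripts > 0 and n_scenarios > n_specific:
        raise ValueError(
            f"{n_scenarios} scenario TFs requested but only "
            f"{n_specific} planted specific TFs"
        )

    est_records: list[ESTRecord] = []
    subject_records: list[ESTRecord] = []
    truth_rows: list[TruthRow] = []
    # (src_id, seq, lib, scenario, dom_start, dom_end)
    dup_jobs: list[tuple[str, str, str, str, int, int]] = []

    def bits(stage_set, tissue_set):
        sb = tuple(1 if s in stage_set else 0 for s in STAGE_ORDER)
        tb = tuple(1 if t in tissue_set else 0 for t in TISSUE_ORDER)
        return sb, tb

    # scenario picks: first specific transcripts get the scenarios
    blast_idx = set(range(config.n_blast_update))
    recov_idx = set(
        range(config.n_blast_update, config.n_blast_update + config.n_filtered_recovery)
    )

    serial = 0
    for t_idx in range(config.n_tf_transcripts):
        serial += 1
        est_id = f"EST{serial:05d}"
        fam = names[t_idx % len(names)]
        peptide = _mutate_peptide(rng, consensus[fam], config.mutation_rate_domain)
        utr5, utr3 = _random_utr(rng, config), _random_utr(rng, config)
        seq = utr5 + back_translate(peptide) + utr3
        dom_start, dom_end = len(utr5), len(utr5) + 3 * len(peptide)

        is_specific = t_idx < n_specific
        if is_specific:
            s = _INFORMATIVE_STAGES[t_idx % 6]
            t = _INFORMATIVE_TISSUES[(t_idx // 6) % 6]
            lib = grid[(s, t)]
            stage_set, tissue_set = {s}, {t}
        else:
            lib = catchall_lib
            stage_set = {StageCategory.UNCLEAR}
            tissue_set = {TissueCategory.OTHER}
        scenario = "plain"

        if t_idx in blast_idx:
            scenario = "blast_update"
            s2 = _INFORMATIVE_STAGES[(t_idx + 1) % 6]
            t2 = _INFORMATIVE_TISSUES[((t_idx // 6) + 1) % 6]
            sub_lib = grid[(s2, t2)]
            protected = set(range(10)) | set(range(len(seq) - 10, len(seq)))
            protected |= set(range(dom_start, dom_start + 9))
            protected |= set(range(dom_end - 9, dom_end))
            n_mut = max(1, int(0.01 * len(seq)))
            sub_seq = _mutate_nt(rng, seq, n_mut, protected)
            sub_seq += "".join(rng.choice(_NON_STOP_CODONS, size=7))  # longer
            subject_records.append(
                ESTRecord(f"SUBJ{serial:05d}", sub_seq, sub_lib)
            )
            stage_set = stage_set | {s2}
            tissue_set = tissue_set | {t2}
        elif t_idx in recov_idx:
            scenario = "filtered_recovery"
            s2 = _INFORMATIVE_STAGES[(t_idx + 2) % 6]
            t2 = _INFORMATIVE_TISSUES[((t_idx // 6) + 2) % 6]
            dup_lib = grid[(s2, t2)]
            dup_jobs.append(
                (est_id, seq, dup_lib, "filtered_recovery", dom_start, dom_end)
            )
            stage_set = stage_set | {s2}
            tissue_set = tissue_set | {t2}
        elif rng.random() < config.duplicate_rate:
            dup_jobs.append((est_id, seq, lib, "plain", dom_start, dom_end))

        sb, tb = bits(stage_set, tissue_set)
        est_records.append(ESTRecord(est_id, seq, lib))
        truth_rows.append(
            TruthRow(est_id, fam, sb, tb, None, scenario, peptide)
        )

    # duplicates (after all sources, so input order keeps sources first)
    for src_id, seq, lib, scenario, dom_start, dom_end in dup_jobs:
        serial += 1
        dup_id = f"EST{serial:05d}"
        src_row = next(r for r in truth_rows if r.est_id == src_id)
        n_mut = int(round((1.0 - config.duplicate_identity) * len(seq)))
        protected = set(range(5)) | set(range(len(seq) - 5, len(seq)))
        protected |= set(range(dom_start, dom_start + 9))
        protected |= set(range(dom_end - 9, dom_end))
        dup_seq = _mutate_nt(rng, seq, n_mut, protected) if n_mut else seq
        est_records.append(ESTRecord(dup_id, dup_seq, lib))
        s, t = libmap[lib]
        sb, tb = bits({s}, {t})
        truth_rows.append(
            TruthRow(dup_id, src_row.true_family, sb, tb, src_id, scenario,
                     src_row.planted_peptide)
        )

    # background: i.i.d. uniform nucleotides, no ORF control
    all_libs = [a.library_id for a in annotations]
    for _ in range(config.n_background):
        serial += 1
        est_id = f"EST{serial:05d}"
        length = int(rng.integers(150, 401))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        lib = all_libs[int(rng.integers(len(all_libs)))]
        s, t = libmap[lib]
        sb, tb = bits({s}, {t})
        est_records.append(ESTRecord(est_id, seq, lib))
        truth_rows.append(TruthRow(est_id, None, sb, tb, None, "plain", None))

    return SyntheticCorpus(
        est_records=est_records,
        library_annotations=annotations,
        seeds=seeds,
        rules=rules,
        truth=TruthTable(truth_rows),
        subject_records=subject_records,
    )
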