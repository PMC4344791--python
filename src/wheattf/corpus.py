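"""EST corpus input/output and library-category mapping.

An EST corpus is a nucleotide FASTA file plus a library-annotation table
(TSV: ``library_id  stage_label  tissue_label``).  Each library carries the
free-text developmental-stage and tissue labels of its source cDNA library;
these are normalised onto seven stage categories (dormant seed, germinating
seed, seedling, vegetative, reproductive, ripening, unclear) and seven
tissue categories (crown, flower, leaf, root, seed, stem, other).  The
"unclear"/"other" slot is the catch-all for mixed, unclassified or
unrecognised labels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_NT = frozenset("ACGTN")


class StageCategory(enum.Enum):
    """The seven developmental-stage categories; ``UNCLEAR`` is the catch-all."""

    DORMANT_SEED = "dormant_seed"
    GERMINATING_SEED = "germinating_seed"
    SEEDLING = "seedling"
    VEGETATIVE = "vegetative"
    REPRODUCTIVE = "reproductive"
    RIPENING = "ripening"
    UNCLEAR = "unclear"


class TissueCategory(enum.Enum):
    """The seven tissue categories; ``OTHER`` is the catch-all."""

    CROWN = "crown"
    FLOWER = "flower"
    LEAF = "leaf"
    ROOT = "root"
    SEED = "seed"
    STEM = "stem"
    OTHER = "other"


#: Presence-vector column order for stages (catch-all last).
STAGE_ORDER = (
    StageCategory.DORMANT_SEED,
    StageCategory.GERMINATING_SEED,
    StageCategory.REPRODUCTIVE,
    StageCategory.RIPENING,
    StageCategory.SEEDLING,
    StageCategory.VEGETATIVE,
    StageCategory.UNCLEAR,
)

#: Presence-vector column order for tissues (catch-all last).
TISSUE_ORDER = (
    TissueCategory.CROWN,
    TissueCategory.FLOWER,
    TissueCategory.LEAF,
    TissueCategory.ROOT,
    TissueCategory.SEED,
    TissueCategory.STEM,
    TissueCategory.OTHER,
)


@dataclass(frozen=True)
class ESTRecord:
    """One nucleotide EST/TC sequence tied to its source library."""

    id: str
    sequence: str
    library_id: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("EST id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"EST {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - VALID_NT
        if bad:
            raise ValueError(
                f"EST {self.id!r}: invalid nucleotide characters {sorted(bad)!r}; "
                "allowed alphabet is A, C, G, T, N"
            )


@dataclass(frozen=True)
class LibraryAnnotation:
    """Raw stage/tissue labels of one cDNA library (labels may be empty)."""

    library_id: str
    raw_stage_label: str
    raw_tissue_label: str


# Default keyword tables.  Matching is exact after case-folding and
# whitespace-stripping; anything unrecognised falls into the catch-all.
DEFAULT_STAGE_KEYWORDS: dict[str, StageCategory] = {
    "dormant seed": StageCategory.DORMANT_SEED,
    "germinating seed": StageCategory.GERMINATING_SEED,
    "seedling": StageCategory.SEEDLING,
    "vegetative": StageCategory.VEGETATIVE,
    "reproductive": StageCategory.REPRODUCTIVE,
    "ripening": StageCategory.RIPENING,
    # explicit catch-all spellings
    "unknown developmental stage": StageCategory.UNCLEAR,
    "mixed": StageCategory.UNCLEAR,
    "not yet classified": StageCategory.UNCLEAR,
}

DEFAULT_TISSUE_KEYWORDS: dict[str, TissueCategory] = {
    "crown": TissueCategory.CROWN,
    "flower": TissueCategory.FLOWER,
    "inflorescence": TissueCategory.FLOWER,
    "leaf": TissueCategory.LEAF,
    "sheath": TissueCategory.LEAF,
    "root": TissueCategory.ROOT,
    "seed": TissueCategory.SEED,
    "stem": TissueCategory.STEM,
    # explicit catch-all spellings
    "callus": TissueCategory.OTHER,
    "cell culture": TissueCategory.OTHER,
    "whole plant": TissueCategory.OTHER,
    "mixed tissue": TissueCategory.OTHER,
    "not yet classified": TissueCategory.OTHER,
    "unspecified": TissueCategory.OTHER,
}


def _normalize(label: str) -> str:
    return label.strip().lower()


def map_stage(
    raw_stage_label: str,
    overrides: Mapping[str, StageCategory] | None = None,
) -> StageCategory:
    """Map a raw library stage label onto one of the seven stage categories.

    Total function: unrecognised, empty, mixed or unclassified labels map to
    ``UNCLEAR``.  ``overrides`` extends/replaces entries of the default
    keyword table (keys are normalised the same way as labels).
    """
    table = dict(DEFAULT_STAGE_KEYWORDS)
    if overrides:
        table.update({_normalize(k): v for k, v in overrides.items()})
    return table.get(_normalize(raw_stage_label), StageCategory.UNCLEAR)


def map_tissue(
    raw_tissue_label: str,
    overrides: Mapping[str, TissueCategory] | None = None,
) -> TissueCategory:
    """Map a raw library tissue label onto one of the seven tissue categories.

    Total function: unrecognised labels (callus, cell culture, whole plant,
    mixed tissue, empty, ...) map to ``OTHER``.
    """
    table = dict(DEFAULT_TISSUE_KEYWORDS)
    if overrides:
        table.update({_normalize(k): v for k, v in overrides.items()})
    return table.get(_normalize(raw_tissue_label), TissueCategory.OTHER)


def load_corpus(
    fasta_path: str | Path,
    library_table_path: str | Path,
) -> tuple[list[ESTRecord], list[LibraryAnnotation]]:
    """Read an EST FASTA plus its library-annotation TSV.

    Every EST's library id (taken from the FASTA description field
    ``lib=<id>``, or the second whitespace token of the header) must appear
    in the table.  Duplicate sequence ids and unknown libraries are errors.
    """
    fasta_path = Path(fasta_path)
    library_table_path = Path(library_table_path)
    if not fasta_path.exists():
        raise FileNotFoundError(str(fasta_path))
    if not library_table_path.exists():
        raise FileNotFoundError(str(library_table_path))

    annotations = read_library_table(library_table_path)
    known = {a.library_id for a in annotations}

    records: list[ESTRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        lib = _library_of(rec)
        if lib is None:
            raise ValueError(f"EST {rec.id!r} has no lib=<library_id> annotation")
        if lib not in known:
            raise ValueError(f"EST {rec.id!r} references unknown library {lib!r}")
        records.append(ESTRecord(rec.id, str(rec.seq).upper(), lib))
    return records, annotations


def _library_of(rec: SeqRecord) -> str | None:
    for token in rec.description.split()[1:]:
        if token.startswith("lib="):
            return token[4:]
    return None


def read_library_table(path: str | Path) -> list[LibraryAnnotation]:
    """Parse the 3-column TSV ``library_id  stage_label  tissue_label``."""
    annotations: list[LibraryAnnotation] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header and not header.startswith("library_id"):
            raise ValueError(
                "library table must start with header "
                "'library_id\\tstage_label\\ttissue_label'"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed library table row: {line!r}")
            lib, stage, tissue = parts
            if lib in seen:
                raise ValueError(f"duplicate library_id {lib!r}")
            seen.add(lib)
            annotations.append(LibraryAnnotation(lib, stage, tissue))
    return annotations


def write_corpus(
    records: Iterable[ESTRecord],
    annotations: Iterable[LibraryAnnotation],
    fasta_path: str | Path,
    library_table_path: str | Path,
) -> None:
    """Write a corpus back to FASTA + TSV (inverse of :func:`load_corpus`)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=f"lib={r.library_id}")
        for r in records
    ]
    with open(fasta_path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(seq_records, fh, "fasta")
    with open(library_table_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("library_id\tstage_label\ttissue_label\n")
        for a in annotations:
            fh.write(f"{a.library_id}\t{a.raw_stage_label}\t{a.raw_tissue_label}\n")


def library_category_maps(
    annotations: Iterable[LibraryAnnotation],
    stage_overrides: Mapping[str, StageCategory] | None = None,
    tissue_overrides: Mapping[str, TissueCategory] | None = None,
) -> tuple[dict[str, StageCategory], dict[str, TissueCategory]]:
    """Resolve every library to exactly one stage and one tissue category."""
    stages: dict[str, StageCategory] = {}
    tissues: dict[str, TissueCategory] = {}
    for a in annotations:
        stages[a.library_id] = map_stage(a.raw_stage_label, stage_overrides)
        tissues[a.library_id] = map_tissue(a.raw_tissue_label, tissue_overrides)
    return stages, tissues
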