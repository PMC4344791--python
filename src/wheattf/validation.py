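"""Validation of putative specific TFs against an EST hit table, annotation
merging, and recovery of information from clustered-away sequences.

A query TF's original EST is aligned (or looked up in a precomputed
tabular hit file) against a subject EST set.  A *matched* subject must
(i) cover more than 0.95 of the query length, (ii) align at identity of at
least 0.80, and (iii) be strictly longer than the query.  Matched subjects
from a different library category add that category to the query's
presence row (bits are only ever set, never cleared), after which the
specificity flags are recomputed.

Filtered-out sequences (cluster members removed during redundancy
filtering) are independently translated and domain-scanned; those that are
themselves TFs donate their library categories to their cluster
representative's row the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .corpus import ESTRecord
from .redundancy import smith_waterman
from .specificity import PresenceMatrix


@dataclass(frozen=True)
class AlignmentHit:
    """A query-subject alignment summary (internal aligner or external table)."""

    query_id: str
    subject_id: str
    identity: float          # fraction in [0, 1]
    aln_length: int
    query_length: int
    subject_length: int
    subject_library_id: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0, 1]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.query_length < 1 or self.subject_length < 1:
            raise ValueError("sequence lengths must be >= 1")


def local_align(
    a: ESTRecord | tuple[str, str],
    b: ESTRecord | tuple[str, str],
    subject_library_id: str = "",
) -> AlignmentHit:
    """Best Smith-Waterman local alignment of query a vs subject b.

    Scores: match +1, mismatch -2, gap open 2, gap extend 1 (a gap of
    length g costs 2 + g).  Identity = identical positions / alignment
    columns.
    """
    qid, qseq = (a.id, a.sequence) if isinstance(a, ESTRecord) else a
    sid, sseq = (b.id, b.sequence) if isinstance(b, ESTRecord) else b
    if not qseq or not sseq:
        raise ValueError("sequences must be non-empty")
    res = smith_waterman(qseq, sseq)
    aln_len = max(res.aln_length, 1)
    identity = res.identities / aln_len if res.aln_length else 0.0
    return AlignmentHit(
        query_id=qid,
        subject_id=sid,
        identity=identity,
        aln_length=aln_len,
        query_length=len(qseq),
        subject_length=len(sseq),
        subject_library_id=subject_library_id,
    )


def is_matched(hit: AlignmentHit) -> bool:
    """The three matched-sequence criteria: coverage strictly > 0.95,
    identity >= 0.80, subject strictly longer than query."""
    return (
        hit.aln_length / hit.query_length > 0.95
        and hit.identity >= 0.80
        and hit.subject_length > hit.query_length
    )


@dataclass(frozen=True)
class ChangeLogEntry:
    tf_id: str
    axis: str
    category: str
    source_id: str   # the subject or filtered EST that donated the category
    origin: str      # 'blast_update' | 'filtered_recovery'


def update_from_matches(
    tf_by_query: Mapping[str, str],
    presence: PresenceMatrix,
    hits: Sequence[AlignmentHit],
    library_categories: Mapping[str, object],
    axis: str,
) -> tuple[PresenceMatrix, list[ChangeLogEntry]]:
    """Merge matched subjects' categories into their query TFs' rows.

    ``tf_by_query`` maps query_id (the TF's source EST id or the tf_id
    itself) to tf_id.  Only hits passing :func:`is_matched` contribute; a
    bit already set produces no change and no log entry.  Returns an
    updated copy plus the change log (specificity must be re-classified by
    the caller afterwards).
    """
    updated = presence.copy()
    log: list[ChangeLogEntry] = []
    for hit in hits:
        if not is_matched(hit):
            continue
        tf_id = tf_by_query.get(hit.query_id, hit.query_id)
        if tf_id not in updated.data.index:
            raise KeyError(f"hit references unknown TF {hit.query_id!r}")
        if hit.subject_library_id not in library_categories:
            raise KeyError(
                f"subject library {hit.subject_library_id!r} has no category"
            )
        cat = library_categories[hit.subject_library_id].value
        if updated.data.loc[tf_id, cat] == 0:
            updated.data.loc[tf_id, cat] = 1
            log.append(ChangeLogEntry(tf_id, axis, cat, hit.subject_id,
                                      "blast_update"))
    return updated, log


def recover_filtered(
    filtered_ests: Sequence[ESTRecord],
    cluster_map: Mapping[str, str],
    tf_by_est: Mapping[str, str],
    is_tf: Callable[[ESTRecord], bool],
    matrices: Mapping[str, PresenceMatrix],
    library_categories: Mapping[str, Mapping[str, object]],
) -> tuple[dict[str, PresenceMatrix], list[ChangeLogEntry]]:
    """OR filtered-out TF sequences' categories into their representatives.

    ``cluster_map`` maps each filtered EST id to its cluster representative
    EST id; ``tf_by_est`` maps representative EST ids to tf_ids; ``is_tf``
    translates and domain-scans a filtered EST.  ``matrices`` and
    ``library_categories`` are keyed by axis ('stage'/'tissue').  Only
    filtered ESTs that are themselves TFs *and* whose representative is an
    identified TF contribute.
    """
    updated = {axis: m.copy() for axis, m in matrices.items()}
    log: list[ChangeLogEntry] = []
    for est in filtered_ests:
        if est.id not in cluster_map:
            raise KeyError(f"filtered EST {est.id!r} has no cluster representative")
        rep = cluster_map[est.id]
        tf_id = tf_by_est.get(rep)
        if tf_id is None:
            continue  # representative is not an identified TF
        if not is_tf(est):
            continue
        for axis, matrix in updated.items():
            cats = library_categories[axis]
            if est.library_id not in cats:
                raise KeyError(
                    f"library {est.library_id!r} has no {axis} category"
                )
            cat = cats[est.library_id].value
            if matrix.data.loc[tf_id, cat] == 0:
                matrix.data.loc[tf_id, cat] = 1
                log.append(
                    ChangeLogEntry(tf_id, axis, cat, est.id, "filtered_recovery")
                )
    return updated, log


def replay_change_log(
    presence: PresenceMatrix, log: Iterable[ChangeLogEntry]
) -> PresenceMatrix:
    """Apply a change log to an initial matrix (for audit/round-trip checks)."""
    updated = presence.copy()
    for entry in log:
        if entry.axis != presence.axis:
            continue
        updated.data.loc[entry.tf_id, entry.category] = 1
    return updated


def change_log_to_tsv(log: Sequence[ChangeLogEntry]) -> str:
    lines = ["tf_id\taxis\tcategory\tsource_id\torigin"]
    for e in log:
        lines.append(f"{e.tf_id}\t{e.axis}\t{e.category}\t{e.source_id}\t{e.origin}")
    return "\n".join(lines) + "\n"


def read_tabular_hits(
    path, subject_libraries: Mapping[str, str],
    query_lengths: Mapping[str, int],
    subject_lengths: Mapping[str, int],
) -> list[AlignmentHit]:
    """Read a 12-column tabular alignment hit file (qid, sid, %identity,
    aln_length, mismatches, gapopens, qstart, qend, sstart, send, evalue,
    bitscore) plus a sidecar subject_id -> library_id mapping.

    Percent identities are normalised to fractions on load.
    """
    hits: list[AlignmentHit] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"expected 12 columns, got {len(parts)}: {line!r}")
            qid, sid = parts[0], parts[1]
            identity = float(parts[2])
            if identity > 1.0:  # percentage convention
                identity /= 100.0
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    identity=identity,
                    aln_length=int(parts[3]),
                    query_length=query_lengths[qid],
                    subject_length=subject_lengths[sid],
                    subject_library_id=subject_libraries[sid],
                )
            )
    return hits
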