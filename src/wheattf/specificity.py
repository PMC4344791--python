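"""Stage/tissue presence matrices, specificity classification, family ×
category tables and 7-set Venn region counts.

A presence matrix has one row per TF and seven 0/1 columns: six informative
categories plus the catch-all ("unclear" stage / "other" tissue) last.  A
TF is *specific* when exactly one informative column is set (the catch-all
is ignored for this test), *unclear* when no informative column is set and
the catch-all is, and *unspecific* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import STAGE_ORDER, TISSUE_ORDER
from .families import TFRecord


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def category_names(axis: str) -> list[str]:
    if axis == "stage":
        return [c.value for c in STAGE_ORDER]
    if axis == "tissue":
        return [c.value for c in TISSUE_ORDER]
    raise ValueError(f"axis must be 'stage' or 'tissue', got {axis!r}")


@dataclass
class PresenceMatrix:
    """0/1 presence of each TF in the seven categories of one axis."""

    axis: str
    data: pd.DataFrame  # index tf_id, columns the 7 category names

    def __post_init__(self) -> None:
        cols = category_names(self.axis)
        if list(self.data.columns) != cols:
            raise ValueError(f"columns must be {cols} in order")
        vals = self.data.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValueError("presence cells must be 0/1")
        if (vals.sum(axis=1) == 0).any():
            empty = self.data.index[vals.sum(axis=1) == 0].tolist()
            raise ValueError(f"all-zero presence rows for {empty!r}")

    def copy(self) -> "PresenceMatrix":
        return PresenceMatrix(self.axis, self.data.copy())

    @property
    def informative_columns(self) -> list[str]:
        return list(self.data.columns[:6])

    @property
    def catchall_column(self) -> str:
        return self.data.columns[6]


def build_presence(
    tf_records: Sequence[TFRecord],
    clusters: Mapping[str, Iterable[str]],
    est_to_library: Mapping[str, str],
    library_categories: Mapping[str, object],
    axis: str,
) -> PresenceMatrix:
    """Presence from cluster membership: cell(tf, c) = 1 iff any EST in the
    TF's cluster comes from a library of category c.

    ``clusters`` maps tf_id -> the EST ids of its cluster (representative
    plus members); ``library_categories`` maps library_id -> a
    StageCategory/TissueCategory whose ``.value`` names the column.
    """
    cols = category_names(axis)
    rows = {}
    for tf in tf_records:
        if tf.tf_id not in clusters:
            raise KeyError(f"TF {tf.tf_id!r} has no cluster entry")
        row = dict.fromkeys(cols, 0)
        for est_id in clusters[tf.tf_id]:
            if est_id not in est_to_library:
                raise KeyError(f"EST {est_id!r} has no library")
            lib = est_to_library[est_id]
            if lib not in library_categories:
                raise KeyError(f"library {lib!r} has no {axis} category")
            row[library_categories[lib].value] = 1
        rows[tf.tf_id] = row
    if rows:
        data = pd.DataFrame.from_dict(rows, orient="index").reindex(
            columns=cols
        ).astype(int)
    else:
        data = pd.DataFrame(columns=cols, dtype=int)
    return PresenceMatrix(axis, data)


@dataclass(frozen=True)
class SpecificityFlag:
    kind: str                 # 'specific' | 'unspecific' | 'unclear'
    category: str | None = None  # set only for 'specific'


def classify_specific(matrix: PresenceMatrix) -> dict[str, SpecificityFlag]:
    """Classify every TF row; the catch-all column is ignored for the
    single-category test."""
    flags: dict[str, SpecificityFlag] = {}
    informative = matrix.informative_columns
    catchall = matrix.catchall_column
    for tf_id, row in matrix.data.iterrows():
        n_info = int(row[informative].sum())
        if n_info == 1:
            cat = next(c for c in informative if row[c] == 1)
            flags[tf_id] = SpecificityFlag("specific", cat)
        elif n_info == 0:
            if row[catchall] != 1:
                raise ValueError(f"all-zero presence row for {tf_id!r}")
            flags[tf_id] = SpecificityFlag("unclear")
        else:
            flags[tf_id] = SpecificityFlag("unspecific")
    return flags


def family_category_table(
    tf_records: Sequence[TFRecord],
    flags: Mapping[str, SpecificityFlag],
    families: Sequence[str],
    axis: str,
    total_tf_count: int | None = None,
) -> pd.DataFrame:
    """Per-family counts of category-specific TFs, with footer rows.

    Columns: the six informative categories, ``sum_specific`` (their row
    sum) and the catch-all (count of unclear TFs of the family).  Footer
    rows ``_total`` (column sums) and ``_percent`` (column totals divided by
    the total TF count, x100, rounded half-up to 2 decimals).
    """
    cols = category_names(axis)
    informative, catchall = cols[:6], cols[6]
    fam_of = {tf.tf_id: tf.family for tf in tf_records}
    if total_tf_count is None:
        total_tf_count = len(tf_records)

    table = pd.DataFrame(
        0, index=list(families), columns=[*informative, "sum_specific", catchall]
    )
    for tf_id, flag in flags.items():
        fam = fam_of.get(tf_id)
        if fam is None or fam not in table.index:
            continue
        if flag.kind == "specific":
            table.loc[fam, flag.category] += 1
            table.loc[fam, "sum_specific"] += 1
        elif flag.kind == "unclear":
            table.loc[fam, catchall] += 1

    totals = table.sum(axis=0)
    table.loc["_total"] = totals
    if total_tf_count > 0:
        table.loc["_percent"] = [
            round_half_up(100.0 * t / total_tf_count) for t in totals
        ]
    else:
        table.loc["_percent"] = 0.0
    return table


def venn_region_counts(
    matrix: PresenceMatrix,
) -> tuple[dict[str, int], dict[str, int]]:
    """Counts of the 127 non-empty 7-set membership patterns.

    Returns ``(region_counts, category_totals)`` where region keys are
    7-character bit strings in column order (e.g. ``"1000000"``) covering
    all 127 non-empty patterns (zero where no TF shows the pattern), and
    ``category_totals[c]`` is the number of TFs present in category c.
    """
    cols = list(matrix.data.columns)
    counts = {
        format(p, "07b"): 0 for p in range(1, 2 ** 7)
    }
    for _, row in matrix.data.iterrows():
        pattern = "".join(str(int(row[c])) for c in cols)
        counts[pattern] += 1
    totals = {c: int(matrix.data[c].sum()) for c in cols}
    return counts, totals


def venn_counts_to_tsv(counts: Mapping[str, int]) -> str:
    lines = ["pattern\tcount"]
    for pattern in sorted(counts):
        lines.append(f"{pattern}\t{counts[pattern]}")
    return "\n".join(lines) + "\n"
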