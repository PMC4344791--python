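"""Pipeline orchestration, catalog export and the percentage arithmetic.

The end-to-end flow mirrors the standard EST-to-TF-catalog workflow:
nucleotide redundancy clustering, six-frame translation, protein-level
clustering, profile-HMM domain scanning, family assignment, stage/tissue
presence and specificity classification, matched-alignment validation,
filtered-sequence recovery, and catalog export.  Counts at every stage are
collected into a single JSON-able run report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import families as fam
from . import hmm as hmm_mod
from . import redundancy as red
from . import specificity as spec
from . import validation as val
from .corpus import ESTRecord, LibraryAnnotation, library_category_maps
from .orf import best_protein, ProteinCandidate, protein_fasta_header


@dataclass(frozen=True)
class PipelineConfig:
    cluster_threshold_nt: float = 0.95
    cluster_threshold_aa: float = 0.95
    word_size_nt: int = 8
    word_size_aa: int = 5
    e_max: float = 0.01
    min_orf_aa: int = 30
    genome_gene_count: int = 108569
    calibration_n_random: int = 200
    calibration_mean_len: int = 100
    validate_all_tfs: bool = False   # default: validate putative specific only
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cluster_threshold_nt", "cluster_threshold_aa"):
            if not (0.0 < getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.genome_gene_count < 1:
            raise ValueError("genome_gene_count must be >= 1")
        if self.min_orf_aa < 1:
            raise ValueError("min_orf_aa must be >= 1")


def tf_percentage(n_tfs: int, n_genes: int) -> float:
    """TF share of the genome: 100 * n_tfs / n_genes, half-up to 2 decimals."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_tfs < 0:
        raise ValueError("n_tfs must be >= 0")
    return spec.round_half_up(100.0 * n_tfs / n_genes)


def fraction_report(part: int, whole: int) -> float:
    """100 * part / whole, rounded half-up to 2 decimals."""
    if whole < 1:
        raise ValueError("whole must be >= 1")
    return spec.round_half_up(100.0 * part / whole)


@dataclass
class PipelineResult:
    tf_records: list[fam.TFRecord]
    retained_families: list[str]
    removed_families: list[str]
    matrices: dict[str, spec.PresenceMatrix]
    flags: dict[str, dict[str, spec.SpecificityFlag]]
    change_log: list[val.ChangeLogEntry]
    nt_clusters: list[red.SequenceCluster]
    aa_clusters: list[red.SequenceCluster]
    proteins: dict[str, ProteinCandidate]   # source EST id -> best protein
    run_report: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    est_records: Sequence[ESTRecord],
    library_annotations: Sequence[LibraryAnnotation],
    seeds: Mapping[str, hmm_mod.SeedAlignment],
    rules: Sequence[fam.FamilyRule],
    subject_records: Sequence[ESTRecord] | None = None,
) -> PipelineResult:
    """Run the full identification/classification pipeline in memory."""
    report: dict = {"n_input_ests": len(est_records)}
    stage_cats, tissue_cats = library_category_maps(library_annotations)
    est_by_id = {r.id: r for r in est_records}
    est_to_library = {r.id: r.library_id for r in est_records}
    for r in est_records:
        if r.library_id not in stage_cats:
            raise KeyError(f"EST {r.id!r} references unknown library")

    # 1. nucleotide-level redundancy clustering
    nt_clusters = red.greedy_cluster(
        [(r.id, r.sequence) for r in est_records],
        threshold=config.cluster_threshold_nt,
        word_size=config.word_size_nt,
        alphabet="nucleotide",
    )
    nt_rep_ids = [c.representative_id for c in nt_clusters]
    nt_member_map = {
        mid: c.representative_id for c in nt_clusters for mid in c.member_ids
    }
    report["n_nt_clusters"] = len(nt_clusters)
    report["n_nt_filtered"] = len(nt_member_map)

    # 2. six-frame translation of the non-redundant nucleotides
    proteins: dict[str, ProteinCandidate] = {}
    for rid in nt_rep_ids:
        cand = best_protein(est_by_id[rid], config.min_orf_aa)
        if cand is not None:
            proteins[rid] = cand
    report["n_proteins"] = len(proteins)

    # 3. protein-level redundancy clustering
    aa_clusters = red.greedy_cluster(
        [(rid, c.protein) for rid, c in proteins.items()],
        threshold=config.cluster_threshold_aa,
        word_size=config.word_size_aa,
        alphabet="protein",
    )
    aa_rep_ids = [c.representative_id for c in aa_clusters]
    aa_member_map = {
        mid: c.representative_id for c in aa_clusters for mid in c.member_ids
    }
    report["n_aa_clusters"] = len(aa_clusters)
    report["n_aa_filtered"] = len(aa_member_map)

    # 4. profiles: build + calibrate, deterministically per family
    profiles = []
    for k, name in enumerate(sorted(seeds)):
        p = hmm_mod.build_profile(seeds[name])
        hmm_mod.calibrate_evalue(
            p,
            n_random=config.calibration_n_random,
            mean_len=config.calibration_mean_len,
            rng_seed=(config.rng_seed + 7919 * (k + 1)) % (2**31),
        )
        profiles.append(p)

    # 5. domain scan of the non-redundant proteins
    scanned = [proteins[rid] for rid in aa_rep_ids]
    hits = hmm_mod.scan(scanned, profiles, e_max=config.e_max)
    report["n_scanned_proteins"] = len(scanned)
    report["n_domain_hits"] = len(hits)

    # 6. family assignment
    candidates = fam.assign_families(hits, list(rules))
    resolved = fam.resolve_multi_family(candidates, list(rules))
    declared = sorted(seeds)
    retained, removed = fam.drop_empty_families(resolved, declared)
    tf_records = fam.mint_tf_ids(resolved, {pid: pid for pid in resolved})
    report["n_tfs"] = len(tf_records)
    report["n_families_declared"] = len(declared)
    report["n_families_retained"] = len(retained)
    if declared:
        report["avg_tfs_per_declared_family"] = spec.round_half_up(
            len(tf_records) / len(declared)
        )
    if retained:
        report["avg_tfs_per_retained_family"] = spec.round_half_up(
            len(tf_records) / len(retained)
        )
    report["tf_genome_percentage"] = tf_percentage(
        len(tf_records), config.genome_gene_count
    )

    # 7. presence from each TF's own source record; cluster-mates enter
    # later through the audited filtered-sequence recovery channel
    singleton = {tf.tf_id: [tf.source_est_id] for tf in tf_records}
    cats = {"stage": stage_cats, "tissue": tissue_cats}
    matrices = {
        axis: spec.build_presence(
            tf_records, singleton, est_to_library, cats[axis], axis
        )
        for axis in ("stage", "tissue")
    }
    flags = {a: spec.classify_specific(m) for a, m in matrices.items()}
    for axis in ("stage", "tissue"):
        report[f"n_putative_{axis}_specific"] = sum(
            1 for f in flags[axis].values() if f.kind == "specific"
        )

    change_log: list[val.ChangeLogEntry] = []

    # 8. matched-alignment validation against the subject set
    if subject_records:
        sub_stage, sub_tissue = stage_cats, tissue_cats
        for s in subject_records:
            if s.library_id not in stage_cats:
                raise KeyError(f"subject {s.id!r} references unknown library")
        tf_by_query = {tf.source_est_id: tf.tf_id for tf in tf_records}
        queries = {
            tf.tf_id: tf
            for tf in tf_records
            if config.validate_all_tfs
            or any(flags[a][tf.tf_id].kind == "specific" for a in flags)
        }
        matched_hits: list[val.AlignmentHit] = []
        for tf in queries.values():
            q = est_by_id[tf.source_est_id]
            for s in subject_records:
                hit = val.local_align(q, s, subject_library_id=s.library_id)
                if val.is_matched(hit):
                    matched_hits.append(hit)
        report["n_matched_subjects"] = len(matched_hits)
        for axis, cat_map in (("stage", sub_stage), ("tissue", sub_tissue)):
            axis_hits = [
                h
                for h in matched_hits
                if config.validate_all_tfs
                or flags[axis][tf_by_query[h.query_id]].kind == "specific"
            ]
            matrices[axis], log = val.update_from_matches(
                tf_by_query, matrices[axis], axis_hits, cat_map, axis
            )
            change_log.extend(log)
        flags = {a: spec.classify_specific(m) for a, m in matrices.items()}
    report["n_validation_changes"] = sum(
        1 for e in change_log if e.origin == "blast_update"
    )

    # 9. recovery from filtered-out (clustered-away) sequences
    filtered_est_ids: dict[str, str] = dict(nt_member_map)
    for mid, rep in aa_member_map.items():   # protein-level members, est ids
        filtered_est_ids[mid] = rep
    filtered = [est_by_id[eid] for eid in filtered_est_ids]
    tf_by_est = {tf.source_est_id: tf.tf_id for tf in tf_records}

    if filtered:
        fcands = []
        for est in filtered:
            c = best_protein(est, config.min_orf_aa)
            if c is not None:
                fcands.append(c)
        fhits = hmm_mod.scan(fcands, profiles, e_max=config.e_max)
        fassign = fam.assign_families(fhits, list(rules))
        tf_positive = set(fassign)
        matrices, log = val.recover_filtered(
            filtered,
            filtered_est_ids,
            tf_by_est,
            lambda est: est.id in tf_positive,
            matrices,
            cats,
        )
        change_log.extend(log)
        flags = {a: spec.classify_specific(m) for a, m in matrices.items()}
        report["n_filtered_tfs"] = len(tf_positive)
    else:
        report["n_filtered_tfs"] = 0
    report["n_recovery_changes"] = sum(
        1 for e in change_log if e.origin == "filtered_recovery"
    )

    # 10. final flags onto the records + summary counts
    for tf in tf_records:
        for axis, attr in (("stage", "stage_presence"), ("tissue", "tissue_presence")):
            row = matrices[axis].data.loc[tf.tf_id]
            setattr(tf, attr, [int(v) for v in row.tolist()])
        tf.stage_specific = flags["stage"][tf.tf_id].kind == "specific"
        tf.tissue_specific = flags["tissue"][tf.tf_id].kind == "specific"

    for axis in ("stage", "tissue"):
        n_specific = sum(1 for f in flags[axis].values() if f.kind == "specific")
        n_unclear = sum(1 for f in flags[axis].values() if f.kind == "unclear")
        report[f"n_{axis}_specific"] = n_specific
        report[f"n_{axis}_unclear"] = n_unclear
        if tf_records:
            report[f"{axis}_specific_percentage"] = fraction_report(
                n_specific, len(tf_records)
            )

    return PipelineResult(
        tf_records=tf_records,
        retained_families=retained,
        removed_families=removed,
        matrices=matrices,
        flags=flags,
        change_log=change_log,
        nt_clusters=nt_clusters,
        aa_clusters=aa_clusters,
        proteins=proteins,
        run_report=report,
    )


def export_catalog(
    result: PipelineResult,
    est_records: Sequence[ESTRecord],
    out_dir: str | Path,
) -> dict:
    """Write tf_catalog.tsv, tf_proteins.fasta, tf_nucleotides.fasta and
    summary.json; summary counts are re-derived from the written TSV and
    must agree with the in-memory result."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_cols = spec.category_names("stage")
    tissue_cols = spec.category_names("tissue")
    est_by_id = {r.id: r for r in est_records}

    catalog_path = out_dir / "tf_catalog.tsv"
    with open(catalog_path, "w", encoding="utf-8", newline="\n") as fh:
        header = (
            ["tf_id", "family"]
            + [f"stage_{c}" for c in stage_cols]
            + [f"tissue_{c}" for c in tissue_cols]
            + ["stage_specific", "tissue_specific"]
        )
        fh.write("\t".join(header) + "\n")
        for tf in result.tf_records:
            row = (
                [tf.tf_id, tf.family]
                + [str(v) for v in tf.stage_presence]
                + [str(v) for v in tf.tissue_presence]
                + [str(int(tf.stage_specific)), str(int(tf.tissue_specific))]
            )
            fh.write("\t".join(row) + "\n")

    with open(out_dir / "tf_proteins.fasta", "w", encoding="utf-8",
              newline="\n") as fh:
        for tf in result.tf_records:
            cand = result.proteins[tf.source_est_id]
            fh.write(f">{tf.tf_id} {protein_fasta_header(cand)}\n")
            fh.write(cand.protein + "\n")

    with open(out_dir / "tf_nucleotides.fasta", "w", encoding="utf-8",
              newline="\n") as fh:
        for tf in result.tf_records:
            rec = est_by_id[tf.source_est_id]
            fh.write(f">{tf.tf_id} {rec.id} lib={rec.library_id}\n")
            fh.write(rec.sequence + "\n")

    summary = _summarise(result)
    recount = _recount_from_tsv(catalog_path)
    for key in ("family_counts", "stage_specific_counts",
                "tissue_specific_counts", "n_tfs"):
        if summary[key] != recount[key]:
            raise RuntimeError(
                f"summary/recount mismatch for {key}: "
                f"{summary[key]!r} != {recount[key]!r}"
            )
    with open(out_dir / "summary.json", "w", encoding="utf-8",
              newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _summarise(result: PipelineResult) -> dict:
    n = len(result.tf_records)
    family_counts: dict[str, int] = {}
    for tf in result.tf_records:
        family_counts[tf.family] = family_counts.get(tf.family, 0) + 1
    out = {
        "n_tfs": n,
        "family_counts": dict(sorted(family_counts.items())),
        "run_report": result.run_report,
    }
    for axis in ("stage", "tissue"):
        counts: dict[str, int] = {}
        for f in result.flags[axis].values():
            if f.kind == "specific":
                counts[f.category] = counts.get(f.category, 0) + 1
        out[f"{axis}_specific_counts"] = dict(sorted(counts.items()))
        total = sum(counts.values())
        out[f"n_{axis}_specific"] = total
        if n:
            out[f"{axis}_specific_percentage"] = fraction_report(total, n)
    return out


def _recount_from_tsv(path: Path) -> dict:
    family_counts: dict[str, int] = {}
    stage_counts: dict[str, int] = {}
    tissue_counts: dict[str, int] = {}
    n = 0
    stage_cols = spec.category_names("stage")
    tissue_cols = spec.category_names("tissue")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            parts = dict(zip(header, line.rstrip("\n").split("\t")))
            n += 1
            family_counts[parts["family"]] = family_counts.get(parts["family"], 0) + 1
            if parts["stage_specific"] == "1":
                cat = next(
                    c for c in stage_cols[:6] if parts[f"stage_{c}"] == "1"
                )
                stage_counts[cat] = stage_counts.get(cat, 0) + 1
            if parts["tissue_specific"] == "1":
                cat = next(
                    c for c in tissue_cols[:6] if parts[f"tissue_{c}"] == "1"
                )
                tissue_counts[cat] = tissue_counts.get(cat, 0) + 1
    return {
        "n_tfs": n,
        "family_counts": dict(sorted(family_counts.items())),
        "stage_specific_counts": dict(sorted(stage_counts.items())),
        "tissue_specific_counts": dict(sorted(tissue_counts.items())),
    }
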