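"""Family assignment: required/forbidden-domain rules, multi-family
resolution, empty-family pruning, and TF id minting.

A family rule follows the PlantTFDB-style scheme: ``required`` is a list of
domain-name sets interpreted as AND over the sets with OR within each set,
and ``forbidden`` is a set of domains whose presence vetoes the family.  A
protein whose domain-hit set satisfies more than one family rule is
resolved to a single family by diagnostic bit score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .hmm import DomainHit


@dataclass(frozen=True)
class FamilyRule:
    family: str
    required: tuple[frozenset[str], ...]
    forbidden: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.required:
            raise ValueError(f"rule for {self.family!r}: required must be non-empty")
        all_req = frozenset().union(*self.required)
        if all_req & self.forbidden:
            raise ValueError(
                f"rule for {self.family!r}: required and forbidden overlap"
            )

    @property
    def n_domains(self) -> int:
        """Total domain names mentioned by the rule (rule specificity)."""
        return sum(len(s) for s in self.required) + len(self.forbidden)

    @classmethod
    def make(
        cls,
        family: str,
        required: Sequence[Sequence[str]],
        forbidden: Iterable[str] = (),
    ) -> "FamilyRule":
        return cls(
            family,
            tuple(frozenset(s) for s in required),
            frozenset(forbidden),
        )


def rules_to_json(rules: Sequence[FamilyRule]) -> str:
    return json.dumps(
        [
            {
                "family": r.family,
                "required": [sorted(s) for s in r.required],
                "forbidden": sorted(r.forbidden),
            }
            for r in rules
        ],
        indent=2,
    )


def rules_from_json(text: str) -> list[FamilyRule]:
    return [
        FamilyRule.make(d["family"], d["required"], d.get("forbidden", ()))
        for d in json.loads(text)
    ]


def evaluate_rule(hits_for_protein: set[str], rule: FamilyRule) -> bool:
    """True iff every required set has a present member and nothing forbidden
    is present."""
    if hits_for_protein & rule.forbidden:
        return False
    return all(hits_for_protein & req for req in rule.required)


@dataclass(frozen=True)
class FamilyCandidate:
    family: str
    bit_score: float  # protein's best score among the rule's diagnostic domains


def assign_families(
    hits: Sequence[DomainHit],
    rules: Sequence[FamilyRule],
) -> dict[str, list[FamilyCandidate]]:
    """Per protein, all families whose rule is satisfied by its domain hits.

    Each candidate carries the protein's best bit score over the domains the
    family's rule requires (its diagnostic domains).
    """
    names = [r.family for r in rules]
    if len(set(names)) != len(names):
        raise ValueError("family rules must have unique family names")

    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)

    out: dict[str, list[FamilyCandidate]] = {}
    for pid, phits in by_protein.items():
        present = {h.family for h in phits}
        best_by_domain = {}
        for h in phits:
            if h.family not in best_by_domain or h.bit_score > best_by_domain[h.family]:
                best_by_domain[h.family] = h.bit_score
        cands: list[FamilyCandidate] = []
        for rule in rules:
            if evaluate_rule(present, rule):
                diag = frozenset().union(*rule.required)
                score = max(best_by_domain[d] for d in diag & present)
                cands.append(FamilyCandidate(rule.family, score))
        if cands:
            out[pid] = cands
    return out


def resolve_multi_family(
    candidates: Mapping[str, Sequence[FamilyCandidate]],
    rules: Sequence[FamilyRule],
) -> dict[str, FamilyCandidate]:
    """One family per protein: highest diagnostic bit score wins; ties go to
    the more specific rule (fewer total domains), then the lexicographically
    smallest family name."""
    rule_size = {r.family: r.n_domains for r in rules}
    resolved: dict[str, FamilyCandidate] = {}
    for pid, cands in candidates.items():
        if not cands:
            raise ValueError(f"protein {pid!r} has no candidate family")
        resolved[pid] = min(
            cands,
            key=lambda c: (-c.bit_score, rule_size.get(c.family, 0), c.family),
        )
    return resolved


def drop_empty_families(
    assignments: Mapping[str, FamilyCandidate],
    declared_families: Sequence[str],
) -> tuple[list[str], list[str]]:
    """Split the declared family list into (retained, removed) by whether any
    protein was assigned to the family."""
    populated = {c.family for c in assignments.values()}
    retained = [f for f in declared_families if f in populated]
    removed = [f for f in declared_families if f not in populated]
    return retained, removed


@dataclass
class TFRecord:
    """One identified transcription factor (a catalog row).

    Presence vectors use the canonical category orders of
    :data:`wheattf.corpus.STAGE_ORDER` / :data:`~wheattf.corpus.TISSUE_ORDER`
    (catch-all last).
    """

    tf_id: str
    family: str
    source_est_id: str
    protein_id: str
    bit_score: float
    stage_presence: list[int] = field(default_factory=lambda: [0] * 7)
    tissue_presence: list[int] = field(default_factory=lambda: [0] * 7)
    stage_specific: bool = False
    tissue_specific: bool = False


def mint_tf_ids(
    assignments: Mapping[str, FamilyCandidate],
    protein_sources: Mapping[str, str],
    prefix: str = "TaTF",
) -> list[TFRecord]:
    """Mint zero-padded sequential ids in (family, source id) order.

    ``protein_sources`` maps protein_id -> source EST id.  Deterministic:
    identical input yields identical ids.
    """
    items = sorted(
        assignments.items(),
        key=lambda kv: (kv[1].family, protein_sources.get(kv[0], kv[0]), kv[0]),
    )
    if len(items) > 99999:
        raise ValueError("id space exhausted (> 99999 TFs)")
    records = []
    for k, (pid, cand) in enumerate(items, start=1):
        records.append(
            TFRecord(
                tf_id=f"{prefix}{k:05d}",
                family=cand.family,
                source_est_id=protein_sources.get(pid, pid),
                protein_id=pid,
                bit_score=cand.bit_score,
            )
        )
    return records
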