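"""Six-frame ORF search and translation of EST nucleotide records.

EST reads are single-pass cDNA fragments: they routinely lack the start
codon, so an "ORF" here is any maximal stop-free stretch of codons (no Met
requirement) of at least ``min_aa`` residues, in any of the six reading
frames.  One best protein per record (the longest stretch, deterministic
tie-break) feeds the downstream domain scan.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

from .corpus import ESTRecord

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)

FRAME_ORDER = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Standard genetic code; '*' for stops, 'X' for codons containing N."""
    aa = _CODON_TABLE.get(codon)
    if aa is not None:
        return aa
    if codon in _STOP_CODONS:
        return "*"
    return "X"


@dataclass(frozen=True)
class ProteinCandidate:
    """A stop-free translated stretch of one EST.

    ``nt_start``/``nt_end`` are 0-based half-open coordinates on the forward
    strand covering exactly the translated residues (stop codon excluded);
    ``frame`` is +1/+2/+3 (forward offsets 0/1/2) or -1/-2/-3 (reverse
    complement offsets 0/1/2).
    """

    source_id: str
    protein: str
    frame: int
    nt_start: int
    nt_end: int

    def __post_init__(self) -> None:
        if (self.nt_end - self.nt_start) != 3 * len(self.protein):
            raise ValueError("coordinate span must equal 3 x protein length")


def six_frame_orfs(record: ESTRecord, min_aa: int = 30) -> list[ProteinCandidate]:
    """All maximal stop-free stretches of >= ``min_aa`` residues in 6 frames.

    Candidates are returned in frame order +1, +2, +3, -1, -2, -3, and by
    position within a frame.
    """
    seq = record.sequence
    n = len(seq)
    out: list[ProteinCandidate] = []
    for frame in FRAME_ORDER:
        offset = abs(frame) - 1
        strand_seq = seq if frame > 0 else revcomp(seq)
        n_codons = (n - offset) // 3
        aa = [translate_codon(strand_seq[offset + 3 * i : offset + 3 * i + 3])
              for i in range(n_codons)]
        # split on stops, keep maximal stop-free runs
        start = 0
        for i in range(n_codons + 1):
            if i == n_codons or aa[i] == "*":
                if i - start >= min_aa:
                    prot = "".join(aa[start:i])
                    s_strand = offset + 3 * start  # on the translated strand
                    e_strand = offset + 3 * i
                    if frame > 0:
                        nt_start, nt_end = s_strand, e_strand
                    else:
                        nt_start, nt_end = n - e_strand, n - s_strand
                    out.append(
                        ProteinCandidate(record.id, prot, frame, nt_start, nt_end)
                    )
                start = i + 1
    return out


def best_protein(record: ESTRecord, min_aa: int = 30) -> ProteinCandidate | None:
    """Longest candidate; ties broken by frame order then smaller nt_start.

    Returns ``None`` when no stretch reaches ``min_aa``.
    """
    candidates = six_frame_orfs(record, min_aa)
    if not candidates:
        return None
    frame_rank = {f: i for i, f in enumerate(FRAME_ORDER)}
    return min(
        candidates,
        key=lambda c: (-len(c.protein), frame_rank[c.frame], c.nt_start),
    )


def protein_fasta_header(candidate: ProteinCandidate) -> str:
    """Header convention ``source_id|frame|start-end`` (forward-strand)."""
    return (
        f"{candidate.source_id}|{candidate.frame:+d}|"
        f"{candidate.nt_start}-{candidate.nt_end}"
    )
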