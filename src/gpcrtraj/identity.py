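"""Pairwise sequence identity between receptor orthologs/paralogs.

Global alignment (Needleman–Wunsch via Biopython's ``PairwiseAligner``)
with configurable substitution matrix and affine gap penalties (defaults
BLOSUM62, open 10, extend 0.5).  Identity is reported over aligned columns
that carry a residue in *both* sequences — gap columns are excluded from
numerator and denominator — optionally restricted to a residue interval of
the first sequence (e.g. the helix bundle of a receptor model).  Because
the alignment itself depends on matrix and gap choices, identity figures
from different tools agree only approximately.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["IdentityResult", "sequence_identity"]

_VALID = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class IdentityResult:
    pair_label: str
    aligned_length: int  # aligned columns with residues in both sequences
    identical_positions: int
    percent_identity: float
    region: tuple[int, int] | None = None

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent identity outside [0, 100]")


def sequence_identity(
    seq_a: str,
    seq_b: str,
    region: tuple[int, int] | None = None,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    pair_label: str = "A-B",
) -> IdentityResult:
    """Percent identity from one optimal global alignment.

    ``region`` is an inclusive 1-based residue interval on ``seq_a``; when
    given, only alignment columns whose ``seq_a`` residue index falls in
    the interval contribute.
    """
    seq_a, seq_b = seq_a.strip().upper(), seq_b.strip().upper()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    for label, seq in (("first", seq_a), ("second", seq_b)):
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"invalid characters in {label} sequence: {sorted(bad)}")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    alignment = aligner.align(seq_a, seq_b)[0]

    aligned_cols = 0
    identical = 0
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for offset in range(a_end - a_start):
            ia, ib = a_start + offset, b_start + offset
            if region is not None and not region[0] <= ia + 1 <= region[1]:
                continue
            aligned_cols += 1
            if seq_a[ia] == seq_b[ib]:
                identical += 1
    if aligned_cols == 0:
        raise ValueError("no aligned residue columns (empty region?)")
    percent = round(100.0 * identical / aligned_cols, 1)
    return IdentityResult(
        pair_label=pair_label,
        aligned_length=aligned_cols,
        identical_positions=identical,
        percent_identity=percent,
        region=region,
    )
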