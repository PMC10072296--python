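"""Pairwise percent-identity matrices over a receptor set.

Each pair is aligned globally (Needleman–Wunsch) and percent identity
is the fraction of identical alignment columns.  The matrix supports
reference-normalized ranking of orphan receptors against the two known
CCK receptors: each candidate's raw score is the mean of its identities
with the two references, divided by the inter-reference identity.  The
normalization is a positive rescaling and never reorders candidates.

Alignments use :class:`Bio.Align.PairwiseAligner` with BLOSUM62 and
affine gap penalties by default.  Note the Biopython gap convention:
``open_gap_score`` is charged for the first gapped position, so a
length-k gap costs ``open + (k - 1) * extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .records import ProteinRecord, check_unique_ids


@dataclass
class AlignParams:
    """Global-alignment scoring parameters.

    ``matrix_name`` selects a Biopython substitution matrix (or ``None``
    for simple match/mismatch scores); gap penalties are positive
    magnitudes.  ``denominator`` chooses the percent-identity
    denominator: 'columns' (all alignment columns, gap-inclusive) or
    'shorter' (length of the shorter sequence).
    """

    matrix_name: str | None = "BLOSUM62"
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    denominator: str = "columns"

    def __post_init__(self):
        if self.denominator not in ("columns", "shorter"):
            raise ValueError("denominator must be 'columns' or 'shorter'")

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        if self.matrix_name is not None:
            aligner.substitution_matrix = substitution_matrices.load(self.matrix_name)
        else:
            aligner.match_score = self.match
            aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = -abs(self.gap_open)
        aligner.extend_gap_score = -abs(self.gap_extend)
        return aligner


@dataclass(frozen=True)
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows must have equal length")
        if any(x == "-" and y == "-" for x, y in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("alignment contains an all-gap column")

    def __len__(self) -> int:
        return len(self.aligned_a)


@dataclass(frozen=True)
class IdentityMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # square, percent identities in [0, 100]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.ids.index(id_a), self.ids.index(id_b)])


def global_align(
    a: ProteinRecord, b: ProteinRecord, params: AlignParams | None = None
) -> PairwiseAlignment:
    """Optimal Needleman–Wunsch global alignment of two records.

    Deterministic: of the co-optimal tracebacks Biopython enumerates we
    take the first, whose order is fixed by the library's traceback
    preference.
    """
    params = params or AlignParams()
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    aligner = params.make_aligner()
    alignments = aligner.align(a.residues, b.residues)
    best = alignments[0]
    return PairwiseAlignment(
        id_a=a.id,
        id_b=b.id,
        aligned_a=str(best[0]),
        aligned_b=str(best[1]),
        score=float(best.score),
    )


def percent_identity(alignment: PairwiseAlignment, denominator: str = "columns") -> float:
    """Percent of identical columns in a pairwise alignment.

    Gap columns count in the denominator and never as identities.  With
    ``denominator='shorter'`` the shorter ungapped sequence length is
    used instead of the column count.
    """
    n_cols = len(alignment)
    if n_cols == 0:
        raise ValueError("zero-length alignment")
    identical = sum(
        1
        for x, y in zip(alignment.aligned_a, alignment.aligned_b)
        if x == y and x != "-"
    )
    if denominator == "columns":
        denom = n_cols
    elif denominator == "shorter":
        denom = min(
            len(alignment.aligned_a.replace("-", "")),
            len(alignment.aligned_b.replace("-", "")),
        )
    else:
        raise ValueError("denominator must be 'columns' or 'shorter'")
    return 100.0 * identical / denom


def build_identity_matrix(
    records: Sequence[ProteinRecord], params: AlignParams | None = None
) -> IdentityMatrix:
    """All-pairs percent-identity matrix (symmetric, diagonal 100)."""
    params = params or AlignParams()
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    check_unique_ids(records)
    n = len(records)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i], records[j], params)
            pid = percent_identity(aln, params.denominator)
            values[i, j] = values[j, i] = pid
    return IdentityMatrix(ids=tuple(r.id for r in records), values=values)


def normalized_reference_score(
    matrix: IdentityMatrix,
    ref_ids: tuple[str, str],
    top_k: int = 5,
) -> pd.DataFrame:
    """Rank non-reference receptors by reference-normalized mean identity.

    raw(c) = mean(PID(c, ref1), PID(c, ref2));
    normalized(c) = raw(c) / PID(ref1, ref2).
    Returns a DataFrame sorted descending by normalized score (ties by
    id), with a boolean ``top_k`` column marking the leading entries.
    """
    ref1, ref2 = ref_ids
    for ref in (ref1, ref2):
        if ref not in matrix.ids:
            raise ValueError(f"reference id {ref!r} not in matrix")
    inter_ref = matrix.get(ref1, ref2)
    if inter_ref == 0:
        raise ValueError("inter-reference identity is zero; cannot normalize")
    rows = []
    for cid in matrix.ids:
        if cid in (ref1, ref2):
            continue
        raw = 0.5 * (matrix.get(cid, ref1) + matrix.get(cid, ref2))
        rows.append({"candidate_id": cid, "raw": raw, "normalized": raw / inter_ref})
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["normalized", "candidate_id"], ascending=[False, True]
    ).reset_index(drop=True)
    table["top_k"] = table.index < top_k
    return table
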