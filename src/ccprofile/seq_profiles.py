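"""Sequence-derived tracks: alignment-column conservation and hydropathy.

Conservation: per-column amino-acid frequencies are weighted by independent
counts (single-linkage sequence clusters at a fractional-identity threshold,
counted once per cluster), scored as the entropy sum f*ln(f) in
[-ln 20, 0] and normalized linearly to [0, 1] (1 = perfectly conserved).

Hydropathy: per-position sum of Kyte-Doolittle values over a 15-residue
window (7 leading, 7 trailing, truncated at the termini).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO

from .constants import (
    AA_ALPHABET,
    DEFAULT_CLUSTER_THETA,
    HYDROPATHY_WINDOW,
    KYTE_DOOLITTLE,
    LN20,
)
from .profile import Profile, new_profile
from .refmap import ReferenceSequence

GAP = "-"


@dataclass
class MSA:
    """A gapped multiple sequence alignment with a designated reference row."""

    ids: list[str]
    rows: list[str]
    ref_row: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows differ in length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def depth(self) -> int:
        return len(self.rows)

    def reference_positions(self) -> list[int]:
        """Column indices (0-based) where the reference row is not a gap."""
        return [c for c, ch in enumerate(self.rows[self.ref_row]) if ch != GAP]

    def degapped_reference(self) -> str:
        return self.rows[self.ref_row].replace(GAP, "")


def read_msa_fasta(path: str | Path, ref_id: str | None = None) -> MSA:
    """Read an aligned FASTA file; the reference row is matched by id or row 0."""
    ids, rows = [], []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        rows.append(str(record.seq))
    if not rows:
        raise ValueError(f"no FASTA records in {path}")
    ref_row = 0
    if ref_id is not None:
        try:
            ref_row = ids.index(ref_id)
        except ValueError:
            raise ValueError(f"reference row {ref_id!r} missing from alignment") from None
    return MSA(ids, rows, ref_row)


# ---------------------------------------------------------------------------
# independent-count weighting
# ---------------------------------------------------------------------------


def _row_identity(a: str, b: str) -> float:
    """Fractional identity over columns where both rows are non-gap."""
    same = both = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            both += 1
            if x == y:
                same += 1
    return same / both if both else 0.0


def _single_linkage_clusters(rows: Sequence[int], msa: MSA, theta: float) -> int:
    """Number of single-linkage clusters at identity >= theta among rows."""
    if theta > 1.0:
        return len(rows)  # unweighted mode: every row its own cluster
    parent = {r: r for r in rows}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rows = list(rows)
    for i, a in enumerate(rows):
        for b in rows[i + 1 :]:
            if _row_identity(msa.rows[a], msa.rows[b]) >= theta:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    return len({find(r) for r in rows})


def independent_count_weights(
    msa: MSA, column: int, theta: float = DEFAULT_CLUSTER_THETA
) -> Optional[dict[str, float]]:
    """Weighted amino-acid frequencies f_a at a column (0-based index).

    Rows carrying type ``a`` are clustered by full-row identity; the cluster
    count is the independent count IC_a, and f_a = IC_a / sum_b IC_b.  Gaps
    are excluded; an all-gap column returns None.
    """
    carriers: dict[str, list[int]] = {}
    for r, row in enumerate(msa.rows):
        ch = row[column]
        if ch != GAP and ch in AA_ALPHABET:
            carriers.setdefault(ch, []).append(r)
    if not carriers:
        return None
    counts = {a: float(_single_linkage_clusters(rows, msa, theta)) for a, rows in carriers.items()}
    total = sum(counts.values())
    return {a: c / total for a, c in counts.items()}


def raw_conservation(frequencies: dict[str, float]) -> float:
    """Entropy score sum_a f_a ln f_a, in [-ln 20, 0]."""
    return sum(f * math.log(f) for f in frequencies.values() if f > 0)


def normalize_conservation(raw: float) -> float:
    """Linear map from [-ln 20, 0] to [0, 1]."""
    return (raw + LN20) / LN20


def conservation_profile(
    msa: MSA,
    ref: ReferenceSequence,
    theta: float = DEFAULT_CLUSTER_THETA,
) -> Profile:
    """Normalized per-reference-position conservation from the alignment.

    Columns where the reference row is a gap do not map to any position and
    are skipped; all-gap columns are null.
    """
    if msa.degapped_reference() != ref.sequence:
        raise ValueError("degapped reference row does not equal the reference sequence")
    profile = new_profile(ref.id, len(ref), kind="real", name="conservation")
    for pos, col in enumerate(msa.reference_positions(), start=1):
        freqs = independent_count_weights(msa, col, theta)
        if freqs is None:
            continue
        profile.values[pos - 1] = normalize_conservation(raw_conservation(freqs))
    return profile


# ---------------------------------------------------------------------------
# hydropathy
# ---------------------------------------------------------------------------


def hydropathy_profile(
    sequence: str | ReferenceSequence, window: int = HYDROPATHY_WINDOW
) -> Profile:
    """Windowed hydropathy sum (not mean); unknown letters contribute 0."""
    if isinstance(sequence, ReferenceSequence):
        ref_id, seq = sequence.id, sequence.sequence
    else:
        ref_id, seq = "seq", sequence.upper()
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd number")
    half = window // 2
    L = len(seq)
    profile = new_profile(ref_id, L, kind="real", name="hydropathy")
    for i in range(1, L + 1):
        lo, hi = max(1, i - half), min(L, i + half)
        profile.values[i - 1] = sum(
            KYTE_DOOLITTLE.get(seq[j - 1], 0.0) for j in range(lo, hi + 1)
        )
    return profile
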