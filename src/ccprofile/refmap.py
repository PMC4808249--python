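"""Mapping of structure SEQRES sequences onto a reference sequence.

A fragment is accepted only when it embeds into the reference gaplessly and
end-to-end, with identity >= 95% and expectation value < 0.001; a pair of
structures is usable only when both mapped intervals overlap.  The gapless
end-to-end constraints reduce alignment to an exhaustive offset scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Align import substitution_matrices

from .constants import (
    EVALUE_THRESHOLD,
    IDENTITY_THRESHOLD,
    KA_K,
    KA_LAMBDA,
)
from .structure_io import ProteinStructure

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class OverlapError(ValueError):
    """Mapped intervals of the two structures do not overlap."""


@dataclass
class ReferenceSequence:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError("empty reference sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def read_reference_fasta(path: str | Path) -> ReferenceSequence:
    """Read the first record of a FASTA file as the reference sequence."""
    for record in SeqIO.parse(str(path), "fasta"):
        return ReferenceSequence(id=record.id, sequence=str(record.seq))
    raise ValueError(f"no FASTA records in {path}")


@dataclass
class MappingResult:
    offset: int            # 1-based start on the reference; 0 when not embeddable
    identity: float        # percent of matched residues over fragment length
    evalue: float
    valid: bool
    reasons: list[str] = field(default_factory=list)
    matches: int = 0
    frag_len: int = 0

    @property
    def interval(self) -> tuple[int, int]:
        return (self.offset, self.offset + self.frag_len - 1)


def alignment_score(frag: str, ref_window: str) -> float:
    """Ungapped BLOSUM62 score of two equal-length strings."""
    score = 0.0
    for a, b in zip(frag, ref_window):
        try:
            score += _BLOSUM62[a, b]
        except (KeyError, IndexError):
            score += _BLOSUM62["X", "X"]
    return score


def evalue(score: float, frag_len: int, ref_len: int) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    return KA_K * frag_len * ref_len * math.exp(-KA_LAMBDA * score)


def map_fragment(frag: str, ref: ReferenceSequence) -> MappingResult:
    """Best gapless end-to-end placement of ``frag`` inside the reference.

    All offsets are scanned; ties on identity resolve to the smallest offset
    (ambiguity is recorded in ``reasons``).
    """
    frag = frag.upper()
    m, n = len(frag), len(ref)
    if m < 1:
        raise ValueError("empty fragment")
    if m > n:
        return MappingResult(0, 0.0, math.inf, False, ["not embeddable"], 0, m)

    best_offset, best_matches, ambiguous = 0, -1, False
    for off in range(1, n - m + 2):
        window = ref.sequence[off - 1 : off - 1 + m]
        matches = sum(a == b for a, b in zip(frag, window))
        if matches > best_matches:
            best_offset, best_matches, ambiguous = off, matches, False
        elif matches == best_matches:
            ambiguous = True

    window = ref.sequence[best_offset - 1 : best_offset - 1 + m]
    identity = 100.0 * best_matches / m
    ev = evalue(alignment_score(frag, window), m, n)

    reasons: list[str] = []
    if identity < IDENTITY_THRESHOLD:
        reasons.append("identity")
        if _gapped_rescue(frag, ref.sequence):
            reasons.append("indel")
    if ev >= EVALUE_THRESHOLD:
        reasons.append("evalue")
    if ambiguous:
        reasons.append("ambiguous placement")
    valid = "identity" not in reasons and "evalue" not in reasons
    return MappingResult(best_offset, identity, ev, valid, reasons, best_matches, m)


def write_mapping_report(
    mappings: dict[str, MappingResult], path: str | Path
) -> None:
    """TSV report of fragment mappings: one row per labelled fragment."""
    lines = ["\t".join(["fragment", "offset", "identity", "evalue", "valid", "reasons"])]
    for label, mp in mappings.items():
        lines.append("\t".join([
            label, str(mp.offset), f"{mp.identity:.2f}", f"{mp.evalue:.3g}",
            "true" if mp.valid else "false", ";".join(mp.reasons) or "-",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def alignment_text(frag: str, ref: ReferenceSequence, mapping: MappingResult) -> str:
    """Two-row text dump of the placed (gapless) alignment."""
    if mapping.offset < 1:
        return "(not embeddable)"
    pad = " " * (mapping.offset - 1)
    tail = " " * (len(ref) - mapping.offset - len(frag) + 1)
    window = ref.sequence[mapping.offset - 1 : mapping.offset - 1 + len(frag)]
    marks = "".join("|" if a == b else "." for a, b in zip(frag, window))
    return "\n".join([
        f"{ref.id}  1 {ref.sequence} {len(ref)}",
        f"{'':{len(ref.id)}s}    {pad}{marks}{tail}",
        f"{'frag':{len(ref.id)}s}    {pad}{frag}{tail}",
    ])


def _piece_matches(piece: str, ref: str) -> list[int]:
    """Match count of an ungapped placement of ``piece`` at every offset."""
    k, n = len(piece), len(ref)
    return [
        sum(a == b for a, b in zip(piece, ref[o : o + k]))
        for o in range(n - k + 1)
    ]


def _gapped_rescue(frag: str, ref: str, max_insertion: int = 10) -> bool:
    """Would a single indel lift the placement above the identity threshold?

    Diagnostic only: tries every two-piece split with either a reference gap
    (deletion in the fragment) or a skipped fragment stretch (insertion).
    """
    m, n = len(frag), len(ref)
    if m * m * n > 20_000_000:  # diagnostic not worth cubic time on long inputs
        return False
    threshold = IDENTITY_THRESHOLD / 100.0
    for k in range(1, m):
        left = _piece_matches(frag[:k], ref)
        right = _piece_matches(frag[k:], ref)
        # deletion: right piece placed at least one past the left piece's end
        suffix_best = [0] * (len(right) + 1)
        for o in range(len(right) - 1, -1, -1):
            suffix_best[o] = max(right[o], suffix_best[o + 1])
        for o1, m1 in enumerate(left):
            nxt = o1 + k + 1
            if nxt < len(right) and (m1 + suffix_best[nxt]) / m >= threshold:
                return True
        # insertion: skip g fragment residues, pieces contiguous on the ref
        for g in range(1, min(max_insertion, m - k) + 1):
            right_g = _piece_matches(frag[k + g :], ref) if k + g < m else []
            denom = m - g
            for o1, m1 in enumerate(left):
                o2 = o1 + k
                if o2 < len(right_g) and (m1 + right_g[o2]) / denom >= threshold:
                    return True
    return False


# ---------------------------------------------------------------------------
# joint per-position residue map
# ---------------------------------------------------------------------------

OBSERVED = "observed"
DISORDERED = "disordered"
NULL = "null"


@dataclass
class ResidueMap:
    """Joint per-reference-position view of two mapped structures."""

    ref: ReferenceSequence
    s1: ProteinStructure
    s2: ProteinStructure
    mapping1: MappingResult
    mapping2: MappingResult

    def _status(self, which: int, i: int):
        mapping = self.mapping1 if which == 1 else self.mapping2
        structure = self.s1 if which == 1 else self.s2
        lo, hi = mapping.interval
        if not lo <= i <= hi:
            return NULL, None
        idx = i - mapping.offset + 1
        res = structure.observed.get(idx)
        if res is None:
            return DISORDERED, None
        return OBSERVED, res

    def status(self, which: int, i: int) -> str:
        return self._status(which, i)[0]

    def residue(self, which: int, i: int):
        return self._status(which, i)[1]

    def seqres_index(self, which: int, i: int) -> Optional[int]:
        mapping = self.mapping1 if which == 1 else self.mapping2
        lo, hi = mapping.interval
        if not lo <= i <= hi:
            return None
        return i - mapping.offset + 1

    def doubly_observed(self) -> list[int]:
        return [
            i
            for i in range(1, len(self.ref) + 1)
            if self.status(1, i) == OBSERVED and self.status(2, i) == OBSERVED
        ]

    @property
    def overlap_interval(self) -> tuple[int, int]:
        lo = max(self.mapping1.interval[0], self.mapping2.interval[0])
        hi = min(self.mapping1.interval[1], self.mapping2.interval[1])
        return (lo, hi)


def build_residue_map(
    s1: ProteinStructure,
    s2: ProteinStructure,
    ref: ReferenceSequence,
    mapping1: MappingResult | None = None,
    mapping2: MappingResult | None = None,
) -> ResidueMap:
    """Validate both fragment mappings and assemble the joint residue map."""
    mapping1 = mapping1 or map_fragment(s1.seqres, ref)
    mapping2 = mapping2 or map_fragment(s2.seqres, ref)
    for name, mp in (("s1", mapping1), ("s2", mapping2)):
        if not mp.valid:
            raise ValueError(f"invalid mapping for {name}: {mp.reasons}")
    lo = max(mapping1.interval[0], mapping2.interval[0])
    hi = min(mapping1.interval[1], mapping2.interval[1])
    if lo > hi:
        raise OverlapError("no overlap between mapped intervals")
    return ResidueMap(ref, s1, s2, mapping1, mapping2)
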