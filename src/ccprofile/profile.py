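"""Fixed-length per-position tracks keyed to reference positions (1-based)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Optional, Sequence


@dataclass
class Profile:
    """A per-position track over the reference sequence.

    ``values[i-1]`` holds the value at reference position ``i``; ``None``
    marks a null position.  ``kind`` is a free tag ("real", "boolean",
    "category", "names"); ``units`` is informational.
    """

    ref_id: str
    values: list[Any]
    kind: str = "real"
    units: str = ""
    name: str = ""

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, position: int) -> Any:
        if not 1 <= position <= len(self.values):
            raise IndexError(f"position {position} outside [1, {len(self.values)}]")
        return self.values[position - 1]

    def __iter__(self) -> Iterator[Any]:
        return iter(self.values)

    def positions(self) -> range:
        return range(1, len(self.values) + 1)

    def non_null(self) -> list[tuple[int, Any]]:
        return [(i, v) for i, v in enumerate(self.values, start=1) if v is not None]

    @property
    def max_position(self) -> Optional[int]:
        best = None
        for i, v in self.non_null():
            if best is None or v > best[1]:
                best = (i, v)
        return None if best is None else best[0]


def new_profile(
    ref_id: str, length: int, kind: str = "real", units: str = "", name: str = ""
) -> Profile:
    return Profile(ref_id, [None] * length, kind, units, name)
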