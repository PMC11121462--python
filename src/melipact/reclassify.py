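"""Conductivity-based botanical reclassification.

Electrical conductivity above 0.8 mS/cm is characteristic of honeydew honey;
flower (nectar) honey lies below.  Before any compliance screening, every
sample's declared class is checked against its measured conductivity:

* a non-honeydew sample with conductivity strictly above the cut is moved
  *into* the honeydew class;
* a declared honeydew sample strictly below the cut is moved *out*, to
  polyfloral (the mixed-nectar default — no attempt is made to recover a
  monofloral label);
* a value exactly at the cut leaves the declared class unchanged.

The rule is idempotent: out-moves land in polyfloral with conductivity below
the cut, which cannot re-trigger either branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .data_model import HoneySample, HoneyType, SampleTable, ThresholdPolicy

__all__ = ["Direction", "ReclassificationReport", "reclassify_sample", "reclassify_table"]


class Direction(str, Enum):
    INTO_HONEYDEW = "into-honeydew"
    OUT_OF_HONEYDEW = "out-of-honeydew"
    NONE = "none"


@dataclass(frozen=True)
class MoveRecord:
    sample_id: str
    declared_type: HoneyType
    final_type: HoneyType
    direction: Direction

    @property
    def moved(self) -> bool:
        return self.direction is not Direction.NONE


@dataclass(frozen=True)
class ReclassificationReport:
    moves: tuple[MoveRecord, ...]

    @property
    def moved_count(self) -> int:
        return sum(1 for m in self.moves if m.moved)

    @property
    def in_count(self) -> int:
        return sum(1 for m in self.moves if m.direction is Direction.INTO_HONEYDEW)

    @property
    def out_count(self) -> int:
        return sum(1 for m in self.moves if m.direction is Direction.OUT_OF_HONEYDEW)

    @property
    def final_honeydew_count(self) -> int:
        return sum(1 for m in self.moves if m.final_type is HoneyType.HONEYDEW)

    def to_dict(self) -> dict:
        return {
            "moved": self.moved_count,
            "into_honeydew": self.in_count,
            "out_of_honeydew": self.out_count,
            "final_honeydew": self.final_honeydew_count,
            "moves": [
                {
                    "sample_id": m.sample_id,
                    "declared_type": m.declared_type.value,
                    "final_type": m.final_type.value,
                    "direction": m.direction.value,
                }
                for m in self.moves
                if m.moved
            ],
        }


def reclassify_sample(
    declared: HoneyType, econd: float, policy: ThresholdPolicy | None = None
) -> tuple[HoneyType, Direction]:
    """Apply the conductivity rule to one (declared type, conductivity) pair."""
    if not isinstance(declared, HoneyType):
        raise TypeError(f"unknown honey type {declared!r}")
    if econd < 0:
        raise ValueError(f"conductivity must be >= 0, got {econd}")
    cut = (policy or ThresholdPolicy()).econd_flower_max
    if declared is not HoneyType.HONEYDEW and econd > cut:
        return HoneyType.HONEYDEW, Direction.INTO_HONEYDEW
    if declared is HoneyType.HONEYDEW and econd < cut:
        return HoneyType.POLYFLORAL, Direction.OUT_OF_HONEYDEW
    return declared, Direction.NONE


def reclassify_table(
    table: SampleTable, policy: ThresholdPolicy | None = None
) -> tuple[SampleTable, ReclassificationReport]:
    """Set ``final_type`` on every record; return the moved table and report.

    Record count and all other fields are preserved; the operation is
    idempotent on its own output.
    """
    policy = policy or ThresholdPolicy()
    out: list[HoneySample] = []
    moves: list[MoveRecord] = []
    for s in table:
        base = s.effective_type
        final, direction = reclassify_sample(base, s.econd, policy)
        out.append(s.with_final_type(final))
        moves.append(MoveRecord(s.sample_id, s.declared_type, final, direction))
    return SampleTable(out, provenance=table.provenance), ReclassificationReport(tuple(moves))
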