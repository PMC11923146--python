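"""Leakage-controlled train/validation partitioning.

Confocal image series from one patient share cellular "fingerprint" cues and
may physically overlap, and square tiles cut from one annotation share
pixels. Both therefore inflate validation metrics if they straddle the
train/validation boundary. Splits are drawn at the patient level, and all
tiles of one annotation group stay on one side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["SplitItem", "SplitPlan", "SplitError", "grouped_split", "audit_leakage"]


class SplitError(ValueError):
    """Raised when a valid grouped split cannot be formed."""


@dataclass(frozen=True)
class SplitItem:
    """One splittable unit (an image or a tile) with its grouping keys."""

    item_id: str
    patient_id: str
    group_id: str = ""  # annotation group; empty = item is its own group


@dataclass
class SplitPlan:
    """A patient- and group-disjoint train/validation partition of item ids."""

    train_ids: frozenset[str]
    val_ids: frozenset[str]
    grouping: dict[str, tuple[str, str]]  # item_id -> (patient_id, group_id)
    seed: int
    val_fraction: float

    def side_of(self, item_id: str) -> str:
        if item_id in self.train_ids:
            return "train"
        if item_id in self.val_ids:
            return "val"
        raise KeyError(item_id)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "val_fraction": self.val_fraction,
            "train_ids": sorted(self.train_ids),
            "val_ids": sorted(self.val_ids),
            "grouping": {k: list(v) for k, v in sorted(self.grouping.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        return cls(
            train_ids=frozenset(payload["train_ids"]),
            val_ids=frozenset(payload["val_ids"]),
            grouping={k: (v[0], v[1]) for k, v in payload["grouping"].items()},
            seed=int(payload["seed"]),
            val_fraction=float(payload["val_fraction"]),
        )


def grouped_split(
    items: Sequence[SplitItem], val_fraction: float, seed: int
) -> SplitPlan:
    """Partition items into train/validation with no patient on both sides.

    Patients are shuffled deterministically by ``seed`` and assigned to the
    validation side until the validation item count reaches
    ``val_fraction * len(items)``; the achieved fraction is therefore within
    one patient's worth of items of the request. Annotation groups never span
    patients by construction, so the group constraint is inherited and then
    verified; a group spanning two patients is rejected outright.
    """
    if not 0.0 < val_fraction < 1.0:
        raise SplitError(f"val_fraction must be in (0, 1), got {val_fraction}")
    by_patient: dict[str, list[SplitItem]] = {}
    group_patient: dict[str, str] = {}
    for it in items:
        by_patient.setdefault(it.patient_id, []).append(it)
        if it.group_id:
            prev = group_patient.setdefault(it.group_id, it.patient_id)
            if prev != it.patient_id:
                raise SplitError(
                    f"annotation group {it.group_id!r} spans patients "
                    f"{prev!r} and {it.patient_id!r}; cannot split safely"
                )
    if len(by_patient) < 2:
        raise SplitError("grouped split needs at least 2 patients")

    rng = np.random.default_rng(seed)
    patients = sorted(by_patient)
    rng.shuffle(patients)
    target = val_fraction * len(items)
    val_ids: set[str] = set()
    for pid in patients:
        if len(val_ids) >= target:
            break
        val_ids.update(it.item_id for it in by_patient[pid])
    # never allow an empty side
    if len(val_ids) == len(items):
        first = patients[0]
        val_ids.difference_update(it.item_id for it in by_patient[first])
    train_ids = {it.item_id for it in items} - val_ids
    plan = SplitPlan(
        train_ids=frozenset(train_ids),
        val_ids=frozenset(val_ids),
        grouping={it.item_id: (it.patient_id, it.group_id) for it in items},
        seed=seed,
        val_fraction=val_fraction,
    )
    violations = audit_leakage(plan, items)
    if violations:  # defensive: unreachable when constraints are consistent
        raise SplitError(f"split produced leakage: {violations}")
    return plan


def audit_leakage(
    plan: SplitPlan, items: Iterable[SplitItem]
) -> list[dict[str, str]]:
    """Report every patient or annotation group present on both split sides.

    Returns an empty list iff the plan satisfies both disjointness
    invariants; otherwise one record per offending key, e.g.
    ``{"kind": "patient", "key": "P003"}``.
    """
    patient_sides: dict[str, set[str]] = {}
    group_sides: dict[str, set[str]] = {}
    for it in items:
        if it.item_id in plan.train_ids:
            side = "train"
        elif it.item_id in plan.val_ids:
            side = "val"
        else:
            continue
        patient_sides.setdefault(it.patient_id, set()).add(side)
        if it.group_id:
            group_sides.setdefault(it.group_id, set()).add(side)
    violations = [
        {"kind": "patient", "key": pid}
        for pid, sides in sorted(patient_sides.items())
        if len(sides) > 1
    ]
    violations += [
        {"kind": "group", "key": gid}
        for gid, sides in sorted(group_sides.items())
        if len(sides) > 1
    ]
    return violations
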