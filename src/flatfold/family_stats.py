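"""Per-label occurrence frequency and average length over a protein family.

Each family-wide label is counted once per member; frequency is count divided
by the number of members.  Labels at or above the primary threshold are
"primary" (shared by most of the family), the rest "secondary" — the split that
drives the two-stage layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .errors import FlatfoldError
from .sse_annotation import AnnotatedFamily

PRIMARY = "primary"
SECONDARY = "secondary"


@dataclass(frozen=True)
class LabelStats:
    count: int
    frequency: float
    avg_length: float  # residues, arithmetic mean over occurrences
    sse_type: str
    sse_class: str  # "primary" | "secondary"


@dataclass
class FamilyStats:
    family_id: str
    n_members: int
    primary_threshold: float
    per_label: dict[str, LabelStats]

    def class_of(self, label: str) -> str:
        return self.per_label[label].sse_class


def compute_family_stats(
    family: AnnotatedFamily, primary_threshold: float = 0.5
) -> FamilyStats:
    """Count label occurrences, average lengths, and split primary/secondary.

    A label is primary iff frequency >= ``primary_threshold`` (boundary
    inclusive).  A label occurring twice within one member violates the
    annotation invariants and raises.
    """
    n_members = len(family.members)
    if n_members == 0:
        raise ValueError("empty family")
    counts: dict[str, int] = {}
    lengths: dict[str, list[int]] = {}
    types: dict[str, str] = {}
    for dom_id, sses in family.members.items():
        seen = set()
        for s in sses:
            if s.label in seen:
                raise FlatfoldError(f"label {s.label} occurs twice in {dom_id}")
            seen.add(s.label)
            counts[s.label] = counts.get(s.label, 0) + 1
            lengths.setdefault(s.label, []).append(s.n_residues)
            types[s.label] = s.sse_type
    per_label = {}
    for label in sorted(counts):
        freq = counts[label] / n_members
        per_label[label] = LabelStats(
            count=counts[label],
            frequency=freq,
            avg_length=sum(lengths[label]) / len(lengths[label]),
            sse_type=types[label],
            sse_class=PRIMARY if freq >= primary_threshold else SECONDARY,
        )
    return FamilyStats(
        family_id=family.family_id,
        n_members=n_members,
        primary_threshold=primary_threshold,
        per_label=per_label,
    )


def stats_to_json(stats: FamilyStats) -> dict:
    return {
        "family": stats.family_id,
        "n_members": stats.n_members,
        "primary_threshold": stats.primary_threshold,
        "labels": {
            label: {
                "count": ls.count,
                "frequency": ls.frequency,
                "avg_length": ls.avg_length,
                "type": ls.sse_type,
                "class": ls.sse_class,
            }
            for label, ls in sorted(stats.per_label.items())
        },
    }


def stats_from_json(doc: dict) -> FamilyStats:
    return FamilyStats(
        family_id=doc["family"],
        n_members=doc["n_members"],
        primary_threshold=doc.get("primary_threshold", 0.5),
        per_label={
            label: LabelStats(
                count=e["count"],
                frequency=e["frequency"],
                avg_length=e["avg_length"],
                sse_type=e["type"],
                sse_class=e["class"],
            )
            for label, e in doc["labels"].items()
        },
    )


def write_stats(stats: FamilyStats, path: str | Path) -> None:
    Path(path).write_text(json.dumps(stats_to_json(stats), indent=2, sort_keys=True) + "\n")


def read_stats(path: str | Path) -> FamilyStats:
    return stats_from_json(json.loads(Path(path).read_text()))
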