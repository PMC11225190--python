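"""Grouping scenarios for MRPP batteries.

A scenario names disjoint groups of specimens (a taxon-delimitation
hypothesis, e.g. "GR01: ochraceofulva s.lat. vs sliwae s.lat.") and may
restrict the character set (e.g. an incomplete dataset without apothecial
characters). Scenario files are YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chardata import CharacterMatrix
from .errors import ScenarioError


@dataclass
class GroupingScenario:
    name: str
    groups: dict[str, frozenset[str]]
    character_subset: frozenset[str] | None = None

    def __post_init__(self):
        self.groups = {g: frozenset(m) for g, m in self.groups.items()}
        if self.character_subset is not None:
            self.character_subset = frozenset(self.character_subset)
        labels = list(self.groups)
        for i, a in enumerate(labels):
            if len(self.groups[a]) < 2:
                raise ScenarioError(f"{self.name}: group {a!r} has fewer than 2 members")
            for b in labels[i + 1 :]:
                overlap = self.groups[a] & self.groups[b]
                if overlap:
                    raise ScenarioError(
                        f"{self.name}: groups {a!r} and {b!r} share {sorted(overlap)}"
                    )
        if len(self.groups) < 2:
            raise ScenarioError(f"{self.name}: need at least 2 groups")

    @property
    def member_ids(self) -> list[str]:
        out: list[str] = []
        for g in self.groups.values():
            out.extend(sorted(g))
        return out

    def validate_against(self, matrix: CharacterMatrix) -> None:
        unknown = set(self.member_ids) - set(matrix.specimen_ids)
        if unknown:
            raise ScenarioError(
                f"{self.name}: specimens not in matrix: {sorted(unknown)}"
            )
        if self.character_subset is not None:
            missing = self.character_subset - set(matrix.character_ids)
            if missing:
                raise ScenarioError(
                    f"{self.name}: unknown characters: {sorted(missing)}"
                )


def read_scenarios(path: str | Path) -> list[GroupingScenario]:
    doc = yaml.safe_load(Path(path).read_text())
    entries = doc["scenarios"] if isinstance(doc, dict) else doc
    out = []
    for entry in entries:
        out.append(
            GroupingScenario(
                name=str(entry["name"]),
                groups={str(g): frozenset(map(str, m)) for g, m in entry["groups"].items()},
                character_subset=(
                    frozenset(map(str, entry["character_subset"]))
                    if entry.get("character_subset")
                    else None
                ),
            )
        )
    return out


def write_scenarios(scenarios: list[GroupingScenario], path: str | Path) -> None:
    doc = {
        "scenarios": [
            {
                "name": s.name,
                "groups": {g: sorted(m) for g, m in s.groups.items()},
                **(
                    {"character_subset": sorted(s.character_subset)}
                    if s.character_subset is not None
                    else {}
                ),
            }
            for s in scenarios
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
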