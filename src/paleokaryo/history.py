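"""Curated karyotype-evolution scenario library.

The package ships count-level event scripts describing how 19 modern plant
and animal genomes descend from their founder karyotypes (the n = 5
ancestral grass karyotype, the n = 21 hexaploid eudicot intermediate, and
the n = 10 ancestral vertebrate karyotype) through rounds of whole-genome
duplication, chromosome fissions and fusions.  Replaying a script through
:func:`paleokaryo.scenario.count_trace` yields the chromosome-number
trajectory of the lineage.

For three lineages (chicken, human, chimpanzee) the curated event counts
do not reproduce the stated modern chromosome number under the count law;
the scripts keep the curated counts and carry the stated number in a
separate ``stated_n`` field so the discrepancy stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import yaml

from .scenario import count_trace

CountStep = tuple[str, int] | str


@dataclass(frozen=True)
class LineageScript:
    name: str
    ancestor: str
    start_n: int
    steps: tuple[CountStep, ...]  # full step list from the ancestor
    expected_n: int
    stated_n: Optional[int] = None  # only when it differs from expected_n

    def replay(self) -> tuple[int, list[int]]:
        return count_trace(self.start_n, self.steps)


def _parse_steps(raw: list) -> list[CountStep]:
    steps: list[CountStep] = []
    for item in raw:
        if item == "WGD":
            steps.append("WGD")
        elif isinstance(item, dict) and len(item) == 1:
            (kind, k), = item.items()
            if kind not in ("fis", "fus"):
                raise ValueError(f"unknown count step kind {kind!r}")
            steps.append((kind, int(k)))
        else:
            raise ValueError(f"malformed scenario step {item!r}")
    return steps


def load_scenario_library(kingdom: str) -> dict[str, LineageScript]:
    """Load the plant or animal scenario scripts shipped with the package."""
    if kingdom not in ("plant", "animal"):
        raise ValueError("kingdom must be 'plant' or 'animal'")
    text = (
        resources.files("paleokaryo.data.scenarios")
        .joinpath(f"{kingdom}.yaml")
        .read_text()
    )
    doc = yaml.safe_load(text)
    ancestors: dict[str, int] = doc["ancestors"]

    resolved: dict[str, LineageScript] = {}

    def resolve(name: str) -> LineageScript:
        if name in resolved:
            return resolved[name]
        entry = doc["lineages"][name]
        own = _parse_steps(entry.get("steps", []))
        start = entry["start"]
        if start in ancestors:
            ancestor, start_n, prefix = start, ancestors[start], []
        else:
            parent = resolve(start)
            ancestor, start_n, prefix = (
                parent.ancestor, parent.start_n, list(parent.steps)
            )
        script = LineageScript(
            name=name,
            ancestor=ancestor,
            start_n=start_n,
            steps=tuple(prefix + own),
            expected_n=int(entry["expected_n"]),
            stated_n=entry.get("stated_n"),
        )
        resolved[name] = script
        return script

    for name in doc["lineages"]:
        resolve(name)
    return resolved


def replay_library(kingdom: str) -> dict[str, tuple[int, int]]:
    """Replay every lineage script: name -> (computed n, expected n)."""
    return {
        name: (script.replay()[0], script.expected_n)
        for name, script in load_scenario_library(kingdom).items()
    }
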