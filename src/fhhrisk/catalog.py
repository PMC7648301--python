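"""Versioned condition catalog.

The risk engine assesses a closed list of 27 actionable conditions (a mix
of common chronic diseases and hereditary syndromes) plus an ``other:``
escape hatch for conditions that are recorded but not risk-assessed.  The
shipped list is a configurable stand-in covering the conditions the rule
catalog and clustering statistics reference; deployments may load their
own.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml


@dataclass(frozen=True)
class ConditionDef:
    code: str
    label: str
    category: str  # cancer | cardiovascular | metabolic | hereditary | respiratory


@dataclass
class ConditionCatalog:
    version: str
    conditions: dict[str, ConditionDef] = field(default_factory=dict)

    def resolvable(self, code: str) -> bool:
        return code in self.conditions or code.startswith("other:")

    def __contains__(self, code: str) -> bool:
        return self.resolvable(code)

    def codes(self) -> list[str]:
        return sorted(self.conditions)


def load_catalog(path_or_stream) -> ConditionCatalog:
    if hasattr(path_or_stream, "read"):
        data = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            data = yaml.safe_load(fh)
    conds = {
        c["code"]: ConditionDef(code=c["code"], label=c["label"], category=c["category"])
        for c in data["conditions"]
    }
    return ConditionCatalog(version=str(data["version"]), conditions=conds)


_DEFAULT: ConditionCatalog | None = None


def default_catalog() -> ConditionCatalog:
    global _DEFAULT
    if _DEFAULT is None:
        ref = importlib.resources.files("fhhrisk.config").joinpath("conditions.yaml")
        with ref.open() as fh:
            _DEFAULT = load_catalog(fh)
    return _DEFAULT
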