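"""Packaged simulation scenarios.

``wt_default`` reproduces a wild-type-like single-spine experiment
(transient +150% / sustained +40% volume change, binding-fraction baseline
0.12 with transient dP_AD 0.08 and sustained 0.04, dendritic spread length
2 um); ``ko_attenuated`` mimics the knockout phenotype (lower baseline,
attenuated activation, reduced volume change); ``smoke_test`` is a tiny,
fast configuration for pipeline smoke tests and examples.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

__all__ = ["available_scenarios", "load_scenario"]


def available_scenarios() -> list[str]:
    files = resources.files(__name__)
    return sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".yaml"))


def load_scenario(name_or_path):
    """Load a packaged scenario by name, or any scenario YAML by path."""
    from .. import io as fio

    p = Path(str(name_or_path))
    if p.suffix in (".yaml", ".yml") and p.exists():
        return fio.load_scenario_file(p)
    ref = resources.files(__name__) / f"{name_or_path}.yaml"
    if not ref.is_file():
        raise FileNotFoundError(
            f"unknown scenario '{name_or_path}'; packaged scenarios: {available_scenarios()}"
        )
    with resources.as_file(ref) as fp:
        return fio.load_scenario_file(fp)
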