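"""Simulation scenarios: true outcome probabilities and derived dose sets.

A scenario fixes the J x K grid and the true per-dose toxicity (and
optionally efficacy) probabilities used to generate patient outcomes.
Scenario files are YAML with matrices laid out the way combination
dose-finding tables are printed: one row per drug-B level, one column
per drug-A level.  Internally everything is stored as (J, K) arrays
indexed [j-1, k-1].

Derived sets, all relative to the scenario's metric threshold phiT:

* MTDCs  — doses whose true toxicity equals phiT exactly;
* overdoses — doses with true toxicity above phiT;
* OBDCs  — the most efficacious dose(s) among those with toxicity <= phiT;
* TDCs   — doses with efficacy >= 0.45 among those with toxicity <= phiT.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .grid import DoseGrid

__all__ = ["Scenario", "load_scenario", "list_scenarios", "derive_tdc_set"]

_TOL = 1e-9
TDC_EFF_THRESHOLD = 0.45


@dataclass(frozen=True)
class Scenario:
    name: str
    grid: DoseGrid
    tox_true: np.ndarray              # (J, K)
    eff_true: np.ndarray | None       # (J, K) or None
    phiT_metric: float

    @property
    def mtdc_set(self) -> frozenset:
        return frozenset(
            d for d in self.grid.doses()
            if abs(self._tox(d) - self.phiT_metric) < _TOL)

    @property
    def overdose_set(self) -> frozenset:
        return frozenset(d for d in self.grid.doses()
                         if self._tox(d) > self.phiT_metric + _TOL)

    @property
    def safe_set(self) -> frozenset:
        return frozenset(d for d in self.grid.doses()
                         if self._tox(d) <= self.phiT_metric + _TOL)

    @property
    def obdc_set(self) -> frozenset:
        """Most efficacious dose(s) among the safe doses."""
        if self.eff_true is None:
            raise ValueError(f"scenario {self.name!r} has no efficacy matrix")
        safe = self.safe_set
        if not safe:
            return frozenset()
        best = max(self._eff(d) for d in safe)
        return frozenset(d for d in safe if self._eff(d) > best - _TOL)

    @property
    def tdc_set(self) -> frozenset:
        return derive_tdc_set(self, self.phiT_metric, TDC_EFF_THRESHOLD)

    def _tox(self, dose) -> float:
        return float(self.tox_true[dose[0] - 1, dose[1] - 1])

    def _eff(self, dose) -> float:
        return float(self.eff_true[dose[0] - 1, dose[1] - 1])


def derive_tdc_set(scenario: Scenario, phiT: float,
                   eff_threshold: float = TDC_EFF_THRESHOLD) -> frozenset:
    """Target dose combinations: efficacy >= threshold among safe doses."""
    if scenario.eff_true is None:
        raise ValueError(f"scenario {scenario.name!r} has no efficacy matrix")
    return frozenset(
        d for d in scenario.grid.doses()
        if scenario._tox(d) <= phiT + _TOL
        and scenario._eff(d) >= eff_threshold - _TOL)


def _parse_matrix(rows, J: int, K: int, what: str) -> np.ndarray:
    if len(rows) != K or any(len(r) != J for r in rows):
        raise ValueError(f"{what} matrix must have {K} rows of {J} values")
    m = np.asarray(rows, dtype=float).T  # file is K x J; store as (J, K)
    if (m < 0).any() or (m > 1).any():
        raise ValueError(f"{what} probabilities must lie in [0, 1]")
    return m


def load_scenario(source, check_monotone_tox: bool = True) -> Scenario:
    """Load a scenario from a bundled name (e.g. ``"scenario7"``) or a path.

    ``check_monotone_tox`` enforces that the true toxicity surface is
    non-decreasing along both drug axes, as partial ordering requires;
    every bundled scenario satisfies it.
    """
    path = Path(source)
    if path.suffix in {".yaml", ".yml"} or path.exists():
        text = path.read_text()
    else:
        name = str(source)
        stem = f"scenario{int(name.removeprefix('scenario')):02d}"
        ref = resources.files("locrm.scenarios") / f"{stem}.yaml"
        if not ref.is_file():
            raise FileNotFoundError(f"no bundled scenario {source!r}")
        text = ref.read_text()
    doc = yaml.safe_load(text)
    for key in ("name", "rawA", "rawB", "tox", "phiT_metric"):
        if key not in doc:
            raise ValueError(f"scenario file missing key {key!r}")
    grid = DoseGrid(rawA=tuple(doc["rawA"]), rawB=tuple(doc["rawB"]))
    tox = _parse_matrix(doc["tox"], grid.J, grid.K, "toxicity")
    eff = None
    if doc.get("eff") is not None:
        eff = _parse_matrix(doc["eff"], grid.J, grid.K, "efficacy")
    if check_monotone_tox:
        if (np.diff(tox, axis=0) < -_TOL).any() or (np.diff(tox, axis=1) < -_TOL).any():
            raise ValueError(
                f"scenario {doc['name']!r}: toxicity surface is not "
                "non-decreasing along both dose axes")
    return Scenario(name=str(doc["name"]), grid=grid, tox_true=tox,
                    eff_true=eff, phiT_metric=float(doc["phiT_metric"]))


def list_scenarios() -> list:
    """Names of the bundled scenarios, in numeric order."""
    files = sorted(p.name for p in resources.files("locrm.scenarios").iterdir()
                   if p.name.endswith(".yaml"))
    return [f"scenario{int(f[8:10])}" for f in files]
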