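"""Battery specifications: which cognitive functions each test requires.

A battery maps each neuropsychological test to the set of cognitive
functions a subject must have at a high level to perform well on it:
attention (ATT), episodic memory at one of three hierarchical levels
(EM1 immediate recall, EM2 intermediate recall with distractors, EM3
delayed recall with distractors), verbal fluency (VF), cognitive
flexibility (CF) and perceptual motor speed (PS).  Episodic memory is
ordinal: capability at level k implies capability at every level below
it, so a test's memory demand is encoded as a single threshold
``em_required`` in {0, 1, 2, 3}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

#: Canonical reporting order of the seven function indicators.
FUNCTIONS = ("ATT", "EM1", "EM2", "EM3", "VF", "CF", "PS")

#: The four binary functions (EM is ordinal and handled separately).
BINARY_FUNCTIONS = ("ATT", "VF", "CF", "PS")

ORIENTATIONS = ("higher-is-better", "lower-is-better")
RESPONSE_KINDS = ("categorical-quartile", "continuous-timed")


@dataclass(frozen=True)
class FunctionDomain:
    """The set of cognitive functions profiles range over.

    The full domain has four binary functions and the four-level ordinal
    episodic-memory function, giving 2*2*2*2*4 = 64 raw profiles.
    Restricted domains (used mainly for small worked examples) fix the
    excluded functions at level 0.
    """

    binary: tuple[str, ...] = BINARY_FUNCTIONS
    include_em: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.binary) - set(BINARY_FUNCTIONS)
        if unknown:
            raise ValueError(f"unknown binary functions: {sorted(unknown)}")

    @property
    def n_profiles(self) -> int:
        return (4 if self.include_em else 1) * 2 ** len(self.binary)


FULL_DOMAIN = FunctionDomain()


@dataclass(frozen=True)
class TestSpec:
    """One test's function requirements and scoring conventions."""

    name: str
    requires_att: bool = False
    em_required: int = 0
    requires_vf: bool = False
    requires_cf: bool = False
    requires_ps: bool = False
    response_kind: str = "categorical-quartile"
    orientation: str = "higher-is-better"

    def __post_init__(self) -> None:
        if self.em_required not in (0, 1, 2, 3):
            raise ValueError(
                f"{self.name}: em_required must be in 0..3, got {self.em_required}"
            )
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"{self.name}: unknown orientation {self.orientation!r}")
        if self.response_kind not in RESPONSE_KINDS:
            raise ValueError(f"{self.name}: unknown response_kind {self.response_kind!r}")
        if not (
            self.requires_att
            or self.em_required > 0
            or self.requires_vf
            or self.requires_cf
            or self.requires_ps
        ):
            raise ValueError(f"{self.name}: a test must require at least one function")

    @property
    def required_functions(self) -> frozenset[str]:
        """Required functions on the 7-indicator expansion (EM as EM1..EMk)."""
        req = set()
        if self.requires_att:
            req.add("ATT")
        for j in range(1, self.em_required + 1):
            req.add(f"EM{j}")
        if self.requires_vf:
            req.add("VF")
        if self.requires_cf:
            req.add("CF")
        if self.requires_ps:
            req.add("PS")
        return frozenset(req)


@dataclass(frozen=True)
class BatterySpec:
    """An ordered panel of tests over a common function domain.

    The list order is the canonical index order for ideal-response
    vectors throughout the package.
    """

    tests: tuple[TestSpec, ...]
    domain: FunctionDomain = FULL_DOMAIN
    name: str = "battery"

    def __post_init__(self) -> None:
        if not self.tests:
            raise ValueError(
                "battery must contain at least one test (a zero-test battery "
                "collapses all profiles into one indistinguishable class)"
            )
        names = [t.name for t in self.tests]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate test names: {dupes}")

    def __len__(self) -> int:
        return len(self.tests)

    @property
    def test_names(self) -> list[str]:
        return [t.name for t in self.tests]

    def __iter__(self) -> Iterable[TestSpec]:
        return iter(self.tests)


class BatterySpecError(ValueError):
    """Raised for malformed battery specification files."""


_FLAG_KEYS = {"ATT": "requires_att", "VF": "requires_vf",
              "CF": "requires_cf", "PS": "requires_ps"}


def _parse_test(entry: dict, pos: int) -> TestSpec:
    if not isinstance(entry, dict) or "name" not in entry:
        raise BatterySpecError(f"test entry #{pos}: missing 'name'")
    name = str(entry["name"])
    requires = entry.get("requires", [])
    if not isinstance(requires, (list, tuple)):
        raise BatterySpecError(f"test {name!r}: 'requires' must be a list")
    kwargs = {}
    em_levels = set()
    for fn in requires:
        fn = str(fn).upper()
        if fn in _FLAG_KEYS:
            kwargs[_FLAG_KEYS[fn]] = True
        elif fn in ("EM1", "EM2", "EM3"):
            em_levels.add(int(fn[2]))
        else:
            raise BatterySpecError(f"test {name!r}: unknown function {fn!r}")
    if em_levels:
        k = max(em_levels)
        # hierarchy: requiring level k entails requiring every level below it
        if em_levels != set(range(1, k + 1)):
            raise BatterySpecError(
                f"test {name!r}: episodic-memory requirement must be contiguous "
                f"from EM1 (got {sorted(f'EM{j}' for j in em_levels)})"
            )
        kwargs["em_required"] = k
    try:
        return TestSpec(
            name=name,
            response_kind=entry.get("response_kind", "categorical-quartile"),
            orientation=entry.get("orientation", "higher-is-better"),
            **kwargs,
        )
    except ValueError as exc:
        raise BatterySpecError(str(exc)) from exc


def parse_battery_spec(source: str | Path | dict) -> BatterySpec:
    """Parse a battery specification from a YAML/JSON file or mapping.

    Schema::

        name: ADNI2
        tests:
          - name: ADAS delayed recall
            requires: [ATT, EM1, EM2, EM3]
            orientation: lower-is-better        # optional
            response_kind: categorical-quartile # optional

    Episodic-memory requirements must be contiguous from EM1 (a test
    demanding EM2 necessarily demands EM1); non-contiguous lists are
    rejected.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    else:
        data = source
    if not isinstance(data, dict) or "tests" not in data:
        raise BatterySpecError("battery spec must be a mapping with a 'tests' list")
    tests = tuple(_parse_test(e, i) for i, e in enumerate(data["tests"], start=1))
    if not tests:
        raise BatterySpecError("battery must contain at least one test")
    return BatterySpec(tests=tests, name=str(data.get("name", "battery")))


def _load_bundled(stem: str) -> BatterySpec:
    ref = resources.files("cogposet").joinpath(f"data/batteries/{stem}.yaml")
    return parse_battery_spec(yaml.safe_load(ref.read_text()))


def adni2_battery() -> BatterySpec:
    """The bundled 9-test ADNI2 panel."""
    return _load_bundled("adni2")


def aibl_battery() -> BatterySpec:
    """The bundled 13-test AIBL panel."""
    return _load_bundled("aibl")
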