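"""Declarative band tables for early-warning-score systems.

An early-warning score (EWS) maps each vital parameter to a subscore in
{0, 1, 2, 3} through an ordered list of value bands, plus categorical maps
for non-numeric items (level of consciousness).  Scoring tables are *data*,
not code: each system ships as a YAML file (``news.yaml``, ``gews.yaml``
bundled under :mod:`ewsval.data`) so that a disputed band placement is a
one-line config edit.

Band semantics
--------------
A band is an interval with explicit bound closedness.  Validation enforces
that, per parameter, bands are pairwise disjoint and jointly cover a dense
grid over the physiologic domain at the parameter's stated resolution.
Values falling in a *printed gap* between bands (possible only off-grid,
e.g. a respiration rate of 23.5 between the 12-23 and 24-27 bands) are
assigned to the band below in the default lenient mode; ``strict=True``
raises :class:`BandCoverageError` instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Band",
    "ParameterBands",
    "CategoricalMap",
    "BandTable",
    "BandTableError",
    "BandCoverageError",
    "ValidationError",
    "load_band_table",
    "bundled_table_names",
]


class BandTableError(Exception):
    """A band-table definition is internally inconsistent."""


class BandCoverageError(BandTableError):
    """A value falls outside every band of a parameter."""


class ValidationError(ValueError):
    """An input value violates the observation schema."""


@dataclass(frozen=True)
class Band:
    """One scoring interval: ``lower``/``upper`` bounds with closedness flags."""

    lower: float
    upper: float
    lower_closed: bool
    upper_closed: bool
    score: int

    def contains(self, value: float) -> bool:
        lo_ok = value > self.lower or (self.lower_closed and value == self.lower)
        hi_ok = value < self.upper or (self.upper_closed and value == self.upper)
        return lo_ok and hi_ok

    def __str__(self) -> str:  # pragma: no cover - repr aid
        lo = "[" if self.lower_closed else "("
        hi = "]" if self.upper_closed else ")"
        return f"{lo}{self.lower}, {self.upper}{hi} -> {self.score}"


@dataclass
class ParameterBands:
    """Ordered, disjoint, covering bands for one numeric parameter."""

    name: str
    bands: list[Band]
    domain: tuple[float, float]
    resolution: float
    unit: str = ""
    # effective start of each band on the real line; gaps between a band's
    # upper bound and the next band's start belong to the lower band
    _starts: np.ndarray = field(init=False, repr=False)
    _scores: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.bands = sorted(self.bands, key=lambda b: (b.lower, not b.lower_closed))
        starts = []
        for b in self.bands:
            s = b.lower if b.lower_closed else np.nextafter(b.lower, math.inf)
            starts.append(s)
        self._starts = np.asarray(starts, dtype=float)
        self._scores = np.asarray([b.score for b in self.bands], dtype=float)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not self.bands:
            raise BandTableError(f"{self.name}: no bands defined")
        for b in self.bands:
            if b.score not in (0, 1, 2, 3):
                raise BandTableError(f"{self.name}: subscore {b.score} outside 0-3")
            if b.lower > b.upper:
                raise BandTableError(f"{self.name}: inverted band {b}")
        # pairwise disjoint: check each adjacent pair on the sorted order
        for a, b in zip(self.bands, self.bands[1:]):
            if a.upper > b.lower or (
                a.upper == b.lower and a.upper_closed and b.lower_closed
            ):
                raise BandTableError(
                    f"{self.name}: overlapping bands {a} and {b}"
                )
        # joint coverage of the domain grid at stated resolution
        lo, hi = self.domain
        n = int(round((hi - lo) / self.resolution))
        grid = lo + self.resolution * np.arange(n + 1)
        grid = np.round(grid, 10)
        for v in grid:
            if not any(b.contains(v) for b in self.bands):
                raise BandTableError(
                    f"{self.name}: grid value {v} not covered by any band"
                )

    # -- scoring ---------------------------------------------------------
    def score(self, value: float, strict: bool = False) -> int:
        """Subscore of ``value``; gaps resolved downward unless ``strict``."""
        idx = int(np.searchsorted(self._starts, value, side="right")) - 1
        if idx < 0:
            raise BandCoverageError(
                f"{self.name}: value {value} below every band"
            )
        band = self.bands[idx]
        if strict and not band.contains(value):
            raise BandCoverageError(
                f"{self.name}: value {value} falls in a printed gap"
            )
        return band.score

    def score_array(self, values: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`score` (lenient); NaN maps to NaN."""
        values = np.asarray(values, dtype=float)
        out = np.full(values.shape, np.nan)
        mask = ~np.isnan(values)
        if mask.any():
            v = values[mask]
            idx = np.searchsorted(self._starts, v, side="right") - 1
            if (idx < 0).any():
                bad = v[idx < 0]
                raise BandCoverageError(
                    f"{self.name}: values below every band: {bad[:5]}"
                )
            out[mask] = self._scores[idx]
        return out


@dataclass
class CategoricalMap:
    """Category -> subscore map for a non-numeric parameter."""

    name: str
    mapping: dict[str, int]

    def __post_init__(self) -> None:
        for k, v in self.mapping.items():
            if v not in (0, 1, 2, 3):
                raise BandTableError(f"{self.name}: subscore {v} outside 0-3")

    def score(self, value: str) -> int:
        try:
            return self.mapping[value]
        except KeyError:
            raise ValidationError(
                f"{self.name}: unknown category {value!r}; "
                f"expected one of {sorted(self.mapping)}"
            ) from None

    def score_array(self, values) -> np.ndarray:
        import pandas as pd

        s = pd.Series(values, dtype=object)
        present = s.notna()
        unknown = present & ~s.isin(list(self.mapping))
        if unknown.any():
            bad = sorted(set(s[unknown]))
            raise ValidationError(
                f"{self.name}: unknown categories {bad}; "
                f"expected one of {sorted(self.mapping)}"
            )
        return s.map(self.mapping).to_numpy(dtype=float)


@dataclass
class BandTable:
    """A complete EWS definition: one band set or categorical map per item."""

    name: str
    numeric: dict[str, ParameterBands]
    categorical: dict[str, CategoricalMap]
    max_total: int

    @property
    def parameters(self) -> list[str]:
        return list(self.numeric) + list(self.categorical)

    def score_value(self, parameter: str, value, strict: bool = False) -> int:
        if parameter in self.numeric:
            return self.numeric[parameter].score(value, strict=strict)
        if parameter in self.categorical:
            return self.categorical[parameter].score(value)
        raise KeyError(f"{self.name}: unknown parameter {parameter!r}")


def _parse_band(raw: Mapping, ctx: str) -> Band:
    return Band(
        lower=float(raw.get("min", -math.inf)),
        upper=float(raw.get("max", math.inf)),
        lower_closed=bool(raw.get("min_closed", True)),
        upper_closed=bool(raw.get("max_closed", True)),
        score=int(raw["score"]),
    )


def _parse_table(doc: Mapping) -> BandTable:
    numeric: dict[str, ParameterBands] = {}
    categorical: dict[str, CategoricalMap] = {}
    for pname, pdef in doc["parameters"].items():
        kind = pdef.get("kind", "numeric")
        if kind == "numeric":
            bands = [_parse_band(b, pname) for b in pdef["bands"]]
            numeric[pname] = ParameterBands(
                name=pname,
                bands=bands,
                domain=tuple(pdef["domain"]),
                resolution=float(pdef.get("resolution", 1)),
                unit=str(pdef.get("unit", "")),
            )
        elif kind == "categorical":
            categorical[pname] = CategoricalMap(pname, dict(pdef["map"]))
        else:
            raise BandTableError(f"{pname}: unknown kind {kind!r}")
    return BandTable(
        name=str(doc["name"]),
        numeric=numeric,
        categorical=categorical,
        max_total=int(doc.get("max_total", 3 * len(doc["parameters"]))),
    )


def bundled_table_names() -> list[str]:
    base = resources.files("ewsval") / "data"
    return sorted(p.name[:-5] for p in base.iterdir() if p.name.endswith(".yaml"))


def load_band_table(name_or_path: str | Path) -> BandTable:
    """Load a band table by bundled name (``"news"``, ``"gews"``) or file path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        res = resources.files("ewsval") / "data" / f"{name_or_path}.yaml"
        try:
            text = res.read_text()
        except FileNotFoundError:
            raise FileNotFoundError(
                f"no bundled band table {name_or_path!r} "
                f"(have {bundled_table_names()}) and no such file"
            ) from None
    return _parse_table(yaml.safe_load(text))
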