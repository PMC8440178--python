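"""Per-disorder effect-size profiles and their tabular I/O.

An :class:`EffectSizeProfile` holds one disorder's covariate-adjusted
Cohen's d values (case minus control, pooled-SD units) over the registry's
brain phenotypes, together with the case/control counts of the source
case-control studies, carried per measure type because cortical thickness,
surface area and subcortical volume typically come from different subsets
of sites. Missing phenotypes are simply absent from the mapping — e.g. an
epilepsy profile with no surface-area measures has 41 of 75 phenotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .registry import (
    MEASURES,
    PhenotypeKey,
    PhenotypeRegistry,
    canonical_region,
    default_registry,
)

__all__ = [
    "EffectSizeProfile",
    "DisorderPanel",
    "AlignedPair",
    "load_effect_table",
    "write_effect_table",
    "intersect_phenotypes",
    "ValidationError",
    "ParseError",
]

#: Sanity bound on |d|; published case-control SMDs for brain structure are
#: an order of magnitude smaller.
MAX_ABS_D = 5.0

EFFECT_TABLE_COLUMNS = ("disorder", "region", "measure", "d", "n_cases", "n_controls")


class ValidationError(ValueError):
    """Input violates a profile/panel invariant."""


class ParseError(ValueError):
    """Malformed effect-size table row; message names the offending line."""


@dataclass
class EffectSizeProfile:
    """One disorder's Cohen's d values over brain phenotypes.

    Parameters
    ----------
    disorder
        Short identifier, e.g. ``"SCZ"``.
    values
        Mapping from :class:`PhenotypeKey` to Cohen's d. Phenotypes absent
        from the mapping are treated as missing for this disorder.
    n_cases, n_controls
        Participant counts per measure type (``{"thickness": 4474, ...}``);
        optional, required only for heterogeneity (Cochran's Q) analyses.
    """

    disorder: str
    values: dict[PhenotypeKey, float]
    n_cases: dict[str, int] = field(default_factory=dict)
    n_controls: dict[str, int] = field(default_factory=dict)
    provenance: str = ""
    registry: PhenotypeRegistry = field(default_factory=default_registry, repr=False)

    def __post_init__(self) -> None:
        if not self.disorder:
            raise ValidationError("disorder identifier must be non-empty")
        for key, d in self.values.items():
            self.registry.validate(key)
            if not math.isfinite(d):
                raise ValidationError(f"{self.disorder} {key}: non-finite d")
            if abs(d) >= MAX_ABS_D:
                raise ValidationError(
                    f"{self.disorder} {key}: |d|={abs(d):.3g} exceeds sanity bound {MAX_ABS_D}"
                )
        for counts, label in ((self.n_cases, "n_cases"), (self.n_controls, "n_controls")):
            for measure, n in counts.items():
                if measure not in MEASURES:
                    raise ValidationError(f"{self.disorder}: unknown measure {measure!r} in {label}")
                if n < 2:
                    raise ValidationError(f"{self.disorder}: {label}[{measure}]={n} < 2")

    @property
    def phenotypes(self) -> tuple[PhenotypeKey, ...]:
        """Present phenotypes, in registry order."""
        return tuple(k for k in self.registry.phenotypes if k in self.values)

    @property
    def n_phenotypes(self) -> int:
        return len(self.values)

    def vector(self) -> np.ndarray:
        """d values for the present phenotypes, in registry order."""
        return np.array([self.values[k] for k in self.phenotypes], dtype=float)

    def counts_for(self, key: PhenotypeKey) -> tuple[int, int] | None:
        """(n_cases, n_controls) for *key*'s measure type, or None if unknown."""
        n1 = self.n_cases.get(key.measure)
        n2 = self.n_controls.get(key.measure)
        if n1 is None or n2 is None:
            return None
        return n1, n2


@dataclass
class DisorderPanel:
    """An ordered collection of effect-size profiles, one per disorder."""

    profiles: tuple[EffectSizeProfile, ...]

    def __post_init__(self) -> None:
        self.profiles = tuple(self.profiles)
        if len(self.profiles) < 2:
            raise ValidationError("panel needs >= 2 disorders")
        names = [p.disorder for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate disorder identifiers: {names}")

    @property
    def disorders(self) -> tuple[str, ...]:
        return tuple(p.disorder for p in self.profiles)

    @property
    def registry(self) -> PhenotypeRegistry:
        return self.profiles[0].registry

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, disorder: str) -> EffectSizeProfile:
        for p in self.profiles:
            if p.disorder == disorder:
                return p
        raise KeyError(disorder)

    def pairs(self) -> list[tuple[str, str]]:
        """All D*(D-1)/2 unordered disorder pairs, in panel order."""
        names = self.disorders
        return [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]


class AlignedPair(NamedTuple):
    """Two disorders' d values over their shared phenotypes, registry-ordered."""

    x: np.ndarray
    y: np.ndarray
    phenotypes: tuple[PhenotypeKey, ...]

    @property
    def n_overlap(self) -> int:
        return len(self.phenotypes)

    @property
    def df(self) -> int:
        """Degrees of freedom of a correlation over the overlap: n - 2."""
        return self.n_overlap - 2


def intersect_phenotypes(a: EffectSizeProfile, b: EffectSizeProfile) -> AlignedPair:
    """Pair up d values over the phenotypes present in both profiles.

    The overlap is ordered by the registry, so the pairing is deterministic
    and symmetric up to swapping components. Raises if fewer than 3
    phenotypes are shared (a correlation would be undefined).
    """
    shared = tuple(k for k in a.registry.phenotypes if k in a.values and k in b.values)
    if len(shared) < 3:
        raise ValidationError(
            f"{a.disorder} and {b.disorder} share only {len(shared)} phenotypes (< 3)"
        )
    x = np.array([a.values[k] for k in shared], dtype=float)
    y = np.array([b.values[k] for k in shared], dtype=float)
    return AlignedPair(x=x, y=y, phenotypes=shared)


def load_effect_table(
    path: str | Path, registry: PhenotypeRegistry | None = None
) -> DisorderPanel:
    """Read a tab-separated effect-size table into a validated panel.

    Expected header: ``disorder region measure d`` plus optional ``n_cases``
    and ``n_controls`` (blank where unknown). Unknown region/measure
    combinations and duplicate (disorder, phenotype) rows are rejected.
    """
    registry = registry or default_registry()
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty effect-size table") from None
    required = {"disorder", "region", "measure", "d"}
    if missing := required - set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"{path}: no data rows")

    values: dict[str, dict[PhenotypeKey, float]] = {}
    counts: dict[str, dict[str, dict[str, int]]] = {}
    order: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        disorder = row.disorder.strip()
        key = PhenotypeKey(canonical_region(row.region), row.measure.strip())
        registry.validate(key)
        try:
            d = float(row.d)
        except ValueError:
            raise ParseError(f"{path}:{i}: unparseable d value {row.d!r}") from None
        if disorder not in values:
            values[disorder] = {}
            counts[disorder] = {"n_cases": {}, "n_controls": {}}
            order.append(disorder)
        if key in values[disorder]:
            raise ValidationError(f"{path}:{i}: duplicate row for ({disorder}, {key})")
        values[disorder][key] = d
        for col in ("n_cases", "n_controls"):
            raw = getattr(row, col, "")
            if raw != "":
                try:
                    n = int(raw)
                except ValueError:
                    raise ParseError(f"{path}:{i}: unparseable {col} {raw!r}") from None
                prev = counts[disorder][col].get(key.measure)
                if prev is not None and prev != n:
                    raise ValidationError(
                        f"{path}:{i}: conflicting {col} for {disorder}/{key.measure}"
                    )
                counts[disorder][col][key.measure] = n

    profiles = [
        EffectSizeProfile(
            disorder=name,
            values=values[name],
            n_cases=counts[name]["n_cases"],
            n_controls=counts[name]["n_controls"],
            provenance=str(path),
            registry=registry,
        )
        for name in order
    ]
    return DisorderPanel(profiles=tuple(profiles))


def write_effect_table(panel: DisorderPanel, path: str | Path) -> None:
    """Write a panel back to TSV; d at full precision so load/write round-trips."""
    rows = []
    for p in panel.profiles:
        for key in p.phenotypes:
            n1 = p.n_cases.get(key.measure)
            n2 = p.n_controls.get(key.measure)
            rows.append(
                {
                    "disorder": p.disorder,
                    "region": key.region,
                    "measure": key.measure,
                    "d": np.format_float_positional(p.values[key], trim="0", unique=True),
                    "n_cases": "" if n1 is None else str(n1),
                    "n_controls": "" if n2 is None else str(n2),
                }
            )
    pd.DataFrame(rows, columns=list(EFFECT_TABLE_COLUMNS)).to_csv(path, sep="\t", index=False)
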