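"""Brain-phenotype registry: named regions crossed with MRI measure types.

A *phenotype* is a (region, measure) pair — e.g. cortical thickness of the
insula, or the volume of the hippocampus. The default registry is the
Desikan–Killiany cortical parcellation (34 regions, hemispheres averaged)
plus 7 subcortical structures, giving 34x2 cortical phenotypes (thickness
and surface area) + 7 subcortical volumes = 75 phenotypes over 41 regions.
Custom atlases can be swapped in from a two-column TSV (region, class).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "THICKNESS",
    "SURFACE_AREA",
    "SUBCORTICAL_VOLUME",
    "MEASURES",
    "PhenotypeKey",
    "PhenotypeRegistry",
    "default_registry",
    "canonical_region",
]

THICKNESS = "thickness"
SURFACE_AREA = "surface_area"
SUBCORTICAL_VOLUME = "subcortical_volume"
#: Measures applicable to cortical regions vs subcortical structures.
CORTICAL_MEASURES = (THICKNESS, SURFACE_AREA)
MEASURES = (THICKNESS, SURFACE_AREA, SUBCORTICAL_VOLUME)


class RegistryError(ValueError):
    """A region/measure combination not admitted by the registry."""


def canonical_region(name: str) -> str:
    """Canonicalize a region label: lower-case, spaces/dashes to underscores."""
    return name.strip().lower().replace(" ", "_").replace("-", "_")


@dataclass(frozen=True, order=True)
class PhenotypeKey:
    """One brain phenotype: an anatomical region paired with a measure type."""

    region: str
    measure: str

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise RegistryError(
                f"unknown measure {self.measure!r}; expected one of {MEASURES}"
            )

    def __str__(self) -> str:  # used in output tables
        return f"{self.region}:{self.measure}"


class PhenotypeRegistry:
    """Fixed ordered set of admissible brain phenotypes.

    Ordering is measure-major: all cortical thicknesses, then all surface
    areas, then subcortical volumes — each block in the registry's region
    order. Every downstream alignment (profile intersection, permutation)
    uses this order, so it is part of the package's determinism contract.
    """

    def __init__(self, cortical: list[str], subcortical: list[str]):
        cortical = [canonical_region(r) for r in cortical]
        subcortical = [canonical_region(r) for r in subcortical]
        overlap = set(cortical) & set(subcortical)
        if overlap:
            raise RegistryError(f"regions in both classes: {sorted(overlap)}")
        if len(set(cortical)) != len(cortical) or len(set(subcortical)) != len(subcortical):
            raise RegistryError("duplicate region names in registry")
        self.cortical = tuple(cortical)
        self.subcortical = tuple(subcortical)
        phen: list[PhenotypeKey] = []
        for measure in CORTICAL_MEASURES:
            phen.extend(PhenotypeKey(r, measure) for r in self.cortical)
        phen.extend(PhenotypeKey(r, SUBCORTICAL_VOLUME) for r in self.subcortical)
        self._phenotypes = tuple(phen)
        self._index = {k: i for i, k in enumerate(self._phenotypes)}

    @property
    def regions(self) -> tuple[str, ...]:
        return self.cortical + self.subcortical

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def phenotypes(self) -> tuple[PhenotypeKey, ...]:
        return self._phenotypes

    @property
    def n_phenotypes(self) -> int:
        return len(self._phenotypes)

    def __contains__(self, key: PhenotypeKey) -> bool:
        return key in self._index

    def index(self, key: PhenotypeKey) -> int:
        try:
            return self._index[key]
        except KeyError:
            raise RegistryError(f"phenotype {key} not in registry") from None

    def validate(self, key: PhenotypeKey) -> PhenotypeKey:
        """Return *key* if admissible, else raise :class:`RegistryError`.

        Cortical regions admit thickness and surface area only; subcortical
        structures admit volume only.
        """
        if key not in self._index:
            if key.region in self.cortical and key.measure == SUBCORTICAL_VOLUME:
                raise RegistryError(
                    f"{key.region} is cortical; measure {key.measure!r} not admissible"
                )
            if key.region in self.subcortical and key.measure != SUBCORTICAL_VOLUME:
                raise RegistryError(
                    f"{key.region} is subcortical; measure {key.measure!r} not admissible"
                )
            raise RegistryError(f"unknown region {key.region!r}")
        return key

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeRegistry":
        """Load a registry from a TSV with columns ``region`` and ``class``."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"region", "class"} - set(df.columns)
        if missing:
            raise RegistryError(f"registry file lacks columns: {sorted(missing)}")
        bad = set(df["class"]) - {"cortical", "subcortical"}
        if bad:
            raise RegistryError(f"unknown region classes: {sorted(bad)}")
        return cls(
            cortical=df.loc[df["class"] == "cortical", "region"].tolist(),
            subcortical=df.loc[df["class"] == "subcortical", "region"].tolist(),
        )


def default_registry() -> PhenotypeRegistry:
    """The packaged Desikan–Killiany + subcortical registry (41 regions)."""
    ref = resources.files("neuroconcord.data").joinpath("dk_registry.tsv")
    with resources.as_file(ref) as path:
        return PhenotypeRegistry.from_tsv(path)
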