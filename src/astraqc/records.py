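"""Domain types for the Radix Astragali quality-evaluation pipeline.

A :class:`SampleRecord` is one dried root sample: provenance metadata
(species, region, growth years, cultivation class) plus the measured
contents of the seven sweetness-relevant components, stored internally
on the canonical mg/g scale. An :class:`IndicatorPanel` carries the four
pharmacopoeia quality-control indicator values for the same sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

from .units import Unit

#: The two source species: A. membranaceus var. mongholicus (MG) and
#: A. membranaceus (Fisch.) Bge. (MJ).
SPECIES = ("MG", "MJ")

#: Producing regions: Shanxi, Shaanxi, Gansu, Inner Mongolia, Heilongjiang.
REGIONS = ("Sx", "Ssx", "Gs", "Nm", "Hlj")

#: Cultivation classes: fast-growing (1-2 y) vs perennial (>=5 y).
CULTIVATIONS = ("FA", "PA")

#: The seven sweetness components, mapped to the unit their assay reports.
#: Trace sugars and alditols come off the GC-MS in μg/g; sucrose and
#: betaine are abundant enough to be quoted in mg/g.
COMPONENT_UNITS: dict[str, Unit] = {
    "glucose": Unit.UG_PER_G,
    "fructose": Unit.UG_PER_G,
    "inositol": Unit.UG_PER_G,
    "sorbitol": Unit.UG_PER_G,
    "dulcitol": Unit.UG_PER_G,
    "sucrose": Unit.MG_PER_G,
    "betaine": Unit.MG_PER_G,
}

COMPONENTS: tuple[str, ...] = tuple(COMPONENT_UNITS)

#: The four pharmacopoeia quality-control indicators with declared units.
INDICATOR_UNITS: dict[str, Unit] = {
    "calycosin_glucoside": Unit.MG_PER_G,
    "astragaloside_iv": Unit.MG_PER_G,
    "polysaccharides": Unit.G_PER_G,
    "extracts": Unit.G_PER_G,
}

INDICATORS: tuple[str, ...] = tuple(INDICATOR_UNITS)

#: Default relative-sweetness weights T_i: sweetness of each compound at
#: equal concentration relative to a 10% sucrose solution (sucrose = 1.0).
DEFAULT_RELATIVE_SWEETNESS: dict[str, float] = {
    "glucose": 0.75,
    "fructose": 1.7,
    "inositol": 0.5,
    "sorbitol": 0.55,
    "dulcitol": 0.3,
    "sucrose": 1.0,
    "betaine": 0.5,
}


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class SchemaError(ValueError):
    """An input table does not match the registered column schema."""


@dataclass(frozen=True)
class SampleRecord:
    """One root sample: metadata plus component contents in canonical mg/g.

    Parameters
    ----------
    sample_id : str
        Unique identifier; preserved verbatim through all stages.
    species : {"MG", "MJ"}
    region : {"Sx", "Ssx", "Gs", "Nm", "Hlj"}
    growth_years : int
        Age of the root at harvest, in years (> 0).
    cultivation : {"FA", "PA"}
        Fast-growing roots are harvested at <= 2 years, perennial ones
        at >= 5 years; the pairing is validated.
    contents : mapping
        Component name -> content in mg/g (canonical unit). Only
        registered component names are accepted here; use ``extra`` for
        pass-through assay columns.
    extra : mapping
        Unregistered columns carried through untouched and excluded
        from all computations.
    """

    sample_id: str
    species: str
    region: str
    growth_years: int
    cultivation: str
    contents: Mapping[str, float]
    extra: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown species {self.species!r}"
            )
        if self.region not in REGIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown region {self.region!r}"
            )
        if self.cultivation not in CULTIVATIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown cultivation {self.cultivation!r}"
            )
        if not (isinstance(self.growth_years, int) and self.growth_years > 0):
            raise ValidationError(
                f"sample {self.sample_id!r}: growth_years must be a positive "
                f"integer, got {self.growth_years!r}"
            )
        if self.cultivation == "FA" and self.growth_years > 2:
            raise ValidationError(
                f"sample {self.sample_id!r}: fast-growing (FA) roots are "
                f"harvested at <= 2 years, got {self.growth_years}"
            )
        if self.cultivation == "PA" and self.growth_years < 5:
            raise ValidationError(
                f"sample {self.sample_id!r}: perennial (PA) roots are "
                f">= 5 years old, got {self.growth_years}"
            )
        for name, value in self.contents.items():
            if name not in COMPONENT_UNITS:
                raise ValidationError(
                    f"sample {self.sample_id!r}: unregistered component {name!r}"
                )
            if not math.isfinite(value) or value < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: content of {name!r} must be "
                    f"a finite non-negative number, got {value!r}"
                )
        object.__setattr__(self, "contents", dict(self.contents))
        object.__setattr__(self, "extra", dict(self.extra))


@dataclass(frozen=True)
class SweetnessReference:
    """Relative-sweetness weight table T_i, with sucrose pinned to 1.0."""

    weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RELATIVE_SWEETNESS)
    )

    def __post_init__(self) -> None:
        w = dict(self.weights)
        if w.get("sucrose") != 1.0:
            raise ValidationError(
                "relative sweetness of sucrose must be exactly 1.0 "
                f"(got {w.get('sucrose')!r}); it is the scale's definition"
            )
        for name, value in w.items():
            if not math.isfinite(value) or value < 0:
                raise ValidationError(
                    f"relative sweetness of {name!r} must be non-negative, "
                    f"got {value!r}"
                )
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class IndicatorPanel:
    """The four pharmacopoeia indicator values for one sample.

    ``calycosin_glucoside`` and ``astragaloside_iv`` in mg/g,
    ``polysaccharides`` and ``extracts`` as g analyte per g dry root.
    """

    sample_id: str
    calycosin_glucoside: float
    astragaloside_iv: float
    polysaccharides: float
    extracts: float

    def __post_init__(self) -> None:
        for name in INDICATORS:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: indicator {name!r} must be "
                    f"a finite non-negative number, got {value!r}"
                )

    def as_vector(self) -> list[float]:
        """Indicator values in canonical order (X1..X4)."""
        return [getattr(self, name) for name in INDICATORS]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean and sample SD of each variable.

    ``sd`` entries are ``None`` when the group has a single member
    (the n-1 sample SD is undefined at n = 1).
    """

    key: Mapping[str, Any]
    n: int
    mean: Mapping[str, float]
    sd: Mapping[str, float | None]


def group_summary(
    samples: Sequence[SampleRecord],
    by: Iterable[str],
    variables: Iterable[str] | None = None,
) -> list[GroupSummary]:
    """Summarise component contents (mean +/- sample SD) per metadata group.

    Parameters
    ----------
    samples : sequence of SampleRecord
    by : iterable of str
        Metadata field names (``species``, ``region``, ``growth_years``,
        ``cultivation``) to partition on.
    variables : iterable of str, optional
        Component names to summarise; defaults to all registered
        components. Values are reported in the canonical mg/g unit.

    Returns
    -------
    list of GroupSummary, in order of first appearance of each key.
    """
    import numpy as np

    samples = list(samples)
    if not samples:
        raise ValueError("group_summary requires a non-empty sample list")
    by = list(by)
    for f in by:
        if f not in ("sample_id", "species", "region", "growth_years", "cultivation"):
            raise ValueError(f"unknown grouping field {f!r}")
    variables = list(variables) if variables is not None else list(COMPONENTS)

    order: list[tuple] = []
    members: dict[tuple, list[SampleRecord]] = {}
    for s in samples:
        key = tuple(getattr(s, f) for f in by)
        if key not in members:
            members[key] = []
            order.append(key)
        members[key].append(s)

    out: list[GroupSummary] = []
    for key in order:
        group = members[key]
        n = len(group)
        mean: dict[str, float] = {}
        sd: dict[str, float | None] = {}
        for var in variables:
            vals = np.array([s.contents.get(var, 0.0) for s in group], dtype=float)
            mean[var] = float(vals.mean())
            sd[var] = float(vals.std(ddof=1)) if n > 1 else None
        out.append(GroupSummary(key=dict(zip(by, key)), n=n, mean=mean, sd=sd))
    return out
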