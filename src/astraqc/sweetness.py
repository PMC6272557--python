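"""Sucrose-equivalent sweetness index.

The sweetness of a root sample is scored as

    S = sum_i T_i * c_i

over the seven measured sweet components (sucrose, glucose, fructose,
inositol, sorbitol, dulcitol, betaine), where T_i is the relative
sweetness of component i against a 10% sucrose solution (sucrose = 1.0)
and c_i its content in mg per g dry root. S is therefore expressed in
mg sucrose-equivalents per g dry root; because all T_i >= 0 and the sum
is linear in the contents, S is non-negative, additive and positively
homogeneous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .records import COMPONENTS, SampleRecord, SweetnessReference

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweetnessResult:
    """Sweetness of one sample plus its per-component breakdown.

    ``sweetness`` equals the sum of ``contributions`` values; both are in
    mg sucrose-equivalent per g dry root.
    """

    sample_id: str
    sweetness: float
    contributions: Mapping[str, float]


def compute_sweetness(
    contents: Mapping[str, float],
    reference: SweetnessReference | None = None,
    sample_id: str = "",
) -> SweetnessResult:
    """Score one content vector (canonical mg/g) against a weight table.

    Components missing from ``contents`` are treated as content 0 with a
    logged warning — an assay may simply have been skipped. A component
    present in ``contents`` but absent from the reference is an error:
    silently dropping a measured component would bias S downward.
    """
    if reference is None:
        reference = SweetnessReference()
    missing_weight = [c for c in contents if c not in reference.weights]
    if missing_weight:
        raise KeyError(
            f"component(s) without a relative-sweetness weight: "
            f"{', '.join(sorted(missing_weight))}"
        )
    contributions: dict[str, float] = {}
    for component in COMPONENTS:
        if component not in reference.weights:
            continue
        if component not in contents:
            logger.warning(
                "sample %r: component %r not measured; treated as 0",
                sample_id,
                component,
            )
        value = contents.get(component, 0.0)
        if value < 0:
            raise ValueError(
                f"sample {sample_id!r}: negative content for {component!r}"
            )
        contributions[component] = reference.weights[component] * value
    return SweetnessResult(
        sample_id=sample_id,
        sweetness=sum(contributions.values()),
        contributions=contributions,
    )


def sweetness_table(
    samples: Sequence[SampleRecord],
    reference: SweetnessReference | None = None,
) -> list[SweetnessResult]:
    """Score every sample; order is preserved, errors carry the sample id."""
    results = []
    for s in samples:
        try:
            results.append(compute_sweetness(s.contents, reference, sample_id=s.sample_id))
        except (KeyError, ValueError) as exc:
            raise type(exc)(f"sample {s.sample_id!r}: {exc}") from exc
    return results


def sweetness_frame(results: Sequence[SweetnessResult]):
    """Tabulate results: sample_id, sweetness_mg_eq_g, one column per component."""
    import pandas as pd

    rows = []
    for r in results:
        row = {"sample_id": r.sample_id, "sweetness_mg_eq_g": r.sweetness}
        row.update({f"contrib_{c}": v for c, v in r.contributions.items()})
        rows.append(row)
    columns = ["sample_id", "sweetness_mg_eq_g"] + [f"contrib_{c}" for c in COMPONENTS]
    return pd.DataFrame(rows, columns=columns)
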