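"""Published summary statistics of the 48-root Radix Astragali survey.

The original study characterised 48 root batches from two species
(A. membranaceus var. mongholicus, MG; A. membranaceus (Fisch.) Bge.,
MJ), five producing regions (Shanxi Sx, Shaanxi Ssx, Gansu Gs, Inner
Mongolia Nm, Heilongjiang Hlj) and growth years from 1 to 7. Only group
means and SDs of the seven sweetness components were published, not the
raw per-sample matrix; those printed summaries are transcribed here,
in the units they were printed in, and serve two purposes:

* worked-example inputs — the sweetness index recomputed from a group's
  printed mean contents should reproduce the printed group-mean
  sweetness (see docs/methods.md for the three rows where it does not);
* generative defaults — :func:`astraqc.synthetic.default_config` draws
  desk-scale cohorts from these means/SDs with the study's group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

#: component order used in the stats tuples below
STAT_COMPONENTS = (
    "glucose",
    "fructose",
    "inositol",
    "sorbitol",
    "dulcitol",
    "sucrose",
    "betaine",
)


@dataclass(frozen=True)
class GroupStats:
    """Printed per-group summary: n, component means/SDs (declared units),
    and the printed group-mean sweetness +/- SD.

    Trace sugars/alditols (glucose, fructose, inositol, sorbitol,
    dulcitol) are in μg/g; sucrose and betaine in mg/g; sweetness in
    mg sucrose-equivalent per g.
    """

    n: int
    means: Mapping[str, float]
    sds: Mapping[str, float]
    sweetness_mean: float
    sweetness_sd: float


def _stats(n, glc, fru, ino, sor, dul, suc, bet, sweet) -> GroupStats:
    means = dict(
        zip(STAT_COMPONENTS, [glc[0], fru[0], ino[0], sor[0], dul[0], suc[0], bet[0]])
    )
    sds = dict(
        zip(STAT_COMPONENTS, [glc[1], fru[1], ino[1], sor[1], dul[1], suc[1], bet[1]])
    )
    return GroupStats(
        n=n, means=means, sds=sds, sweetness_mean=sweet[0], sweetness_sd=sweet[1]
    )


#: Region groups (species MG except Hlj = MJ).
REGION_STATS: dict[str, GroupStats] = {
    "Sx": _stats(17, (3.4, 1.4), (1.3, 0.9), (75.5, 23.6), (1.5, 0.7), (5.1, 1.2),
                 (17.5, 2.3), (1.4, 0.7), (18.3, 2.2)),
    "Ssx": _stats(7, (1.9, 0.8), (0.7, 0.5), (79.0, 18.9), (1.0, 0.4), (4.3, 0.8),
                  (16.4, 1.8), (1.4, 0.8), (17.1, 1.6)),
    "Gs": _stats(10, (1.0, 0.3), (0.2, 0.1), (79.2, 13.6), (0.8, 0.2), (2.9, 0.8),
                 (12.2, 1.3), (2.8, 0.1), (13.7, 1.3)),
    "Nm": _stats(8, (0.6, 0.3), (0.1, 0.1), (88.4, 14.1), (1.0, 0.6), (2.0, 0.9),
                 (11.8, 0.8), (2.2, 0.9), (13.7, 2.3)),
    "Hlj": _stats(6, (0.9, 0.5), (0.3, 0.2), (49.0, 18.1), (0.6, 0.3), (2.6, 1.1),
                  (12.3, 2.4), (2.2, 1.3), (13.9, 0.8)),
}

#: Growth-year groups.
YEAR_STATS: dict[str, GroupStats] = {
    "1Y": _stats(2, (0.7, 0.4), (0.2, 0.2), (38.1, 7.4), (0.4, 0.2), (1.9, 1.4),
                 (13.1, 0.2), (0.7, 0.1), (13.4, 0.5)),
    "2Y": _stats(18, (0.8, 0.3), (0.2, 0.1), (83.3, 14.3), (0.9, 0.4), (2.5, 0.9),
                 (12.0, 1.1), (1.4, 0.7), (13.7, 1.7)),
    "5Y": _stats(22, (2.4, 1.4), (0.7, 0.4), (69.3, 21.7), (1.2, 0.6), (4.3, 1.3),
                 (16.0, 2.8), (2.5, 1.4), (17.3, 2.1)),
    "7Y": _stats(6, (3.8, 1.2), (2.4, 0.6), (91.0, 19.9), (1.6, 0.7), (5.4, 1.1),
                 (17.1, 0.3), (2.2, 0.3), (18.2, 0.5)),
}

#: Region groups whose printed sweetness is reproduced by the index
#: applied to the printed mean contents (within the 0.1 print-rounding
#: slack); Nm, Hlj and 2Y are internally inconsistent — see methods note.
CONSISTENT_GROUPS: tuple[str, ...] = ("Sx", "Ssx", "Gs", "5Y", "7Y")

#: Published indicator-on-sweetness regressions: slope, intercept,
#: correlation coefficient (signed to match the slope; the extracts
#: association is negative).
PUBLISHED_ASSOCIATIONS: dict[str, tuple[float, float, float]] = {
    "calycosin_glucoside": (0.079, -0.344, 0.659),
    "astragaloside_iv": (0.004, 0.926, 0.412),
    "polysaccharides": (0.007, 0.090, 0.486),
    "extracts": (-0.003, 0.243, -0.183),
}

#: Species by region: Hlj roots are A. membranaceus (Fisch.) Bge.
REGION_SPECIES: dict[str, str] = {
    "Sx": "MG", "Ssx": "MG", "Gs": "MG", "Nm": "MG", "Hlj": "MJ",
}
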