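"""Published component values from the West Virginia insurance-sponsored
weight-management program evaluation (2004-2008 cohort).

These are the printed operational-component values of that evaluation,
usable as a full override set for the index engine: the outcome and
representativeness effect sizes came from analyses of the proprietary
claims database and cannot be recomputed here, so they are carried as
reference inputs rather than derived quantities.
"""

from __future__ import annotations

from .engine import ComponentValues

__all__ = ["PUBLISHED_COMPONENTS", "published_components"]

#: printed component values: participation 1,952 of 32,878 eligible;
#: representativeness effect sizes .073 (sex) and .113 (age); phase-I
#: completion 1,260/1,647 with outcome eta2 .592 and differential .050
#: (sex) / .014 (age); 31 of 352 sites; mean 12.8 of 14 components;
#: phase-II completion 348/762 with outcome .467 and differential .005 /
#: .011; 14 of 18 mature sites continuing.
PUBLISHED_COMPONENTS: dict[str, float] = {
    "ipr": 0.059,
    "dr": (0.073 + 0.113) / 2,
    "icr_phase1": 0.765,
    "outcome_phase1": 0.592,
    "di_phase1": (0.050 + 0.014) / 2,
    "spr": 0.088,
    "cir": 12.8 / 14,
    "icr_phase2": 0.457,
    "outcome_phase2": 0.467,
    "di_phase2": (0.005 + 0.011) / 2,
    "scr": 14 / 18,
    "n_eligible": 32878,
}


def published_components() -> ComponentValues:
    """The published component set as a validated :class:`ComponentValues`."""
    return ComponentValues(**PUBLISHED_COMPONENTS)
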