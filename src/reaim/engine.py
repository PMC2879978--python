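"""RE-AIM index engine.

Eight operational components are combined into the five RE-AIM indices
(reach, effectiveness, adoption, implementation, individual and setting
maintenance) and three composite impacts.  The revised, non-negative
formulas multiply a "positive" effect by the *proportion of positive
effect not explained by differential effects*, ``1 - differential``,
rather than subtracting the differential effect outright:

    R   = IPR * (1 - DR)               * 100
    E   = ICR_I  * O_I  * (1 - DI_I)   * 100
    A   = SPR                          * 100
    I   = CIR                          * 100
    M_I = ICR_II * O_II * (1 - DI_II)  * 100
    M_S = SCR                          * 100

    impact_individual  = R * E / 100
    impact_setting     = A * I / 100
    impact_maintenance = M_I * M_S / 100

Because every component is a proportion or an effect size bounded in
[0, 1], every index lies in [0, 100] — the key property the revision
guarantees (the older convention, positive minus differential, can go
negative; see :func:`legacy_index` for the contrast).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields, replace
from typing import Mapping, Sequence

import numpy as np

from .model import (
    AGE_GROUP_LABELS,
    CohortDataset,
    EligibilityModel,
    N_COMPONENTS,
    Timepoint,
)
from .stats import representativeness_phi2, rm_anova_two_timepoints

__all__ = [
    "ComponentValues",
    "ReaimIndices",
    "estimate_eligible",
    "compute_ipr",
    "aggregate_differential",
    "compute_reach",
    "compute_effectiveness",
    "compute_rate_index",
    "compute_impacts",
    "compute_indices",
    "legacy_index",
    "evaluate",
]


@dataclass(frozen=True)
class ComponentValues:
    """The eight operational components (phase-split where applicable).

    All fields except ``n_eligible`` are proportions or bounded effect
    sizes in [0, 1].
    """

    ipr: float                 # individual participation rate
    dr: float                  # demographic representativeness effect size
    icr_phase1: float          # phase-I individual completion rate
    outcome_phase1: float      # phase-I weight-change effect size (eta^2)
    di_phase1: float           # phase-I differential impact effect size
    spr: float                 # setting participation rate
    cir: float                 # component implementation rate
    icr_phase2: float          # phase-II individual completion rate
    outcome_phase2: float      # phase-II weight-change effect size
    di_phase2: float           # phase-II differential impact effect size
    scr: float                 # setting continuation rate
    n_eligible: float          # eligible-member denominator (> 0)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "n_eligible":
                if not v > 0:
                    raise ValueError("n_eligible must be positive")
            elif not 0 <= v <= 1:
                raise ValueError(f"component {f.name} out of [0, 1]: {v}")


@dataclass(frozen=True)
class ReaimIndices:
    reach: float
    effectiveness: float
    adoption: float
    implementation: float
    maintenance_individual: float
    maintenance_setting: float
    impact_individual: float
    impact_setting: float
    impact_maintenance: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not -1e-9 <= v <= 100 + 1e-9:
                raise ValueError(f"index {f.name} out of [0, 100]: {v}")


def estimate_eligible(model: EligibilityModel) -> float:
    """Eligible members: obese adults plus overweight adults with a
    comorbid condition, ``N * (p_obese + p_overweight * p_comorbid)``."""
    return model.n_adult_members * (
        model.p_obese + model.p_overweight * model.p_comorbid_overweight
    )


def compute_ipr(n_participants: int, n_eligible: float) -> float:
    """Individual participation rate: enrollees over eligible members."""
    if n_participants <= 0:
        raise ValueError("n_participants must be positive")
    if n_eligible <= 0:
        raise ValueError("n_eligible must be positive")
    ipr = n_participants / n_eligible
    if ipr > 1:
        warnings.warn("more participants than eligible members; capping IPR at 1")
        ipr = 1.0
    return ipr


def aggregate_differential(effect_sizes: Sequence[float]) -> float:
    """Unweighted mean of differential effect sizes (e.g. sex and age)."""
    es = np.asarray(effect_sizes, dtype=float)
    if es.size == 0:
        raise ValueError("need at least one effect size")
    if ((es < 0) | (es > 1)).any():
        raise ValueError("effect sizes must lie in [0, 1]")
    return float(es.mean())


def compute_reach(ipr: float, dr: float) -> float:
    """Reach: participation rate discounted by unrepresentativeness."""
    _check_unit(ipr=ipr, dr=dr)
    return ipr * (1.0 - dr) * 100.0


def compute_effectiveness(icr: float, outcome: float, di: float) -> float:
    """Effectiveness (or individual maintenance, with phase-II inputs):
    completion rate x outcome effect size, discounted by differential
    impact."""
    _check_unit(icr=icr, outcome=outcome, di=di)
    return icr * outcome * (1.0 - di) * 100.0


def compute_rate_index(numerator: float, denominator: float) -> float:
    """Simple rate index on the 0-100 scale (adoption, implementation,
    setting maintenance).  The numerator may be fractional — e.g. a mean
    count of implemented components."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError(f"numerator {numerator} outside [0, {denominator}]")
    return numerator / denominator * 100.0


def compute_impacts(indices: ReaimIndices) -> tuple[float, float, float]:
    """Composite impacts: pairwise products of indices divided by 100."""
    return (
        indices.reach * indices.effectiveness / 100.0,
        indices.adoption * indices.implementation / 100.0,
        indices.maintenance_individual * indices.maintenance_setting / 100.0,
    )


def compute_indices(components: ComponentValues) -> ReaimIndices:
    """Derive all five indices and three impacts from the components.

    Base indices are kept at full precision.  Composite impacts combine
    the *reported* (one-decimal) indices, the convention under which the
    published impact values are exactly the products of the printed index
    values — combining full-precision indices can differ in the last
    reported decimal.
    """
    r = compute_reach(components.ipr, components.dr)
    e = compute_effectiveness(components.icr_phase1, components.outcome_phase1,
                              components.di_phase1)
    a = compute_rate_index(components.spr, 1.0)
    i = compute_rate_index(components.cir, 1.0)
    m_i = compute_effectiveness(components.icr_phase2, components.outcome_phase2,
                                components.di_phase2)
    m_s = compute_rate_index(components.scr, 1.0)
    partial = ReaimIndices(r, e, a, i, m_i, m_s, 0.0, 0.0, 0.0)
    reported = ReaimIndices(*(round(v, 1) for v in (r, e, a, i, m_i, m_s)),
                            0.0, 0.0, 0.0)
    ind, set_, maint = compute_impacts(reported)
    return replace(partial, impact_individual=ind, impact_setting=set_,
                   impact_maintenance=maint)


def legacy_index(positive: float, differential: float) -> float:
    """Pre-revision index convention: (positive - differential) * 100.

    Kept for comparison: it subtracts the differential effect outright and
    can therefore go negative, which the revised formulas cannot.
    """
    return (positive - differential) * 100.0


# ---------------------------------------------------------------------------
# full pipeline


def evaluate(
    dataset: CohortDataset,
    overrides: Mapping[str, float] | None = None,
) -> tuple[ComponentValues, ReaimIndices, dict[str, str]]:
    """Compute components and indices from a cohort.

    Components are derived from the data unless ``overrides`` supplies a
    value directly (keys matching :class:`ComponentValues` field names) —
    useful when an effect size comes from an external analysis, e.g. a
    published representativeness value whose comparison-population
    convention differs.  Returns the components, the indices, and a
    provenance map recording for each component whether it was
    ``computed`` or ``supplied``.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - {f.name for f in fields(ComponentValues)}
    if unknown:
        raise ValueError(f"unknown override keys: {sorted(unknown)}")

    computed: dict[str, float] = {}
    provenance: dict[str, str] = {}

    def resolve(name: str, compute) -> float:
        if name in overrides:
            provenance[name] = "supplied"
            return float(overrides[name])
        provenance[name] = "computed"
        value = float(compute())
        computed[name] = value
        return value

    elig = dataset.eligibility
    n_eligible = resolve("n_eligible", lambda: estimate_eligible(elig))
    ipr = resolve("ipr", lambda: compute_ipr(len(dataset.participants), n_eligible))
    dr = resolve("dr", lambda: _representativeness(dataset, n_eligible))

    ph1 = dataset.phase_eligible_participants(1)
    ph2 = dataset.phase_eligible_participants(2)
    icr1 = resolve("icr_phase1",
                   lambda: _completion_rate(ph1, "completed_phase1"))
    icr2 = resolve("icr_phase2",
                   lambda: _completion_rate(ph2, "completed_phase2"))

    o1 = resolve("outcome_phase1",
                 lambda: _outcome_eta2(ph1, Timepoint.END_PHASE1, "completed_phase1"))
    o2 = resolve("outcome_phase2",
                 lambda: _outcome_eta2(ph2, Timepoint.END_PHASE2, "completed_phase2"))
    di1 = resolve("di_phase1",
                  lambda: _differential_eta2(ph1, Timepoint.END_PHASE1,
                                             "completed_phase1"))
    di2 = resolve("di_phase2",
                  lambda: _differential_eta2(ph2, Timepoint.END_PHASE2,
                                             "completed_phase2"))

    spr = resolve("spr", lambda: len(dataset.sites) / dataset.n_potential_sites)
    cir = resolve("cir", lambda: _mean_components(dataset) / N_COMPONENTS)
    scr = resolve("scr", lambda: _continuation_rate(dataset))

    components = ComponentValues(
        ipr=ipr, dr=dr, icr_phase1=icr1, outcome_phase1=o1, di_phase1=di1,
        spr=spr, cir=cir, icr_phase2=icr2, outcome_phase2=o2, di_phase2=di2,
        scr=scr, n_eligible=n_eligible,
    )
    return components, compute_indices(components), provenance


def _completion_rate(eligible, flag: str) -> float:
    if not eligible:
        raise ValueError("no phase-eligible participants")
    return sum(getattr(p, flag) for p in eligible) / len(eligible)


def _paired_weights(participants, endpoint: Timepoint, flag: str):
    """Baseline / end-of-phase weight pairs for completers, pairwise complete."""
    base, follow, sexes, ages = [], [], [], []
    for p in participants:
        if not getattr(p, flag):
            continue
        b = p.measurement(Timepoint.BASELINE).weight_lb
        f = p.measurement(endpoint).weight_lb
        if b is None or f is None:
            continue
        base.append(b)
        follow.append(f)
        sexes.append(p.sex.value)
        ages.append(p.age_group)
    return np.array(base), np.array(follow), sexes, ages


def _outcome_eta2(participants, endpoint: Timepoint, flag: str) -> float:
    base, follow, _, _ = _paired_weights(participants, endpoint, flag)
    return rm_anova_two_timepoints(base, follow).eta2_time


def _differential_eta2(participants, endpoint: Timepoint, flag: str) -> float:
    """Mean of sex-by-time and age-by-time interaction effect sizes, each
    from its own one-factor mixed ANOVA on weight."""
    base, follow, sexes, ages = _paired_weights(participants, endpoint, flag)
    pieces = []
    for labels in (sexes, ages):
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        # groups with a single member cannot contribute a within-group variance
        keep = np.array([counts[lab] >= 2 for lab in labels])
        kept_labels = [lab for lab, k in zip(labels, keep) if k]
        if len(set(kept_labels)) < 2:
            continue
        res = rm_anova_two_timepoints(base[keep], follow[keep], kept_labels)
        pieces.append(res.eta2_interaction)
    if not pieces:
        raise ValueError("no demographic factor with >= 2 usable groups")
    return aggregate_differential(pieces)


def _representativeness(dataset: CohortDataset, n_eligible: float) -> float:
    """Mean of sex and age representativeness effect sizes (convention:
    participant-vs-nonparticipant contingency tables against the eligible
    marginals)."""
    elig = dataset.eligibility
    n_elig = int(round(n_eligible))
    n_f = sum(p.sex.value == "female" for p in dataset.participants)
    n_m = len(dataset.participants) - n_f
    sex_res = representativeness_phi2(
        [n_f, n_m],
        [elig.eligible_sex_split, 1.0 - elig.eligible_sex_split],
        n_elig,
    )
    age_counts = {g: 0 for g in AGE_GROUP_LABELS}
    for p in dataset.participants:
        age_counts[p.age_group] += 1
    enrolled = np.array([age_counts[g] for g in AGE_GROUP_LABELS], dtype=float)
    props = np.array(elig.eligible_age_distribution, dtype=float)
    keep = ~((props == 0) & (enrolled == 0))
    props_kept = props[keep] / props[keep].sum()
    age_res = representativeness_phi2(enrolled[keep], props_kept, n_elig)
    return aggregate_differential([sex_res.phi_c2, age_res.phi_c2])


def _mean_components(dataset: CohortDataset) -> float:
    if not dataset.sites:
        raise ValueError("no site records")
    return float(np.mean([s.n_components for s in dataset.sites]))


def _continuation_rate(dataset: CohortDataset) -> float:
    """Continuing fraction among sites approved >= 1 year before data
    collection (younger sites have not yet faced the continuation choice)."""
    mature = [s for s in dataset.sites
              if (dataset.data_collection_date - s.approval_date).days >= 365]
    if not mature:
        raise ValueError("no sites approved >= 1 year before data collection")
    return sum(s.still_accepting for s in mature) / len(mature)


def _check_unit(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
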