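"""Bounded standardized effect sizes and descriptive summaries.

Two effect sizes feed the evaluation indices, both bounded in [0, 1] so
that index formulas built on them can never go negative:

* squared Cramér phi, ``phi_c2 = chi2 / (n * (min(r, c) - 1))``, from a
  Pearson chi-square test on a contingency table;
* partial eta squared, ``SS_effect / (SS_effect + SS_error)``, from a
  two-timepoint repeated-measures / mixed ANOVA.

With only two timepoints the mixed ANOVA has a closed form in terms of
normalized difference scores ``w_i = (follow-up_i - baseline_i) / sqrt(2)``:
the time effect is the (unweighted) grand mean of ``w``, the group-by-time
interaction is the spread of group means of ``w``, and the within error is
the residual variation of ``w`` around its group means.  Unbalanced groups
use unweighted-means (Type III) sums of squares: group means enter with
equal weight and the effective cell size is the harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "ContingencyResult",
    "RmAnovaResult",
    "DescriptiveSummary",
    "chi_square_phi2",
    "representativeness_phi2",
    "rm_anova_two_timepoints",
    "summarize",
    "DegenerateTableError",
    "InsufficientDataError",
]


class DegenerateTableError(ValueError):
    """Contingency table has an all-zero row or column."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


@dataclass(frozen=True)
class ContingencyResult:
    chi2: float
    df: int
    n: int
    p_value: float
    phi_c2: float
    #: set when the comparison-population construction is a package
    #: convention rather than a uniquely determined table
    convention_dependent: bool = False

    def __post_init__(self) -> None:
        if not -1e-12 <= self.phi_c2 <= 1 + 1e-12:
            raise ValueError(f"phi_c2 out of [0, 1]: {self.phi_c2}")


@dataclass(frozen=True)
class RmAnovaResult:
    ss_time: float
    ss_interaction: float
    ss_within_error: float
    f_time: float
    f_interaction: float
    p_time: float
    p_interaction: float
    eta2_time: float
    eta2_interaction: float
    n_subjects: int
    n_groups: int
    degenerate: bool = False


@dataclass(frozen=True)
class DescriptiveSummary:
    n: int
    central: float
    spread_low: float
    spread_high: float
    style: str  # "median_iqr" or "mean_sd"
    skewness: float

    @property
    def sd(self) -> float:
        """Standard deviation when style is mean_sd (half the spread band)."""
        return (self.spread_high - self.spread_low) / 2.0


def chi_square_phi2(table: Sequence[Sequence[float]]) -> ContingencyResult:
    """Pearson chi-square (no continuity correction) plus squared Cramér phi.

    ``phi_c2`` divides the chi-square statistic by ``n * (min(rows, cols)
    - 1)``, which bounds it in [0, 1]; for a 2x2 table it coincides with
    the classical phi squared, chi2 / n.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError(f"need a table with >=2 rows and columns, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise DegenerateTableError("table has an all-zero row or column")
    n = t.sum()
    if n < 1:
        raise DegenerateTableError("table total must be >= 1")
    chi2, p, df, _ = _st.chi2_contingency(t, correction=False)
    k = min(t.shape) - 1
    phi_c2 = float(chi2) / (n * k)
    return ContingencyResult(
        chi2=float(chi2), df=int(df), n=int(round(n)), p_value=float(p),
        phi_c2=min(float(phi_c2), 1.0),
    )


def representativeness_phi2(
    enrolled_counts: Sequence[float],
    eligible_proportions: Sequence[float],
    n_eligible: int,
) -> ContingencyResult:
    """Effect size for how unrepresentative enrollees are of the eligible pool.

    Builds a participant-vs-nonparticipant by category table: the first row
    holds the enrolled counts; the second row holds the remaining eligible
    members, allocated to categories by the eligible proportions.  The
    result is flagged ``convention_dependent`` because published analyses
    do not uniquely pin down the comparison population; externally supplied
    effect sizes can be used instead when reproducing printed tables.
    """
    enrolled = np.asarray(enrolled_counts, dtype=float)
    props = np.asarray(eligible_proportions, dtype=float)
    if enrolled.shape != props.shape or enrolled.ndim != 1:
        raise ValueError("enrolled_counts and eligible_proportions must be "
                         "1-D and the same length")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("eligible_proportions must sum to 1")
    if enrolled.sum() > n_eligible:
        raise ValueError("enrolled total exceeds the eligible population")
    bad = (props == 0) & (enrolled > 0)
    if bad.any():
        raise ValueError(
            f"categories {np.nonzero(bad)[0].tolist()} have zero eligible "
            "mass but nonzero enrollment"
        )
    eligible_by_cat = props * n_eligible
    nonparticipants = eligible_by_cat - enrolled
    if (nonparticipants < 0).any():
        raise ValueError("enrollment exceeds eligible mass in some category")
    res = chi_square_phi2(np.vstack([enrolled, nonparticipants]))
    return ContingencyResult(
        chi2=res.chi2, df=res.df, n=res.n, p_value=res.p_value,
        phi_c2=res.phi_c2, convention_dependent=True,
    )


def rm_anova_two_timepoints(
    baseline: Sequence[float],
    followup: Sequence[float],
    group_labels: Sequence | None = None,
) -> RmAnovaResult:
    """Two-timepoint repeated-measures ANOVA, optionally with one
    between-subjects factor (mixed design).

    Without groups this reduces to the paired t-test: ``f_time = t**2`` and
    ``eta2_time = t**2 / (t**2 + n - 1)``.  With groups, unweighted-means
    (Type III) sums of squares are used, so strongly unbalanced groups
    (e.g. 993 women vs 267 men) contribute equally through their means.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape or b.ndim != 1:
        raise ValueError("baseline and followup must be 1-D and the same length")
    keep = ~(np.isnan(b) | np.isnan(f))
    b, f = b[keep], f[keep]
    n = b.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")

    w = (f - b) / np.sqrt(2.0)  # normalized within-subject difference contrast

    if group_labels is None:
        groups = [w]
        labels = None
    else:
        lab = np.asarray(group_labels)[keep]
        labels = sorted(set(lab.tolist()), key=str)
        groups = [w[lab == g] for g in labels]
        sizes = [g.size for g in groups]
        if min(sizes) < 2:
            raise InsufficientDataError(
                f"every group needs >= 2 members, got sizes {sizes}"
            )
    g = len(groups)
    means = np.array([grp.mean() for grp in groups])
    n_h = g / np.sum([1.0 / grp.size for grp in groups])  # harmonic mean size
    grand_u = means.mean()  # unweighted grand mean

    ss_time = g * n_h * grand_u**2
    ss_inter = n_h * float(np.sum((means - grand_u) ** 2)) if g > 1 else 0.0
    ss_err = float(sum(np.sum((grp - m) ** 2) for grp, m in zip(groups, means)))
    df_err = n - g

    if ss_time + ss_inter + ss_err == 0.0:
        return RmAnovaResult(
            ss_time=0.0, ss_interaction=0.0, ss_within_error=0.0,
            f_time=0.0, f_interaction=0.0, p_time=1.0, p_interaction=1.0,
            eta2_time=0.0, eta2_interaction=0.0,
            n_subjects=n, n_groups=g, degenerate=True,
        )

    ms_err = ss_err / df_err if df_err > 0 else 0.0
    if ms_err > 0:
        f_time = ss_time / ms_err
        p_time = float(_st.f.sf(f_time, 1, df_err))
        if g > 1:
            f_inter = (ss_inter / (g - 1)) / ms_err
            p_inter = float(_st.f.sf(f_inter, g - 1, df_err))
        else:
            f_inter, p_inter = 0.0, 1.0
    else:  # zero within-group change variance: saturated effects
        f_time = np.inf if ss_time > 0 else 0.0
        p_time = 0.0 if ss_time > 0 else 1.0
        f_inter = np.inf if ss_inter > 0 else 0.0
        p_inter = 0.0 if ss_inter > 0 else 1.0

    eta2_time = ss_time / (ss_time + ss_err) if ss_time + ss_err > 0 else 0.0
    eta2_inter = ss_inter / (ss_inter + ss_err) if ss_inter + ss_err > 0 else 0.0
    return RmAnovaResult(
        ss_time=float(ss_time), ss_interaction=float(ss_inter),
        ss_within_error=ss_err,
        f_time=float(f_time), f_interaction=float(f_inter),
        p_time=p_time, p_interaction=p_inter,
        eta2_time=float(eta2_time), eta2_interaction=float(eta2_inter),
        n_subjects=n, n_groups=g,
    )


def summarize(values: Sequence[float], skew_threshold: float = 1.0) -> DescriptiveSummary:
    """Summarize a measurement as median (IQR) when skewed, else mean (SD).

    Sample skewness uses the adjusted Fisher-Pearson estimator; quartiles
    use linear interpolation between order statistics so fixtures are
    bit-reproducible.  ``|skewness| > skew_threshold`` selects median/IQR.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise InsufficientDataError(f"need >= 2 values, got {x.size}")
    skew = float(_st.skew(x, bias=False)) if x.size >= 3 and np.ptp(x) > 0 else 0.0
    if abs(skew) > skew_threshold:
        q25, med, q75 = np.percentile(x, [25, 50, 75], method="linear")
        return DescriptiveSummary(n=int(x.size), central=float(med),
                                  spread_low=float(q25), spread_high=float(q75),
                                  style="median_iqr", skewness=skew)
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    return DescriptiveSummary(n=int(x.size), central=mean,
                              spread_low=mean - sd, spread_high=mean + sd,
                              style="mean_sd", skewness=skew)
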