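"""Routine statistics and small helpers for condition comparison.

The group comparisons here are deliberately thin wrappers over standard
tests: Shapiro–Wilk normality per group, Student's unpaired two-tailed
t-test against the control, and the conventional star annotation
(* p ≤ 0.05, ** p ≤ 0.01, *** p ≤ 0.001).  No multiple-testing correction
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .imaging_io import ValidationError

__all__ = ["GroupComparison", "compare_conditions", "significance_stars",
           "epinephrine_molarity", "EPINEPHRINE_MOLAR_MASS"]

#: Molar mass of (-)-epinephrine in g/mol.
EPINEPHRINE_MOLAR_MASS = 183.20


@dataclass
class GroupComparison:
    """t-test of one treatment group against the control."""

    label: str
    n: int
    mean: float
    sd: float
    shapiro_p: float | None
    t_statistic: float | None
    p_value: float | None
    stars: str
    skipped: bool = False


def significance_stars(p: float) -> str:
    """Conventional star annotation (thresholds are inclusive)."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compare_conditions(
    control: np.ndarray,
    treatments: dict[str, np.ndarray],
    min_n: int = 3,
) -> list[GroupComparison]:
    """Compare replicate metrics of each treatment group with the control.

    Each group gets a Shapiro–Wilk normality p-value and an unpaired
    two-tailed t-test vs the control.  Groups with fewer than ``min_n``
    replicates are reported but their test is skipped with a warning flag.
    """
    control = np.asarray(control, float)
    if len(treatments) < 1:
        raise ValidationError("need at least one treatment group")
    out = []
    ctrl_ok = control.size >= min_n
    for label, values in treatments.items():
        v = np.asarray(values, float)
        if v.size < min_n or not ctrl_ok:
            out.append(GroupComparison(
                label=label, n=int(v.size), mean=float(v.mean()),
                sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
                shapiro_p=None, t_statistic=None, p_value=None,
                stars="", skipped=True,
            ))
            continue
        sw_p = float(stats.shapiro(v).pvalue) if np.ptp(v) > 0 else 1.0
        if np.allclose(v, v[0]) and np.allclose(control, control[0]) \
                and np.isclose(v[0], control[0]):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(v, control, equal_var=True)
            t_stat, p = float(t_stat), float(p)
            if np.isnan(p):  # identical zero-variance groups
                p, t_stat = 1.0, 0.0
        out.append(GroupComparison(
            label=label, n=int(v.size), mean=float(v.mean()),
            sd=float(v.std(ddof=1)), shapiro_p=sw_p,
            t_statistic=t_stat, p_value=p, stars=significance_stars(p),
        ))
    return out


def epinephrine_molarity(
    dilution_denominator: float,
    molar_mass: float = EPINEPHRINE_MOLAR_MASS,
) -> float:
    """Molar concentration (µM) of a 1 g : D mL epinephrine dilution.

    1 g of compound in D mL of medium gives (1/molar_mass) mol per
    (D/1000) L, i.e. 10⁹ / (D × molar_mass) µM.  A 1:80 000 dilution of
    (-)-epinephrine computes to 68.23 µM.

    Note: the two stock dilutions used for the dose–response work are
    internally inconsistent as labelled — 34.12 µM is exactly half of
    68.23 µM and therefore corresponds to 1:160 000, not the labelled
    1:175 000 (which would give 31.19 µM).  Both readings are obtainable
    from this helper; no downstream computation depends on the choice.
    """
    if dilution_denominator <= 0 or molar_mass <= 0:
        raise ValidationError("dilution and molar mass must be positive")
    return 1e9 / (dilution_denominator * molar_mass)
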