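"""Relative-risk handling: dose–response scaling, age expansion, incidence
calibration, population impact fractions, and Monte Carlo RR draws.

Relative risks act on disease incidence only; any effect on mortality is
realized through the presence of disease.  Incidence is calibrated so that
the observed (reference) exposure distribution reproduces the baseline
incidence exactly — the standard comparative-risk-assessment convention
that keeps the reference scenario consistent with observed epidemiology.
"""

from __future__ import annotations

import logging

import numpy as np

from .data import AGE_MAX, N_AGES, N_SEXES, RelativeRiskTable

__all__ = [
    "category_rr",
    "expand_rr_by_age",
    "calibrate_incidence",
    "population_impact_fraction",
    "draw_rr",
    "draw_rr_table",
    "Z_95",
]

logger = logging.getLogger(__name__)

# two-sided 95% normal quantile used to convert a CI into a lognormal sd
Z_95 = 1.959964


def category_rr(rr_per_unit: float, delta: float, unit: float = 100.0) -> float:
    """RR of a consumption level ``delta`` g/day away from the reference.

    A dose–response estimate ``rr_per_unit`` per ``unit`` g/day scales
    multiplicatively: RR(delta) = rr_per_unit ** (delta / unit), so the
    reference intake itself maps to 1 and RR(a + b) = RR(a) * RR(b).
    """
    if rr_per_unit <= 0:
        raise ValueError("rr_per_unit must be > 0")
    if unit <= 0:
        raise ValueError("unit size must be > 0")
    return float(rr_per_unit ** (delta / unit))


def expand_rr_by_age(
    table: RelativeRiskTable,
    adult_min_age: int = 19,
    rr: np.ndarray | None = None,
) -> np.ndarray:
    """Expand band-level RRs to a piecewise-constant ``(age, sex, category)`` grid.

    Ages below ``adult_min_age`` get RR 1 (diet effects are modeled in
    adults only); ages above the last band carry the last band's value,
    adult ages below the first band carry the first band's.  ``rr``
    optionally substitutes a redrawn array of the table's shape.
    """
    values = table.rr if rr is None else np.asarray(rr, dtype=float)
    if values.shape != table.rr.shape:
        raise ValueError("substitute rr array must match the table shape")
    n_cat = len(table.category_labels)
    out = np.ones((N_AGES, N_SEXES, n_cat))
    band_low = np.array([b[0] for b in table.bands])
    for age in range(adult_min_age, N_AGES):
        b = int(np.clip(np.searchsorted(band_low, age, side="right") - 1, 0, len(table.bands) - 1))
        out[age] = values[:, b, :].T
    return out


def calibrate_incidence(
    baseline_incidence: np.ndarray,
    prevalence: np.ndarray,
    rr: np.ndarray,
) -> np.ndarray:
    """Per-category incidence reproducing baseline incidence in the observed population.

    ``i[c] = i * rr[c] / sum_c p[c] * rr[c]``, so the prevalence-weighted
    mean over categories equals the baseline incidence exactly.  Arrays
    are ``(age, sex)`` for the baseline and ``(age, sex, category)`` for
    prevalence and RR.  Values scaled above 1 are clipped (logged).
    """
    baseline_incidence = np.asarray(baseline_incidence, dtype=float)
    prevalence = np.asarray(prevalence, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("relative risks must be > 0")
    sums = prevalence.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ValueError("category prevalences must sum to 1 per stratum")
    mean_rr = (prevalence * rr).sum(axis=-1, keepdims=True)
    out = baseline_incidence[..., None] * rr / mean_rr
    if np.any(out > 1.0):
        logger.warning(
            "calibrated incidence exceeded 1 in %d cells; clipped", int(np.sum(out > 1.0))
        )
        out = np.minimum(out, 1.0)
    return out


def population_impact_fraction(p_ref: np.ndarray, p_cf: np.ndarray, rr: np.ndarray) -> np.ndarray:
    """PIF = 1 − (Σ p_cf·rr)/(Σ p_ref·rr) along the trailing category axis.

    Equals the first-cycle proportional incidence reduction under the
    calibrated incidence; invariant to rescaling all RRs by a constant.
    """
    p_ref = np.asarray(p_ref, dtype=float)
    p_cf = np.asarray(p_cf, dtype=float)
    rr = np.asarray(rr, dtype=float)
    for name, p in (("p_ref", p_ref), ("p_cf", p_cf)):
        if np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-9):
            raise ValueError(f"{name} must sum to 1 along the category axis")
    return 1.0 - (p_cf * rr).sum(axis=-1) / (p_ref * rr).sum(axis=-1)


def draw_rr(rr: float, ci_low: float, ci_high: float, rng: np.random.Generator) -> float:
    """One lognormal draw of an RR from its 95% confidence interval.

    The draw has median ``rr`` and ln-scale standard deviation
    ``(ln ci_high − ln ci_low) / (2 · 1.959964)``; a degenerate CI returns
    ``rr`` exactly.  Deterministic given the generator state.
    """
    if not 0 < ci_low <= rr <= ci_high:
        raise ValueError(f"need 0 < ci_low <= rr <= ci_high, got ({rr}, {ci_low}, {ci_high})")
    z = rng.standard_normal()
    sd = (np.log(ci_high) - np.log(ci_low)) / (2.0 * Z_95)
    return float(np.exp(np.log(rr) + z * sd))


def draw_rr_table(table: RelativeRiskTable, rng: np.random.Generator) -> np.ndarray:
    """Redraw a whole RR table with one shared lognormal quantile.

    All cells of a table descend from the same dose–response estimate, so
    a single standard-normal deviate ``z`` is applied to every cell:
    ``rr' = rr · exp(z · sd_cell)`` with the cell's own CI-derived sd.
    This preserves the ordering of categories within a replicate; draws
    for different disease endpoints use independent generators.
    """
    z = rng.standard_normal()
    sd = (np.log(table.ci_high) - np.log(table.ci_low)) / (2.0 * Z_95)
    return table.rr * np.exp(z * sd)
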