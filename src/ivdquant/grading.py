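"""Degeneration grading and deviation scoring of measured disc parameters.

Grading uses the modified Pfirrmann scale with the signal-poor grades
collapsed (grades 1, 2, 3, 4 and 5–8), each grade characterised by the mean
μ_g and standard deviation σ_g of ΔSI in a reference cohort.  A disc is
assigned the grade whose σ-normalised distance to its ΔSI is smallest (ties
toward the more severe grade); the pairwise deviation

    Δ_i = |ΔSI − μ_{i+1}|/σ_{i+1} − |ΔSI − μ_i|/σ_i

changes sign at the boundary between grades i and i+1, so the assignment is
equivalent to scanning Δ_i for the sign change.

Population baselines give per (gender, segment, age band) means and SDs of
ΔSI, DHI and HDR, plus the mean healthy DH.  Normalised parameters are
reported as signed deviations β = (x − μ)/σ (more negative = more
degenerate); DH, which is not standardised, is reported as a collapse
percentage relative to the healthy mean.

The tables shipped by :func:`synthetic_criteria` / :func:`synthetic_baseline`
are derived from the synthetic phantom presets and are *not* clinical
values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GradingCriteria",
    "BaselineTable",
    "BaselineLookupError",
    "DiscReport",
    "DegenerationReport",
    "grade_delta",
    "assign_grade",
    "beta_deviation",
    "collapse_percentage",
    "build_report",
    "synthetic_criteria",
    "synthetic_baseline",
    "AGE_BANDS",
]

#: Cohort age bands used as the default baseline schema.
AGE_BANDS = ["20-30", "30-40", "40-50", "50-60", "60-70", "70-90"]

SEGMENTS = ["DISC_L1L2", "DISC_L2L3", "DISC_L3L4", "DISC_L4L5", "DISC_L5S1"]


class BaselineLookupError(KeyError):
    """No baseline row for the requested (gender, segment, age band)."""


@dataclass(frozen=True)
class GradingCriteria:
    """Per-grade (μ, σ) of ΔSI; μ strictly decreasing with grade severity."""

    mu: np.ndarray
    sigma: np.ndarray
    grade_labels: tuple[str, ...] = ("1", "2", "3", "4", "5-8")

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, float))
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 1:
            raise ValueError("mu and sigma must be 1-D of equal length")
        if len(self.mu) < 2:
            raise ValueError("need at least two grades")
        if not (np.diff(self.mu) < 0).all():
            raise ValueError("grade means must be strictly decreasing")
        if not (self.sigma > 0).all():
            raise ValueError("grade SDs must be positive")
        if len(self.grade_labels) != len(self.mu):
            object.__setattr__(self, "grade_labels",
                               tuple(str(g + 1) for g in range(len(self.mu))))

    @property
    def n_grades(self) -> int:
        return len(self.mu)

    @classmethod
    def from_csv(cls, path) -> "GradingCriteria":
        df = pd.read_csv(path)
        df = df.sort_values("grade")
        return cls(df["mu"].to_numpy(), df["sigma"].to_numpy(),
                   tuple(str(g) for g in df["grade"]))

    def to_csv(self, path) -> None:
        pd.DataFrame({"grade": self.grade_labels, "mu": self.mu,
                      "sigma": self.sigma}).to_csv(path, index=False)

    @classmethod
    def from_json(cls, path) -> "GradingCriteria":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(np.asarray(raw["mu"]), np.asarray(raw["sigma"]),
                   tuple(raw.get("grade_labels", ())))


@dataclass
class BaselineTable:
    """Healthy-population baselines keyed by (gender, segment, age_band).

    Columns: mean/SD for each of delta_si, dhi, hdr, plus ``mean_dh`` (the
    healthy average disc height used for the collapse percentage).  Gender
    is coded 0/1.
    """

    table: pd.DataFrame
    fallback: dict | None = None

    REQUIRED = ["gender", "segment", "age_band", "delta_si_mu", "delta_si_sigma",
                "dhi_mu", "dhi_sigma", "hdr_mu", "hdr_sigma", "mean_dh"]

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"baseline table missing columns: {sorted(missing)}")
        sig = [c for c in self.table.columns if c.endswith("_sigma")]
        if (self.table[sig] <= 0).any().any():
            raise ValueError("baseline SDs must be positive")
        for (g, a), grp in self.table.groupby(["gender", "age_band"]):
            if set(SEGMENTS) - set(grp["segment"]):
                raise ValueError(
                    f"baseline incomplete for gender={g}, age_band={a}: "
                    f"all five segments required")

    def row(self, gender: int, segment: str, age_band: str) -> dict:
        m = self.table[(self.table.gender == gender)
                       & (self.table.segment == segment)
                       & (self.table.age_band == age_band)]
        if len(m) == 0:
            if self.fallback is not None:
                return self.fallback
            raise BaselineLookupError(
                f"no baseline row for gender={gender}, segment={segment}, "
                f"age_band={age_band}")
        return m.iloc[0].to_dict()

    @classmethod
    def from_csv(cls, path, fallback: dict | None = None) -> "BaselineTable":
        return cls(pd.read_csv(path), fallback)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def grade_delta(delta_si_value: float, criteria: GradingCriteria, i: int) -> float:
    """Pairwise grade deviation Δ between grades i and i+1 (i is 1-based).

    Positive Δ means ΔSI is closer (σ-normalised) to grade i than to grade
    i+1; Δ changes sign where the assignment flips to the severer grade.
    """
    if not 1 <= i <= criteria.n_grades - 1:
        raise ValueError(f"i must be in 1..{criteria.n_grades - 1}, got {i}")
    mu, sg = criteria.mu, criteria.sigma
    return (abs(delta_si_value - mu[i]) / sg[i]
            - abs(delta_si_value - mu[i - 1]) / sg[i - 1])


def assign_grade(delta_si_value: float, criteria: GradingCriteria) -> int:
    """Grade (1-based) minimising |ΔSI − μ_g|/σ_g; ties go to the severer grade."""
    d = np.abs(delta_si_value - criteria.mu) / criteria.sigma
    # argmin on the reversed array prefers the higher grade among ties
    return int(criteria.n_grades - np.argmin(d[::-1]))


def beta_deviation(x: float, mu: float, sigma: float) -> float:
    """Signed standardised deviation β = (x − μ)/σ from the healthy baseline.

    Smaller (more negative) β means stronger degeneration: lower signal
    contrast or more collapsed geometry than the healthy reference.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return (x - mu) / sigma


def collapse_percentage(dh: float, healthy_mean_dh: float) -> tuple[float, bool]:
    """Height-collapse percentage (1 − DH/healthy mean)×100, floored at 0.

    Returns ``(percent, above_baseline)``; discs taller than the healthy
    mean report 0% with the above-baseline flag set.
    """
    if healthy_mean_dh <= 0:
        raise ValueError("healthy mean DH must be positive")
    pct = (1.0 - dh / healthy_mean_dh) * 100.0
    if pct < 0:
        return 0.0, True
    return float(pct), False


@dataclass
class DiscReport:
    segment: str
    delta_si: float | None
    DH: float | None
    DHI: float | None
    HDR: float | None
    grade: int | None
    grade_label: str | None
    grade_deviation: float | None     # Δ at the assigned boundary
    beta_delta_si: float | None
    beta_dhi: float | None
    beta_hdr: float | None
    collapse_percent: float | None
    flags: list[str] = field(default_factory=list)


@dataclass
class DegenerationReport:
    discs: list[DiscReport]
    subject: dict
    flags: list[str] = field(default_factory=list)


def _age_band(age: float) -> str:
    edges = [(20, 30), (30, 40), (40, 50), (50, 60), (60, 70), (70, 90)]
    for band, (lo, hi) in zip(AGE_BANDS, edges):
        if lo <= age < hi or (hi == 90 and age == 90):
            return band
    raise BaselineLookupError(f"age {age} outside the 20-90 baseline bands")


def build_report(measures, criteria: GradingCriteria,
                 baseline: BaselineTable | None,
                 subject_meta: dict) -> DegenerationReport:
    """Assemble the per-disc degeneration report.

    ``measures`` is the :class:`~ivdquant.geometry.SpineMeasurements` of one
    subject; ``subject_meta`` must carry ``gender`` (0/1) and either
    ``age_band`` or ``age`` when a baseline is supplied.
    """
    gender = subject_meta.get("gender")
    band = subject_meta.get("age_band")
    if baseline is not None:
        if gender not in (0, 1):
            raise BaselineLookupError(
                f"subject gender must be 0 or 1, got {gender!r}")
        if band is None:
            band = _age_band(float(subject_meta["age"]))
    reports = []
    for seg in SEGMENTS:
        m = measures.discs.get(seg)
        if m is None:
            reports.append(DiscReport(seg, None, None, None, None, None, None,
                                      None, None, None, None, None,
                                      flags=["measurement_failed"]))
            continue
        flags = list(m.flags)
        grade = glabel = gdev = None
        if m.delta_si is not None:
            grade = assign_grade(m.delta_si, criteria)
            glabel = criteria.grade_labels[grade - 1]
            gdev = grade_delta(m.delta_si, criteria,
                               min(grade, criteria.n_grades - 1))
        b_si = b_dhi = b_hdr = pct = None
        if baseline is not None:
            row = baseline.row(gender, seg, band)
            if m.delta_si is not None:
                b_si = beta_deviation(m.delta_si, row["delta_si_mu"],
                                      row["delta_si_sigma"])
            if m.DHI is not None:
                b_dhi = beta_deviation(m.DHI, row["dhi_mu"], row["dhi_sigma"])
            b_hdr = beta_deviation(m.HDR, row["hdr_mu"], row["hdr_sigma"])
            pct, above = collapse_percentage(m.DH, row["mean_dh"])
            if above:
                flags.append("above_baseline")
        reports.append(DiscReport(seg, m.delta_si, m.DH, m.DHI, m.HDR,
                                  grade, glabel, gdev, b_si, b_dhi, b_hdr,
                                  pct, flags))
    return DegenerationReport(discs=reports, subject=dict(subject_meta),
                              flags=list(measures.flags))


# ---------------------------------------------------------------------------
# synthetic (non-clinical) default tables derived from the phantom presets

def synthetic_criteria(n_grades: int = 5) -> GradingCriteria:
    """Grading criteria spanning the phantom's healthy→collapsed ΔSI range.

    Grade means are evenly spaced from the healthy preset's analytic ΔSI
    down to 0 (fully blurred nucleus/annulus boundary); σ is a fifth of the
    spacing.  Synthetic — for phantoms and tests, not clinical use.
    """
    from .phantom import healthy_spec

    s = healthy_spec()
    top = (s.np_intensity - s.af_intensity) / s.csf_intensity * 255.0
    mu = np.linspace(top, 0.0, n_grades)
    sigma = np.full(n_grades, (mu[0] - mu[-1]) / (n_grades - 1) / 5.0)
    return GradingCriteria(mu, sigma)


def synthetic_baseline(measured: dict | None = None) -> BaselineTable:
    """Baseline table populated from the healthy phantom's analytic truth.

    Every (gender, segment, age band) row carries the phantom's healthy
    ΔSI/DHI/HDR as mean, a 10% relative SD, and the analytic DH as the
    healthy mean height.  Synthetic — not a population reference.
    """
    from .phantom import generate_phantom, healthy_spec

    truth = generate_phantom(healthy_spec()).truth
    rows = []
    for gender in (0, 1):
        for band in AGE_BANDS:
            for seg in SEGMENTS:
                t = truth[seg]
                rows.append(dict(
                    gender=gender, segment=seg, age_band=band,
                    delta_si_mu=t.delta_si,
                    delta_si_sigma=max(1.0, 0.1 * t.delta_si),
                    dhi_mu=t.DHI, dhi_sigma=0.1 * t.DHI,
                    hdr_mu=t.HDR, hdr_sigma=0.1 * t.HDR,
                    mean_dh=t.DH))
    return BaselineTable(pd.DataFrame(rows))
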