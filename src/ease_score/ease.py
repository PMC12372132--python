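"""EASE: a six-parameter echocardiographic risk score for atrial-fibrillation
recurrence after catheter ablation, with a calibrated synthetic-cohort
generator and from-scratch survival analysis.

The score combines six left-atrial metrics — reservoir strain (LASr), atrial
electromechanical conduction time (PA-TDI), volume index (LAVI), the stiffness
index (E/e' divided by LASr), the E/e' ratio itself, and contractile strain
(LASct) — into a 0-12 point total that stratifies patients into low,
intermediate and high recurrence-risk categories.

The module is organised in the order a full analysis runs:

1.  scoring    — domain types, threshold bands, point assignment, categories
2.  synthesis  — latent-severity cohort generator and calibration report
3.  survival   — recurrence filtering, Kaplan-Meier, log-rank (from scratch)
4.  io/report  — CSV and YAML readers/writers, run report

All randomness flows through ``numpy.random.Generator`` objects derived from a
single seed; regenerating a cohort with the same parameters is bit-identical.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import yaml
from scipy import stats as _scipy_stats

__all__ = [
    "DomainError", "ConfigError", "MissingDataError", "SchemaError",
    "PARAMETERS", "CATEGORIES", "SEVERITIES", "DAYS_PER_MONTH",
    "Band", "ThresholdConfig", "EchoMeasurements", "ScoreBreakdown",
    "stiffness_index", "score_parameter", "compute_breakdown", "categorize",
    "validate_config", "default_config", "fig6_config", "load_config",
    "save_config",
    "GeneratorParams", "SyntheticPatient", "SyntheticCohort", "Episode",
    "sample_measurements", "sample_outcome", "generate_cohort",
    "CalibrationTarget", "CalibrationReport", "calibration_report",
    "SurvivalRecord", "KMCurve", "LogRankResult",
    "first_recurrence", "km_estimate", "logrank_test", "incidence_at",
    "read_measurements", "read_episodes", "read_followup",
    "score_measurements", "write_scores", "read_scores", "write_cohort",
    "survival_analysis", "run_report", "validate_report_summary",
]

logger = logging.getLogger("ease_score")

# ---------------------------------------------------------------------------
# Shared constants
# ---------------------------------------------------------------------------

#: Day-to-month conversion used for episode onsets (mean Gregorian month).
DAYS_PER_MONTH = 30.44

#: The "3-month" post-ablation blanking period, operationalised in days.
DEFAULT_BLANKING_DAYS = 90.0

#: Minimum episode duration (seconds) for an episode to count as recurrence;
#: "longer than 30 s" is read strictly (> 30).
DEFAULT_MIN_EPISODE_SECONDS = 30.0

#: Scored parameters, in canonical order.  ``stiffness`` is derived
#: (E/e' / LASr), never measured directly.
PARAMETERS = ("lasr", "pa_tdi", "lavi", "stiffness", "e_over_eprime", "lasct")

CATEGORIES = ("low", "intermediate", "high")
SEVERITIES = ("mild", "moderate", "severe")


class DomainError(ValueError):
    """A value outside its clinically meaningful domain."""


class ConfigError(ValueError):
    """An invalid threshold or generator configuration."""


class MissingDataError(ValueError):
    """Required measurements absent from a record."""


class SchemaError(ValueError):
    """An input table is missing required columns."""


# ===========================================================================
# 1. SCORING
# ===========================================================================

@dataclass(frozen=True)
class Band:
    """One half-open scoring band over a measurement axis.

    A value ``v`` lies in the band when ``lo <(=) v <(=) hi`` according to the
    two closedness flags.  Band edges are chosen so that every threshold the
    score uses (15, 23, 120, 150, 34, 48, 0.5, 14, 6) is exactly
    representable in binary-free comparisons — no tolerance fuzzing.
    """

    lo: float
    hi: float
    points: int
    lo_closed: bool = False
    hi_closed: bool = True

    def contains(self, value: float) -> bool:
        above = value >= self.lo if self.lo_closed else value > self.lo
        below = value <= self.hi if self.hi_closed else value < self.hi
        return above and below

    def to_dict(self) -> dict:
        return {
            "lo": self.lo, "hi": self.hi, "points": self.points,
            "lo_closed": self.lo_closed, "hi_closed": self.hi_closed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Band":
        return cls(lo=float(d["lo"]), hi=float(d["hi"]),
                   points=int(d["points"]),
                   lo_closed=bool(d["lo_closed"]),
                   hi_closed=bool(d["hi_closed"]))


#: Policies for a patient whose LASct could not be measured (the parameter is
#: only measurable in sinus rhythm at the time of the exam).
MISSING_LASCT_POLICIES = ("refuse", "worst_case", "omit_rescale")


@dataclass(frozen=True)
class ThresholdConfig:
    """Scoring bands, abnormality directions, category cuts and the
    missing-LASct policy.

    The default configuration (``default_config``) encodes the published
    thresholds: LASr normal > 23 %, borderline 15-23 %, abnormal < 15 %;
    PA-TDI normal < 120 ms, abnormal > 150 ms; LAVI normal < 34 mL/m²,
    severe > 48 mL/m²; stiffness abnormal > 0.5; E/e' abnormal > 14;
    LASct abnormal <= 6 %.  Three-band parameters score 0/1/2 and two-band
    parameters 0/2, the only point assignment consistent with a 0-12 total.
    """

    bands: Mapping[str, tuple[Band, ...]]
    higher_is_worse: Mapping[str, bool]
    category_boundaries: tuple[int, int] = (3, 8)
    missing_lasct_policy: str = "refuse"
    name: str = "custom"

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "category_boundaries": list(self.category_boundaries),
            "missing_lasct_policy": self.missing_lasct_policy,
            "higher_is_worse": dict(self.higher_is_worse),
            "bands": {p: [b.to_dict() for b in bs]
                      for p, bs in self.bands.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThresholdConfig":
        return cls(
            bands={p: tuple(Band.from_dict(b) for b in bs)
                   for p, bs in d["bands"].items()},
            higher_is_worse=dict(d["higher_is_worse"]),
            category_boundaries=tuple(int(x)
                                      for x in d["category_boundaries"]),
            missing_lasct_policy=d.get("missing_lasct_policy", "refuse"),
            name=d.get("name", "custom"),
        )

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def max_points(self, parameter: str) -> int:
        return max(b.points for b in self.bands[parameter])


def _three_band(cut1: float, cut2: float, *, higher_is_worse: bool
                ) -> tuple[Band, ...]:
    """0/1/2 bands from two cuts; the *stated-normal* side is open at its cut.

    For lower-is-worse parameters (LASr): normal is (cut2, inf), borderline
    [cut1, cut2], abnormal (0, cut1).  For higher-is-worse (PA-TDI, LAVI):
    normal (0, cut1), intermediate [cut1, cut2], abnormal (cut2, inf).
    """
    if higher_is_worse:
        return (
            Band(0.0, cut1, 0, lo_closed=False, hi_closed=False),
            Band(cut1, cut2, 1, lo_closed=True, hi_closed=True),
            Band(cut2, math.inf, 2, lo_closed=False, hi_closed=False),
        )
    return (
        Band(0.0, cut1, 2, lo_closed=False, hi_closed=False),
        Band(cut1, cut2, 1, lo_closed=True, hi_closed=True),
        Band(cut2, math.inf, 0, lo_closed=False, hi_closed=False),
    )


def _two_band(cut: float, *, higher_is_worse: bool) -> tuple[Band, ...]:
    """0/2 bands from a single cut; the cut value itself is normal."""
    if higher_is_worse:
        return (
            Band(0.0, cut, 0, lo_closed=False, hi_closed=True),
            Band(cut, math.inf, 2, lo_closed=False, hi_closed=False),
        )
    return (
        Band(0.0, cut, 2, lo_closed=False, hi_closed=True),
        Band(cut, math.inf, 0, lo_closed=False, hi_closed=False),
    )


def default_config() -> ThresholdConfig:
    """Default thresholds with published category boundaries 0-3 / 4-8 / 9-12."""
    return ThresholdConfig(
        bands={
            "lasr": _three_band(15.0, 23.0, higher_is_worse=False),
            "pa_tdi": _three_band(120.0, 150.0, higher_is_worse=True),
            "lavi": _three_band(34.0, 48.0, higher_is_worse=True),
            "stiffness": _two_band(0.5, higher_is_worse=True),
            "e_over_eprime": _two_band(14.0, higher_is_worse=True),
            "lasct": _two_band(6.0, higher_is_worse=False),
        },
        higher_is_worse={
            "lasr": False, "pa_tdi": True, "lavi": True,
            "stiffness": True, "e_over_eprime": True, "lasct": False,
        },
        category_boundaries=(3, 8),
        missing_lasct_policy="refuse",
        name="ease_default",
    )


def fig6_config() -> ThresholdConfig:
    """Alternate category boundaries 0-3 / 4-7 / 8-12 (used by the source
    cohort's baseline table and survival figure)."""
    cfg = default_config()
    return replace(cfg, category_boundaries=(3, 7), name="ease_fig6")


_NAMED_CONFIGS = {"default": default_config, "fig6": fig6_config}


def load_config(source: str | Path) -> ThresholdConfig:
    """Load a ThresholdConfig by name (``default``/``fig6``) or from a
    YAML/JSON file."""
    if isinstance(source, str) and source in _NAMED_CONFIGS:
        return _NAMED_CONFIGS[source]()
    with open(source) as fh:
        data = yaml.safe_load(fh)
    return ThresholdConfig.from_dict(data)


def save_config(config: ThresholdConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class EchoMeasurements:
    """One patient's echocardiographic inputs.

    Parameters
    ----------
    lasr_pct : float
        Left atrial reservoir strain, percent.  Lower values indicate a
        stiffer, more fibrotic atrium.
    pa_tdi_ms : float
        Atrial electromechanical conduction time, milliseconds (P-wave onset
        to lateral-annulus A' onset on tissue Doppler).
    lavi_ml_m2 : float
        Left atrial volume index, mL/m².
    e_over_eprime : float
        E/e' ratio (dimensionless), a surrogate for LV filling pressure.
    lasct_pct : float or None
        Left atrial contractile strain, percent.  ``None`` when the patient
        was not in sinus rhythm at the exam (the parameter is then not
        measurable).
    """

    lasr_pct: float
    pa_tdi_ms: float
    lavi_ml_m2: float
    e_over_eprime: float
    lasct_pct: float | None = None

    def __post_init__(self):
        for name in ("lasr_pct", "pa_tdi_ms", "lavi_ml_m2", "e_over_eprime"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise DomainError(f"{name} must be a finite positive number, "
                                  f"got {v!r}")
        if self.lasct_pct is not None and not (
                math.isfinite(self.lasct_pct) and self.lasct_pct > 0):
            raise DomainError(f"lasct_pct must be finite positive or None, "
                              f"got {self.lasct_pct!r}")

    @property
    def stiffness(self) -> float:
        """Left atrial stiffness index: E/e' divided by LASr (as percent)."""
        return stiffness_index(self.e_over_eprime, self.lasr_pct)


def stiffness_index(e_over_eprime: float, lasr_pct: float) -> float:
    """Stiffness index = E/e' / LASr, LASr entering as its percent value.

    E/e' = 10 with LASr = 20 % gives 0.5, exactly the normal/abnormal
    boundary (values <= 0.5 are normal).
    """
    if not (math.isfinite(e_over_eprime) and e_over_eprime > 0):
        raise DomainError(f"e_over_eprime must be positive, got {e_over_eprime!r}")
    if not (math.isfinite(lasr_pct) and lasr_pct > 0):
        raise DomainError(f"lasr_pct must be positive, got {lasr_pct!r}")
    return e_over_eprime / lasr_pct


def score_parameter(value: float, bands: Sequence[Band]) -> int:
    """Points for ``value`` under an ordered band list.

    Exactly one band contains any positive finite value in a valid
    configuration; a value outside all bands indicates a broken config.
    """
    if not (math.isfinite(value) and value > 0):
        raise DomainError(f"measurement must be finite positive, got {value!r}")
    for band in bands:
        if band.contains(value):
            return band.points
    raise ConfigError(f"value {value} not covered by any band")


def categorize(total: int, boundaries: tuple[int, int] = (3, 8)) -> str:
    """Risk category of a total score: low if total <= b1, intermediate if
    b1 < total <= b2, high otherwise.  Default boundaries (3, 8)."""
    if not (0 <= total <= 12):
        raise DomainError(f"total score must be in 0..12, got {total}")
    b1, b2 = boundaries
    if total <= b1:
        return "low"
    if total <= b2:
        return "intermediate"
    return "high"


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-parameter points, total, category and data-quality flags.

    ``points['lasct']`` is ``None`` when LASct was absent and the policy
    omitted it; ``total`` then reflects the active missing-data policy.
    """

    points: Mapping[str, int | None]
    total: int
    category: str
    flags: tuple[str, ...] = ()


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def compute_breakdown(meas: EchoMeasurements,
                      config: ThresholdConfig | None = None) -> ScoreBreakdown:
    """Score one patient: per-parameter points, total (0-12) and category.

    The stiffness index is derived internally from E/e' and LASr.  A missing
    LASct is handled per ``config.missing_lasct_policy``:

    - ``refuse`` (default): raise :class:`MissingDataError`;
    - ``worst_case``: assign the maximum LASct points, flag the record;
    - ``omit_rescale``: score the five available parameters, rescale the
      total to the 0-12 range (x 12/10), round half-up, flag the record.
    """
    config = config or default_config()
    values = {
        "lasr": meas.lasr_pct,
        "pa_tdi": meas.pa_tdi_ms,
        "lavi": meas.lavi_ml_m2,
        "stiffness": meas.stiffness,
        "e_over_eprime": meas.e_over_eprime,
        "lasct": meas.lasct_pct,
    }
    points: dict[str, int | None] = {}
    flags: list[str] = []
    for p in PARAMETERS:
        if p == "lasct" and values[p] is None:
            policy = config.missing_lasct_policy
            if policy == "refuse":
                raise MissingDataError(
                    "missing fields: lasct_pct (policy 'refuse'; set "
                    "missing_lasct_policy to 'worst_case' or 'omit_rescale' "
                    "to score without it)")
            if policy == "worst_case":
                points[p] = config.max_points("lasct")
                flags.append("lasct_imputed_worst_case")
            elif policy == "omit_rescale":
                points[p] = None
                flags.append("lasct_omitted_rescaled")
            else:  # pragma: no cover - guarded by validate_config
                raise ConfigError(f"unknown missing_lasct_policy {policy!r}")
        else:
            points[p] = score_parameter(values[p], config.bands[p])

    if points["lasct"] is None:
        partial = sum(v for v in points.values() if v is not None)
        attainable = sum(config.max_points(p) for p in PARAMETERS
                         if p != "lasct")
        total = _round_half_up(partial * 12.0 / attainable)
    else:
        total = sum(points.values())
    return ScoreBreakdown(points=points, total=total,
                          category=categorize(total,
                                              config.category_boundaries),
                          flags=tuple(flags))


def validate_config(config: ThresholdConfig) -> list[str]:
    """Check a ThresholdConfig; return a list of violations (empty = valid).

    Checks: band contiguity and full coverage of (0, inf) per parameter,
    non-negative integer points monotone in the abnormality direction,
    attainable total spanning exactly 0..12, ordered category boundaries and
    a known missing-LASct policy.
    """
    violations: list[str] = []
    for p in PARAMETERS:
        bands = config.bands.get(p)
        if not bands:
            violations.append(f"{p}: no bands defined")
            continue
        if bands[0].lo != 0.0 or bands[-1].hi != math.inf:
            violations.append(f"{p}: bands do not cover the positive axis")
        for a, b in zip(bands, bands[1:]):
            if a.hi != b.lo:
                violations.append(
                    f"{p}: gap or overlap between bands ending {a.hi} "
                    f"and starting {b.lo}")
            elif a.hi_closed == b.lo_closed:
                violations.append(
                    f"{p}: edge {a.hi} covered "
                    f"{'twice' if a.hi_closed else 'by neither band'}")
        pts = [b.points for b in bands]
        if any(not isinstance(x, int) or x < 0 for x in pts):
            violations.append(f"{p}: point values must be non-negative ints")
        ordered = pts if config.higher_is_worse.get(p, True) else pts[::-1]
        if ordered != sorted(ordered):
            violations.append(f"{p}: points not monotone with abnormality")
    max_total = sum(config.max_points(p) for p in PARAMETERS
                    if config.bands.get(p))
    min_total = sum(min(b.points for b in config.bands[p])
                    for p in PARAMETERS if config.bands.get(p))
    if max_total != 12:
        violations.append(f"max attainable total is {max_total}, expected 12")
    if min_total != 0:
        violations.append(f"min attainable total is {min_total}, expected 0")
    b1, b2 = config.category_boundaries
    if not (0 <= b1 < b2 <= 12):
        violations.append(f"category boundaries {b1},{b2} violate 0<=b1<b2<=12")
    if config.missing_lasct_policy not in MISSING_LASCT_POLICIES:
        violations.append(
            f"unknown missing_lasct_policy {config.missing_lasct_policy!r}")
    return violations


# ===========================================================================
# 2. SYNTHESIS
# ===========================================================================
#
# The generator emulates a single-centre cohort of first-time pulmonary-vein
# isolation patients: a three-class latent remodeling severity (mild /
# moderate / severe) drives all six parameters through severity-conditional
# truncated normals plus one shared latent factor per patient, producing both
# the observed category proportions and the strong negative LASr-stiffness
# correlation.  Recurrence times are exponential within risk category, pinned
# to the published 12-month cumulative incidences; censoring is
# administrative at end of follow-up.

_PRIMITIVES = ("lasr", "pa_tdi", "lavi", "e_over_eprime", "lasct")


class Episode(NamedTuple):
    """One logged arrhythmia episode."""
    onset_day: float
    duration_s: float


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic-cohort generator.

    Defaults were calibrated by Monte Carlo so that, under the default
    ThresholdConfig, cohort category proportions match 29.7 / 47.7 / 22.6 %,
    the LASr-stiffness Pearson correlation sits near -0.72, mild patients
    score <= 3 with probability > 0.8 and severe patients >= 9 with
    probability > 0.6.  Follow-up is log-normal with median 14 months and
    quartiles near 11 / 18; per-category 12-month recurrence defaults to
    8 / 35 / 65 % (the intermediate value is a design choice between the
    published <10 % and >60 % bounds).
    """

    n: int = 128
    seed: int = 42
    severity_weights: tuple[float, float, float] = (0.30, 0.47, 0.23)
    # per-severity means / sds for the five primitive parameters
    means: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: {
        "mild":     {"lasr": 28.0, "pa_tdi": 105.0, "lavi": 29.0,
                     "e_over_eprime": 8.0,  "lasct": 10.0},
        "moderate": {"lasr": 17.5, "pa_tdi": 139.0, "lavi": 41.5,
                     "e_over_eprime": 12.5, "lasct": 6.8},
        "severe":   {"lasr": 11.0, "pa_tdi": 160.0, "lavi": 52.0,
                     "e_over_eprime": 16.0, "lasct": 4.0},
    })
    sds: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: {
        "mild":     {"lasr": 3.0, "pa_tdi": 10.0, "lavi": 4.0,
                     "e_over_eprime": 1.8, "lasct": 2.0},
        "moderate": {"lasr": 2.0, "pa_tdi": 7.0,  "lavi": 3.0,
                     "e_over_eprime": 1.2, "lasct": 1.3},
        "severe":   {"lasr": 3.0, "pa_tdi": 10.0, "lavi": 4.0,
                     "e_over_eprime": 2.0, "lasct": 2.0},
    })
    # shared latent remodeling factor: loading per parameter (z > 0 = worse)
    latent_loadings: Mapping[str, float] = field(default_factory=lambda: {
        "lasr": -2.0, "pa_tdi": 6.0, "lavi": 2.5,
        "e_over_eprime": 1.2, "lasct": -1.2,
    })
    # per-severity scale of the latent factor; the moderate class is damped
    # so it stays concentrated in the intermediate score band
    latent_scale: Mapping[str, float] = field(default_factory=lambda: {
        "mild": 1.0, "moderate": 0.35, "severe": 1.0,
    })
    # physiologic floors (truncation)
    floors: Mapping[str, float] = field(default_factory=lambda: {
        "lasr": 2.0, "pa_tdi": 30.0, "lavi": 5.0,
        "e_over_eprime": 1.0, "lasct": 0.5,
    })
    followup_log_mu: float = math.log(14.0)
    followup_log_sigma: float = 0.373
    hazard_by_category: Mapping[str, float] = field(default_factory=lambda: {
        "low": 0.08, "intermediate": 0.35, "high": 0.65,
    })
    blanking_days: float = DEFAULT_BLANKING_DAYS
    # qualifying-episode duration (seconds), uniform
    recurrence_duration_s: tuple[float, float] = (60.0, 3600.0)
    # nuisance episodes the survival filter must reject
    short_episode_rate: float = 0.5            # Poisson mean per patient
    short_episode_duration_s: tuple[float, float] = (5.0, 30.0)
    blanking_episode_prob: float = 0.3
    blanking_episode_duration_s: tuple[float, float] = (60.0, 600.0)

    def validate(self) -> None:
        if self.n <= 0:
            raise ConfigError("n must be positive")
        w = self.severity_weights
        if len(w) != 3 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ConfigError("severity_weights must be 3 non-negative "
                              "values summing to 1")
        for sev in SEVERITIES:
            if any(self.sds[sev][p] < 0 for p in _PRIMITIVES):
                raise ConfigError("spreads must be non-negative")
        h = [self.hazard_by_category[c] for c in CATEGORIES]
        if any(not 0 <= x < 1 for x in h):
            raise ConfigError("hazards must be probabilities in [0, 1)")
        if not h[0] <= h[1] <= h[2]:
            raise ConfigError("hazards must be non-decreasing across "
                              "low/intermediate/high")
        if self.followup_log_sigma < 0:
            raise ConfigError("followup_log_sigma must be non-negative")

    def to_dict(self) -> dict:
        return {
            "n": self.n, "seed": self.seed,
            "severity_weights": list(self.severity_weights),
            "means": {s: dict(self.means[s]) for s in SEVERITIES},
            "sds": {s: dict(self.sds[s]) for s in SEVERITIES},
            "latent_loadings": dict(self.latent_loadings),
            "latent_scale": dict(self.latent_scale),
            "floors": dict(self.floors),
            "followup_log_mu": self.followup_log_mu,
            "followup_log_sigma": self.followup_log_sigma,
            "hazard_by_category": dict(self.hazard_by_category),
            "blanking_days": self.blanking_days,
            "recurrence_duration_s": list(self.recurrence_duration_s),
            "short_episode_rate": self.short_episode_rate,
            "short_episode_duration_s": list(self.short_episode_duration_s),
            "blanking_episode_prob": self.blanking_episode_prob,
            "blanking_episode_duration_s":
                list(self.blanking_episode_duration_s),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorParams":
        kwargs = dict(d)
        for key in ("severity_weights", "recurrence_duration_s",
                    "short_episode_duration_s", "blanking_episode_duration_s"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def sample_measurements(severity: str, params: GeneratorParams,
                        rng: np.random.Generator) -> EchoMeasurements:
    """Draw one patient's five primitive parameters for a latent severity.

    A single standard-normal latent factor ``z`` (scaled per severity) shifts
    every parameter toward abnormality together; independent noise is added
    per parameter and values are truncated at physiologic floors.  The
    stiffness index is never sampled — it is always derived as E/e' / LASr.
    """
    if severity not in SEVERITIES:
        raise ConfigError(f"unknown severity {severity!r}")
    z = rng.standard_normal() * params.latent_scale[severity]
    vals = {}
    for p in _PRIMITIVES:
        v = (params.means[severity][p]
             + params.latent_loadings[p] * z
             + params.sds[severity][p] * rng.standard_normal())
        vals[p] = max(v, params.floors[p])
    return EchoMeasurements(lasr_pct=vals["lasr"], pa_tdi_ms=vals["pa_tdi"],
                            lavi_ml_m2=vals["lavi"],
                            e_over_eprime=vals["e_over_eprime"],
                            lasct_pct=vals["lasct"])


def sample_outcome(category: str, followup_months: float,
                   params: GeneratorParams,
                   rng: np.random.Generator) -> list[Episode]:
    """Draw one patient's arrhythmia-episode log.

    A latent recurrence time is exponential with 12-month cumulative
    incidence equal to ``hazard_by_category[category]``.  If it falls within
    follow-up, one qualifying episode (> 30 s, strictly post-blanking) is
    emitted at that time (pre-blanking latent times surface just after the
    blanking period ends).  Nuisance episodes — short (< = 30 s) ones and an
    occasional in-blanking episode — are added so the recurrence filter has
    something to reject.
    """
    if followup_months <= 0:
        raise DomainError("followup_months must be positive")
    p12 = params.hazard_by_category[category]
    followup_days = followup_months * DAYS_PER_MONTH
    episodes: list[Episode] = []

    # latent recurrence time (months); p12 == 0 means never
    if p12 > 0:
        lam = -math.log1p(-p12) / 12.0          # per-month hazard rate
        t_months = rng.exponential(1.0 / lam)
        onset_day = max(t_months * DAYS_PER_MONTH, params.blanking_days + 1.0)
        if onset_day <= followup_days:
            episodes.append(Episode(
                onset_day=onset_day,
                duration_s=rng.uniform(*params.recurrence_duration_s)))

    # nuisance: short episodes anywhere in follow-up (duration <= 30 s)
    for _ in range(rng.poisson(params.short_episode_rate)):
        episodes.append(Episode(
            onset_day=rng.uniform(1.0, followup_days),
            duration_s=rng.uniform(*params.short_episode_duration_s)))
    # nuisance: one long episode inside the blanking period
    if rng.uniform() < params.blanking_episode_prob:
        hi = min(params.blanking_days, followup_days)
        episodes.append(Episode(
            onset_day=rng.uniform(1.0, hi) if hi > 1.0 else hi,
            duration_s=rng.uniform(*params.blanking_episode_duration_s)))
    return episodes


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    severity: str
    measurements: EchoMeasurements
    breakdown: ScoreBreakdown
    followup_months: float
    episodes: tuple[Episode, ...]
    survival: "SurvivalRecord"


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus the parameters and config that produced it."""

    params: GeneratorParams
    config: ThresholdConfig
    patients: tuple[SyntheticPatient, ...]

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def survival_records(self) -> list["SurvivalRecord"]:
        return [p.survival for p in self.patients]

    def measurements_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "patient_id": p.patient_id,
            "lasr_pct": p.measurements.lasr_pct,
            "pa_tdi_ms": p.measurements.pa_tdi_ms,
            "lavi_ml_m2": p.measurements.lavi_ml_m2,
            "e_over_eprime": p.measurements.e_over_eprime,
            "lasct_pct": p.measurements.lasct_pct,
        } for p in self.patients])

    def scores_frame(self):
        records = [(p.patient_id, p.measurements) for p in self.patients]
        return score_measurements(records, self.config)

    def episodes_frame(self):
        import pandas as pd
        rows = [{"patient_id": p.patient_id, "onset_day": e.onset_day,
                 "duration_s": e.duration_s}
                for p in self.patients for e in p.episodes]
        return pd.DataFrame(rows,
                            columns=["patient_id", "onset_day", "duration_s"])

    def meta_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "patient_id": p.patient_id,
            "followup_months": p.followup_months,
            "severity": p.severity,
        } for p in self.patients])


def generate_cohort(params: GeneratorParams | None = None,
                    config: ThresholdConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort.

    Each patient draws from an independent substream spawned by counter from
    the root seed, so the cohort is bit-identical under a fixed seed and
    invariant to generation order.  Severity, measurements, follow-up and the
    episode log are drawn per patient; scores and survival records are
    derived with the scoring and recurrence machinery of this module.
    """
    params = params or GeneratorParams()
    params.validate()
    config = config or default_config()
    root = np.random.SeedSequence(params.seed)
    children = root.spawn(params.n)
    weights = np.asarray(params.severity_weights, dtype=float)
    weights = weights / weights.sum()
    width = len(str(params.n))
    patients = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        severity = SEVERITIES[rng.choice(3, p=weights)]
        meas = sample_measurements(severity, params, rng)
        breakdown = compute_breakdown(meas, config)
        followup = math.exp(rng.normal(params.followup_log_mu,
                                       params.followup_log_sigma))
        episodes = sample_outcome(breakdown.category, followup, params, rng)
        pid = f"P{i + 1:0{width}d}"
        survival = first_recurrence(
            episodes, followup, blanking_days=params.blanking_days,
            min_duration_s=DEFAULT_MIN_EPISODE_SECONDS,
            patient_id=pid, category=breakdown.category)
        patients.append(SyntheticPatient(
            patient_id=pid, severity=severity, measurements=meas,
            breakdown=breakdown, followup_months=followup,
            episodes=tuple(episodes), survival=survival))
    return SyntheticCohort(params=params, config=config,
                           patients=tuple(patients))


# -- calibration ------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationTarget:
    name: str
    observed: float | None
    target: float
    tolerance: float
    cmp: str            # "abs" (|obs-target|<=tol), "le" or "ge" (bound)
    passed: bool
    note: str = ""


@dataclass(frozen=True)
class CalibrationReport:
    targets: tuple[CalibrationTarget, ...]
    pairwise_correlations: Mapping[tuple[str, str], float | None]

    @property
    def passed(self) -> bool:
        return all(t.passed for t in self.targets)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "targets": [{
                "name": t.name, "observed": t.observed, "target": t.target,
                "tolerance": t.tolerance, "cmp": t.cmp, "passed": t.passed,
                "note": t.note,
            } for t in self.targets],
        }


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson r, or None when either column is (numerically) constant."""
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        return None
    return float(np.corrcoef(x, y)[0, 1])


#: Default calibration targets: (target, tolerance, cmp).
DEFAULT_CALIBRATION_TARGETS: Mapping[str, tuple[float, float, str]] = {
    "proportion_low": (38 / 128, 0.03, "abs"),
    "proportion_intermediate": (61 / 128, 0.03, "abs"),
    "proportion_high": (29 / 128, 0.03, "abs"),
    "corr_lasr_stiffness": (-0.72, 0.08, "abs"),
    "followup_median_months": (14.0, 0.5, "abs"),
    "followup_iqr_low_months": (11.0, 1.0, "abs"),
    "followup_iqr_high_months": (18.0, 1.0, "abs"),
    "km_incidence_12mo_low": (0.10, 0.0, "le"),
    "km_incidence_12mo_high": (0.60, 0.0, "ge"),
}


def calibration_report(cohort: SyntheticCohort,
                       targets: Mapping[str, tuple[float, float, str]] | None
                       = None) -> CalibrationReport:
    """Compare a cohort's summary statistics against calibration targets.

    Computes category proportions, the LASr-stiffness Pearson correlation
    (plus the full six-parameter pairwise correlation table), follow-up
    median/IQR and per-category 12-month Kaplan-Meier recurrence incidence.
    Constant columns yield 'undefined' correlations (``None``), never NaN.
    """
    if len(cohort) == 0:
        raise DomainError("cohort is empty")
    targets = dict(targets or DEFAULT_CALIBRATION_TARGETS)

    totals = np.array([p.breakdown.total for p in cohort.patients])
    cats = np.array([p.breakdown.category for p in cohort.patients])
    followup = np.array([p.followup_months for p in cohort.patients])
    cols = {
        "lasr": np.array([p.measurements.lasr_pct for p in cohort.patients]),
        "pa_tdi": np.array([p.measurements.pa_tdi_ms
                            for p in cohort.patients]),
        "lavi": np.array([p.measurements.lavi_ml_m2
                          for p in cohort.patients]),
        "e_over_eprime": np.array([p.measurements.e_over_eprime
                                   for p in cohort.patients]),
        "lasct": np.array([p.measurements.lasct_pct or np.nan
                           for p in cohort.patients]),
        "stiffness": np.array([p.measurements.stiffness
                               for p in cohort.patients]),
    }
    pairwise = {}
    names = list(cols)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[(a, b)] = _pearson(cols[a], cols[b])

    observed: dict[str, float | None] = {}
    for cat, key in zip(CATEGORIES, ("proportion_low",
                                     "proportion_intermediate",
                                     "proportion_high")):
        observed[key] = float(np.mean(cats == cat))
    observed["corr_lasr_stiffness"] = pairwise[("lasr", "stiffness")]
    observed["followup_median_months"] = float(np.median(followup))
    q1, q3 = np.percentile(followup, [25, 75])
    observed["followup_iqr_low_months"] = float(q1)
    observed["followup_iqr_high_months"] = float(q3)
    for cat, key in zip(CATEGORIES, ("km_incidence_12mo_low",
                                     "km_incidence_12mo_intermediate",
                                     "km_incidence_12mo_high")):
        recs = [p.survival for p in cohort.patients
                if p.breakdown.category == cat]
        observed[key] = (incidence_at(km_estimate(recs), 12.0)
                         if recs else None)

    checked = []
    for name, (target, tol, cmp) in targets.items():
        obs = observed.get(name)
        if obs is None:
            passed, note = False, "undefined (constant column or empty group)"
        elif cmp == "abs":
            passed, note = abs(obs - target) <= tol, ""
        elif cmp == "le":
            passed, note = obs <= target, ""
        elif cmp == "ge":
            passed, note = obs >= target, ""
        else:
            raise ConfigError(f"unknown comparison {cmp!r}")
        checked.append(CalibrationTarget(name=name, observed=obs,
                                         target=target, tolerance=tol,
                                         cmp=cmp, passed=passed, note=note))
    return CalibrationReport(targets=tuple(checked),
                             pairwise_correlations=pairwise)


# ===========================================================================
# 3. SURVIVAL
# ===========================================================================

@dataclass(frozen=True)
class SurvivalRecord:
    """(time, event) pair for one patient.

    ``time`` is months from ablation to the first qualifying recurrence
    (event=True) or to administrative censoring at end of follow-up
    (event=False).
    """

    patient_id: str
    time: float
    event: bool
    category: str | None = None

    def __post_init__(self):
        if self.time <= 0:
            raise DomainError(f"survival time must be positive, "
                              f"got {self.time}")


def first_recurrence(episodes: Iterable[Episode | tuple],
                     followup_months: float,
                     blanking_days: float = DEFAULT_BLANKING_DAYS,
                     min_duration_s: float = DEFAULT_MIN_EPISODE_SECONDS,
                     *,
                     strict_duration: bool = True,
                     patient_id: str = "",
                     category: str | None = None) -> SurvivalRecord:
    """Apply the recurrence definition to an episode log.

    An episode qualifies when its duration exceeds ``min_duration_s``
    (strictly, by default) AND its onset is strictly after the blanking
    period.  The earliest qualifying onset becomes the event time (days
    converted to months at 30.44 d/mo); with no qualifying episode the
    patient is censored at end of follow-up.  Episodes with onset beyond
    follow-up are ignored with a warning.
    """
    if followup_months <= 0:
        raise DomainError("followup_months must be positive")
    followup_days = followup_months * DAYS_PER_MONTH
    best: float | None = None
    for ep in episodes:
        onset_day, duration_s = ep[0], ep[1]
        if onset_day <= 0 or duration_s <= 0:
            raise DomainError(f"episode onset/duration must be positive, "
                              f"got {ep!r}")
        if onset_day > followup_days:
            logger.warning("episode at day %.1f beyond follow-up (%.1f d) "
                           "for patient %r ignored",
                           onset_day, followup_days, patient_id)
            continue
        long_enough = (duration_s > min_duration_s if strict_duration
                       else duration_s >= min_duration_s)
        if long_enough and onset_day > blanking_days:
            if best is None or onset_day < best:
                best = onset_day
    if best is None:
        return SurvivalRecord(patient_id=patient_id, time=followup_months,
                              event=False, category=category)
    return SurvivalRecord(patient_id=patient_id,
                          time=best / DAYS_PER_MONTH, event=True,
                          category=category)


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit curve over the distinct event times.

    ``survival[i]`` is S(t) just after ``times[i]``; S is 1 before the first
    event time.  ``variance`` holds Greenwood variance estimates of S at each
    event time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    variance: np.ndarray
    n_subjects: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.variance)

    def survival_at(self, t: float) -> float:
        """Step-interpolated S(t): the value after the last event time <= t."""
        if t < 0:
            raise DomainError("time must be non-negative")
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def confidence_band(self, z: float = 1.959963984540054
                        ) -> tuple[np.ndarray, np.ndarray]:
        """Plain Greenwood 95 % band, clipped to [0, 1]."""
        half = z * self.se
        return (np.clip(self.survival - half, 0.0, 1.0),
                np.clip(self.survival + half, 0.0, 1.0))


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    At tied times, events are processed before censorings (subjects censored
    at t remain in the risk set for events at t).  Greenwood's formula gives
    the variance of S at each event time; when the risk set is exhausted
    (S = 0) the variance is reported as 0.
    """
    records = list(records)
    if not records:
        raise DomainError("km_estimate requires at least one record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    n = len(records)

    event_times = np.unique(times[events])
    at_risk = np.empty(len(event_times), dtype=int)
    d = np.empty(len(event_times), dtype=int)
    for i, t in enumerate(event_times):
        at_risk[i] = int(np.sum(times >= t))
        d[i] = int(np.sum(events & (times == t)))
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)
        terms = np.where(at_risk > d,
                         d / (at_risk * (at_risk - d).astype(float)), 0.0)
        var = surv ** 2 * np.cumsum(terms)
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk,
                   events=d, variance=var, n_subjects=n)


def incidence_at(curve: KMCurve, t: float) -> float:
    """Cumulative incidence 1 - S(t) from a KM curve (step-interpolated)."""
    return 1.0 - curve.survival_at(t)


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    groups: tuple[str, ...]


def logrank_test(groups: Mapping[str, Sequence[SurvivalRecord]]
                 ) -> LogRankResult:
    """k-group log-rank test.

    At each pooled event time the observed events per group are compared with
    hypergeometric expectations given the group risk sets; the quadratic form
    of (O - E) against the summed covariance (dropping one group) is
    chi-square with k-1 degrees of freedom under the null of identical
    hazards.  A pseudo-inverse guards against degenerate covariance.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise DomainError("logrank_test requires at least two groups")
    for lab in labels:
        if len(groups[lab]) == 0:
            raise DomainError(f"group {lab!r} has zero subjects")
    k = len(labels)
    times = {lab: np.array([r.time for r in groups[lab]]) for lab in labels}
    events = {lab: np.array([r.event for r in groups[lab]], dtype=bool)
              for lab in labels}
    pooled = np.unique(np.concatenate(
        [times[lab][events[lab]] for lab in labels]))

    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in pooled:
        n_g = np.array([np.sum(times[lab] >= t) for lab in labels],
                       dtype=float)
        d_g = np.array([np.sum(events[lab] & (times[lab] == t))
                        for lab in labels], dtype=float)
        n_tot = n_g.sum()
        d_tot = d_g.sum()
        if n_tot <= 1 or d_tot == 0:
            continue
        O += d_g
        E += d_tot * n_g / n_tot
        frac = n_g / n_tot
        mult = d_tot * (n_tot - d_tot) / (n_tot - 1.0)
        V += mult * (np.diag(frac) - np.outer(frac, frac))
    z = (O - E)[:-1]
    stat = float(z @ np.linalg.pinv(V[:-1, :-1]) @ z)
    stat = max(stat, 0.0)
    p = float(_scipy_stats.chi2.sf(stat, k - 1))
    return LogRankResult(statistic=stat, df=k - 1, p_value=p,
                         groups=tuple(labels))


def crude_recurrence(records: Sequence[SurvivalRecord]) -> float:
    """Crude recurrence proportion (events / subjects), ignoring censoring.

    Reported alongside KM incidence because published per-category recurrence
    figures do not state which of the two they are.
    """
    if not records:
        raise DomainError("no records")
    return float(np.mean([r.event for r in records]))


# ===========================================================================
# 4. IO & REPORT
# ===========================================================================

MEASUREMENT_COLUMNS = ("patient_id", "lasr_pct", "pa_tdi_ms", "lavi_ml_m2",
                       "e_over_eprime", "lasct_pct")
SCORE_COLUMNS = MEASUREMENT_COLUMNS + (
    "stiffness", "pts_lasr", "pts_patdi", "pts_lavi", "pts_stiffness",
    "pts_ee", "pts_lasct", "total", "category", "flags")
EPISODE_COLUMNS = ("patient_id", "onset_day", "duration_s")


class RowError(NamedTuple):
    line: int
    message: str


@dataclass(frozen=True)
class MeasurementTable:
    records: tuple[tuple[str, EchoMeasurements], ...]
    errors: tuple[RowError, ...]


def _open_rows(path):
    # skip provenance comment lines (leading '#') before the header
    with open(path, newline="") as fh:
        lines = [(i + 1, ln) for i, ln in enumerate(fh)
                 if not ln.startswith("#")]
    return lines


def read_measurements(path: str | Path) -> MeasurementTable:
    """Read the measurement CSV (header required, '.' decimal, UTF-8).

    An empty ``lasct_pct`` cell means LASct was not measurable.  Malformed
    rows are collected into ``errors`` with their 1-based line numbers; a
    missing required column is fatal.
    """
    lines = _open_rows(path)
    if not lines:
        raise SchemaError(f"{path}: empty file")
    reader = csv.DictReader([ln for _, ln in lines])
    missing = [c for c in MEASUREMENT_COLUMNS
               if c not in (reader.fieldnames or [])]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): "
                          + ", ".join(missing))
    records: list[tuple[str, EchoMeasurements]] = []
    errors: list[RowError] = []
    for row, (lineno, _) in zip(reader, lines[1:]):
        try:
            lasct_raw = (row.get("lasct_pct") or "").strip()
            meas = EchoMeasurements(
                lasr_pct=float(row["lasr_pct"]),
                pa_tdi_ms=float(row["pa_tdi_ms"]),
                lavi_ml_m2=float(row["lavi_ml_m2"]),
                e_over_eprime=float(row["e_over_eprime"]),
                lasct_pct=float(lasct_raw) if lasct_raw else None)
            records.append((row["patient_id"], meas))
        except (TypeError, ValueError) as exc:
            errors.append(RowError(line=lineno, message=str(exc)))
    return MeasurementTable(records=tuple(records), errors=tuple(errors))


def read_episodes(path: str | Path) -> dict[str, list[Episode]]:
    """Read the episode CSV into per-patient episode logs."""
    lines = _open_rows(path)
    reader = csv.DictReader([ln for _, ln in lines])
    missing = [c for c in EPISODE_COLUMNS
               if c not in (reader.fieldnames or [])]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): "
                          + ", ".join(missing))
    out: dict[str, list[Episode]] = {}
    for row in reader:
        out.setdefault(row["patient_id"], []).append(
            Episode(onset_day=float(row["onset_day"]),
                    duration_s=float(row["duration_s"])))
    return out


def read_followup(path: str | Path) -> dict[str, float]:
    """Read the cohort-metadata CSV (patient_id, followup_months)."""
    lines = _open_rows(path)
    reader = csv.DictReader([ln for _, ln in lines])
    missing = [c for c in ("patient_id", "followup_months")
               if c not in (reader.fieldnames or [])]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): "
                          + ", ".join(missing))
    return {row["patient_id"]: float(row["followup_months"])
            for row in reader}


def score_measurements(records: Sequence[tuple[str, EchoMeasurements]],
                       config: ThresholdConfig | None = None):
    """Score a batch of patients into a DataFrame with deterministic columns."""
    import pandas as pd
    config = config or default_config()
    rows = []
    for pid, meas in records:
        bd = compute_breakdown(meas, config)
        rows.append({
            "patient_id": pid,
            "lasr_pct": meas.lasr_pct,
            "pa_tdi_ms": meas.pa_tdi_ms,
            "lavi_ml_m2": meas.lavi_ml_m2,
            "e_over_eprime": meas.e_over_eprime,
            "lasct_pct": meas.lasct_pct,
            "stiffness": meas.stiffness,
            "pts_lasr": bd.points["lasr"],
            "pts_patdi": bd.points["pa_tdi"],
            "pts_lavi": bd.points["lavi"],
            "pts_stiffness": bd.points["stiffness"],
            "pts_ee": bd.points["e_over_eprime"],
            "pts_lasct": bd.points["lasct"],
            "total": bd.total,
            "category": bd.category,
            "flags": ";".join(bd.flags),
        })
    return pd.DataFrame(rows, columns=list(SCORE_COLUMNS))


def write_scores(frame, path: str | Path,
                 provenance: Mapping[str, object] | None = None) -> None:
    """Write a score table with optional '#'-prefixed provenance header."""
    with open(path, "w", newline="") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, index=False)


def read_scores(path: str | Path):
    import pandas as pd
    return pd.read_csv(path, comment="#",
                       dtype={"patient_id": str, "category": str},
                       keep_default_na=False, na_values=[""])


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path,
                 provenance: Mapping[str, object] | None = None) -> dict:
    """Write a synthetic cohort as measurements/episodes/metadata CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = dict(provenance or {})
    prov.setdefault("seed", cohort.params.seed)
    prov.setdefault("config", cohort.config.name)
    prov.setdefault("config_hash", cohort.config.content_hash())
    paths = {
        "measurements": out / "measurements.csv",
        "episodes": out / "episodes.csv",
        "meta": out / "cohort_meta.csv",
    }
    write_scores(cohort.measurements_frame(), paths["measurements"], prov)
    write_scores(cohort.episodes_frame(), paths["episodes"], prov)
    write_scores(cohort.meta_frame(), paths["meta"], prov)
    return {k: str(v) for k, v in paths.items()}


def survival_analysis(scores_frame, episodes: Mapping[str, list[Episode]],
                      followup: Mapping[str, float],
                      blanking_days: float = DEFAULT_BLANKING_DAYS,
                      min_duration_s: float = DEFAULT_MIN_EPISODE_SECONDS
                      ) -> dict:
    """Derive survival records from scored patients + episode logs and run a
    stratified KM / log-rank analysis.

    Returns a JSON-serialisable summary: per-category step functions with
    Greenwood 95 % bands, 12-month KM incidence, crude recurrence
    proportions, and the log-rank test (marked not-applicable with fewer
    than two occupied categories).
    """
    records: list[SurvivalRecord] = []
    for row in scores_frame.itertuples(index=False):
        pid = row.patient_id
        if pid not in followup:
            raise SchemaError(f"patient {pid!r} missing from follow-up table")
        records.append(first_recurrence(
            episodes.get(pid, []), followup[pid],
            blanking_days=blanking_days, min_duration_s=min_duration_s,
            patient_id=pid, category=row.category))

    by_cat: dict[str, list[SurvivalRecord]] = {}
    for r in records:
        by_cat.setdefault(r.category, []).append(r)
    groups = {c: by_cat[c] for c in CATEGORIES if c in by_cat}

    summary: dict = {"blanking_days": blanking_days,
                     "min_episode_s": min_duration_s,
                     "n": len(records), "groups": {}}
    for cat, recs in groups.items():
        curve = km_estimate(recs)
        lo, hi = curve.confidence_band()
        summary["groups"][cat] = {
            "n": len(recs),
            "events": int(sum(r.event for r in recs)),
            "times": [round(float(t), 6) for t in curve.times],
            "survival": [round(float(s), 6) for s in curve.survival],
            "ci_low": [round(float(x), 6) for x in lo],
            "ci_high": [round(float(x), 6) for x in hi],
            "incidence_12mo": round(incidence_at(curve, 12.0), 6),
            "crude_recurrence": round(crude_recurrence(recs), 6),
        }
    if len(groups) >= 2:
        lr = logrank_test(groups)
        summary["logrank"] = {"statistic": round(lr.statistic, 6),
                              "df": lr.df,
                              "p_value": float(f"{lr.p_value:.6g}")}
    else:
        summary["logrank"] = None
    return summary


# -- run report -------------------------------------------------------------

REPORT_SCHEMA = {
    "required": {
        "n": int,
        "categories": dict,
        "logrank": (dict, type(None)),
        "calibration": (dict, type(None)),
        "provenance": dict,
    },
    "category_fields": {"n": int, "proportion": float,
                        "incidence_12mo": (float, type(None)),
                        "crude_recurrence": (float, type(None))},
}


def validate_report_summary(summary: Mapping) -> list[str]:
    """Structural check of a report-JSON summary; returns violations."""
    problems = []
    for key, typ in REPORT_SCHEMA["required"].items():
        if key not in summary:
            problems.append(f"missing key {key!r}")
        elif not isinstance(summary[key], typ):
            problems.append(f"key {key!r} has wrong type "
                            f"{type(summary[key]).__name__}")
    for cat, entry in (summary.get("categories") or {}).items():
        for key, typ in REPORT_SCHEMA["category_fields"].items():
            if key not in entry:
                problems.append(f"category {cat!r} missing {key!r}")
            elif not isinstance(entry[key], typ):
                problems.append(f"category {cat!r} field {key!r} wrong type")
    return problems


def run_report(scores_frame, survival_summary: Mapping | None = None,
               calibration: CalibrationReport | None = None,
               md_path: str | Path | None = None,
               json_path: str | Path | None = None,
               provenance: Mapping[str, object] | None = None) -> dict:
    """Assemble the human-readable report (markdown) and JSON summary."""
    n = len(scores_frame)
    counts = scores_frame["category"].value_counts().to_dict()
    categories = {}
    for cat in CATEGORIES:
        cnt = int(counts.get(cat, 0))
        entry = {"n": cnt, "proportion": round(cnt / n, 6) if n else 0.0,
                 "incidence_12mo": None, "crude_recurrence": None}
        g = (survival_summary or {}).get("groups", {}).get(cat)
        if g:
            entry["incidence_12mo"] = g["incidence_12mo"]
            entry["crude_recurrence"] = g["crude_recurrence"]
            entry["ci_12mo"] = _incidence_ci_at_12(g)
        categories[cat] = entry
    summary = {
        "n": n,
        "categories": categories,
        "logrank": (survival_summary or {}).get("logrank"),
        "calibration": calibration.to_dict() if calibration else None,
        "provenance": dict(provenance or {}),
    }
    problems = validate_report_summary(summary)
    if problems:  # pragma: no cover - internal consistency guard
        raise ConfigError("report summary failed self-check: "
                          + "; ".join(problems))
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    if md_path:
        with open(md_path, "w") as fh:
            fh.write(_render_markdown(summary))
    return summary


def _incidence_ci_at_12(group: Mapping) -> list[float] | None:
    times = group.get("times") or []
    idx = None
    for i, t in enumerate(times):
        if t <= 12.0:
            idx = i
    if idx is None:
        return None
    return [round(1.0 - group["ci_high"][idx], 6),
            round(1.0 - group["ci_low"][idx], 6)]


def _render_markdown(summary: Mapping) -> str:
    lines = ["# EASE run report", ""]
    prov = summary.get("provenance") or {}
    if prov:
        lines.append("Provenance: "
                     + ", ".join(f"{k}={v}" for k, v in prov.items()))
        lines.append("")
    lines.append(f"Patients scored: {summary['n']}")
    lines.append("")
    lines.append("| Category | n | % | 12-mo KM incidence | 95% CI | crude |")
    lines.append("|---|---|---|---|---|---|")
    for cat in CATEGORIES:
        e = summary["categories"][cat]
        inc = ("-" if e["incidence_12mo"] is None
               else f"{100 * e['incidence_12mo']:.1f}%")
        ci = e.get("ci_12mo")
        ci_s = ("-" if not ci
                else f"[{100 * ci[0]:.1f}%, {100 * ci[1]:.1f}%]")
        crude = ("-" if e["crude_recurrence"] is None
                 else f"{100 * e['crude_recurrence']:.1f}%")
        lines.append(f"| {cat} | {e['n']} | {100 * e['proportion']:.1f}% "
                     f"| {inc} | {ci_s} | {crude} |")
    lines.append("")
    lr = summary.get("logrank")
    if lr:
        lines.append(f"Log-rank test: chi2 = {lr['statistic']:.3f}, "
                     f"df = {lr['df']}, p = {lr['p_value']:.3g}")
    else:
        lines.append("Log-rank test: not applicable "
                     "(fewer than two occupied categories)")
    lines.append("")
    cal = summary.get("calibration")
    if cal:
        lines.append("## Calibration")
        lines.append("")
        lines.append("| Target | observed | target | check | pass |")
        lines.append("|---|---|---|---|---|")
        for t in cal["targets"]:
            obs = "undefined" if t["observed"] is None else f"{t['observed']:.4f}"
            check = {"abs": f"±{t['tolerance']}", "le": "<=",
                     "ge": ">="}[t["cmp"]]
            lines.append(f"| {t['name']} | {obs} | {t['target']:.4f} "
                         f"| {check} | {'yes' if t['passed'] else 'NO'} |")
        lines.append("")
    return "\n".join(lines) + "\n"
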