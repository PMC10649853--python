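"""Three-tier activity calling on a compound profile.

Tier 1 — single-dose *biomarker hits*: a readout strictly outside its
significance envelope whose effect size exceeds 20% (|log10 ratio| > 0.1).

Tier 2 — *dose-dependent annotated activities*: two or more consecutive
tested concentrations classified outside the envelope on the same side, with
at least one of them exceeding the effect-size threshold.  "Consecutive"
refers to adjacency on the tested dose grid; a concentration excluded for
broad cytotoxicity keeps its grid slot and breaks adjacency.

Tier 3 — viability flags: *cytotoxic* when a viability channel (SRB or
alamarBlue) drops below -0.3 log10 (a >50% loss of total protein/metabolic
signal), *antiproliferative* when a low-density proliferation-format readout
drops below -0.1.  One concentration suffices for either flag.  A dose that
is cytotoxic in three or more systems shows *broad cytotoxicity* and is
excluded from hit calling and annotation.

All comparators are strict; values exactly at a threshold do not qualify.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

from .data_io import CompoundProfile
from .envelope import EnvelopeSet, classify_value

__all__ = [
    "AnnotationConfig",
    "BiomarkerHit",
    "AnnotatedActivity",
    "CytotoxFlag",
    "call_hits",
    "annotate_activities",
    "flag_cytotoxicity",
    "apply_broad_cytotox_exclusion",
    "label_modulated",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationConfig:
    """Thresholds of the activity-calling rules (all on the log10-ratio scale)."""

    effect_size_threshold: float = 0.1
    min_consecutive: int = 2
    cytotox_threshold: float = -0.3
    antiproliferative_threshold: float = -0.1
    broad_cytotox_min_systems: int = 3
    #: whether viability channels (SRB/alamarBlue) are themselves eligible as
    #: hits/activities; the reference optimal-dose table lists "down SRB"
    #: entries, so they are included by default.
    include_viability_readouts: bool = True

    def __post_init__(self) -> None:
        if not self.effect_size_threshold > 0:
            raise ValueError("effect_size_threshold must be > 0")
        if self.min_consecutive < 2:
            raise ValueError("min_consecutive must be >= 2")
        if not (self.cytotox_threshold < self.antiproliferative_threshold < 0):
            raise ValueError("need cytotox_threshold < antiproliferative_threshold < 0")
        if self.broad_cytotox_min_systems < 1:
            raise ValueError("broad_cytotox_min_systems must be >= 1")


@dataclass(frozen=True)
class BiomarkerHit:
    """A single readout outside the envelope with a >20% effect size."""

    system: str
    biomarker: str
    dose: float
    direction: str
    log10_ratio: float


@dataclass(frozen=True)
class AnnotatedActivity:
    """A dose-dependent activity supported by a run of consecutive doses."""

    system: str
    biomarker: str
    direction: str
    supporting_doses: tuple[float, ...]
    max_abs_log10_ratio: float


@dataclass(frozen=True)
class CytotoxFlag:
    """A viability loss in one system at one dose."""

    system: str
    dose: float
    kind: str  # "cytotoxic" | "antiproliferative"


def _eligible_readouts(profile: CompoundProfile, cfg: AnnotationConfig):
    for system, biomarker in profile.readouts():
        if (
            not cfg.include_viability_readouts
            and profile.class_of(system, biomarker) == "viability"
        ):
            continue
        yield system, biomarker


def call_hits(
    profile: CompoundProfile, envelopes: EnvelopeSet, cfg: AnnotationConfig | None = None
) -> list[BiomarkerHit]:
    """Tier-1 hit calling: one hit per (system, biomarker, dose) satisfying
    both the envelope and the effect-size condition.  Excluded doses yield no
    hits."""
    cfg = cfg or AnnotationConfig()
    hits: list[BiomarkerHit] = []
    for system, biomarker in _eligible_readouts(profile, cfg):
        half_width = envelopes.get(system, biomarker).half_width
        for dose in profile.active_doses:
            value = profile.values[(system, biomarker, dose)]
            direction = classify_value(value, half_width)
            if direction != "inside" and abs(value) > cfg.effect_size_threshold:
                hits.append(BiomarkerHit(system, biomarker, dose, direction, value))
    return hits


def _runs(classes: list[str]) -> list[tuple[str, int, int]]:
    """Maximal runs of identical non-inside classes as (direction, start, stop)."""
    runs: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(classes) + 1):
        if i == len(classes) or classes[i] != classes[start]:
            if classes[start] in ("up", "down"):
                runs.append((classes[start], start, i))
            start = i
    return runs


def annotate_activities(
    profile: CompoundProfile, envelopes: EnvelopeSet, cfg: AnnotationConfig | None = None
) -> list[AnnotatedActivity]:
    """Tier-2 dose-dependent annotation.

    Per readout: classify every tested dose as up/down/inside (excluded doses
    break runs without contributing), find maximal runs of >= min_consecutive
    adjacent doses sharing one side of the envelope, and keep runs whose peak
    |log10 ratio| exceeds the effect-size threshold.  A 3-long qualifying run
    yields one activity, not two overlapping 2-long ones.  At most one
    activity per (system, biomarker, direction) is reported; if several
    disjoint runs in the same direction qualify (impossible on a 4-dose grid),
    the one with the larger peak wins, ties going to the lower doses.
    """
    cfg = cfg or AnnotationConfig()
    activities: list[AnnotatedActivity] = []
    for system, biomarker in _eligible_readouts(profile, cfg):
        half_width = envelopes.get(system, biomarker).half_width
        series = profile.series(system, biomarker)
        classes = [
            "excluded" if dose in profile.excluded_doses else classify_value(v, half_width)
            for dose, v in zip(profile.doses, series)
        ]
        best: dict[str, AnnotatedActivity] = {}
        for direction, start, stop in _runs(classes):
            if stop - start < cfg.min_consecutive:
                continue
            peak = max(abs(v) for v in series[start:stop])
            if not peak > cfg.effect_size_threshold:
                continue
            candidate = AnnotatedActivity(
                system, biomarker, direction, profile.doses[start:stop], peak
            )
            incumbent = best.get(direction)
            if incumbent is None or candidate.max_abs_log10_ratio > incumbent.max_abs_log10_ratio:
                best[direction] = candidate
        activities.extend(best[d] for d in ("up", "down") if d in best)
    return activities


def flag_cytotoxicity(
    profile: CompoundProfile, cfg: AnnotationConfig | None = None
) -> list[CytotoxFlag]:
    """Tier-3 viability flags; a single qualifying concentration suffices.

    Viability-class readouts (SRB/alamarBlue at plating density) gate the
    cytotoxic flag; proliferation-class readouts (cells plated at lower
    density) gate the antiproliferative flag.  A profile without viability
    readouts produces no cytotoxic flags (logged).
    """
    cfg = cfg or AnnotationConfig()
    flags: list[CytotoxFlag] = []
    has_viability = any(c == "viability" for c in profile.readout_class.values())
    if not has_viability:
        logger.info("%s: no viability-class readouts; no cytotoxicity flags", profile.compound)
    for system, biomarker in profile.readouts():
        rclass = profile.class_of(system, biomarker)
        if rclass == "viability":
            for dose in profile.doses:
                if profile.values[(system, biomarker, dose)] < cfg.cytotox_threshold:
                    flags.append(CytotoxFlag(system, dose, "cytotoxic"))
        elif rclass == "proliferation":
            for dose in profile.doses:
                if profile.values[(system, biomarker, dose)] < cfg.antiproliferative_threshold:
                    flags.append(CytotoxFlag(system, dose, "antiproliferative"))
    return flags


def apply_broad_cytotox_exclusion(
    profile: CompoundProfile,
    flags: list[CytotoxFlag],
    cfg: AnnotationConfig | None = None,
) -> tuple[CompoundProfile, list[float]]:
    """Exclude doses cytotoxic in >= broad_cytotox_min_systems distinct systems.

    Returns the profile with those doses marked excluded (they keep their
    grid slots, so a removed interior dose breaks run adjacency) and the
    sorted excluded-dose list.
    """
    cfg = cfg or AnnotationConfig()
    systems_by_dose: dict[float, set[str]] = defaultdict(set)
    for flag in flags:
        if flag.kind == "cytotoxic":
            systems_by_dose[flag.dose].add(flag.system)
    excluded = sorted(
        d for d, systems in systems_by_dose.items()
        if len(systems) >= cfg.broad_cytotox_min_systems
    )
    if not excluded:
        return profile, []
    out = profile.with_excluded(excluded)
    if not out.active_doses:
        logger.warning("%s: all doses excluded for broad cytotoxicity", profile.compound)
    return out, excluded


def label_modulated(activities: list[AnnotatedActivity]) -> set[str]:
    """Biomarkers annotated up in at least one system and down in another."""
    directions_by_marker: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for act in activities:
        directions_by_marker[act.biomarker].add((act.system, act.direction))
    out: set[str] = set()
    for biomarker, pairs in directions_by_marker.items():
        ups = {s for s, d in pairs if d == "up"}
        downs = {s for s, d in pairs if d == "down"}
        # up and down must come from *different* systems
        if any(u != v for u in ups for v in downs):
            out.add(biomarker)
    return out
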