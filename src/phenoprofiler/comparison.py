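"""Optimal doses, signed activity sets, and cross-compound overlap analysis.

The unit of comparison is the :class:`~phenoprofiler.data_io.SignedActivitySet`:
a compound's set of (system, canonical biomarker, direction) activities, built
either from dose-dependent annotations or from single-dose significant
activities at the compound's optimal dose.  Two compounds *share* an activity
only when system, canonical biomarker, and direction all agree — a biomarker
raised by one compound and lowered by the other is not a shared activity.

``reproduce_reference_report`` recomputes, from the packaged table
transcriptions, every overlap and summary claim printed in the reference
study, and labels each claim "pass" or "discrepancy".  The study's printed
tables are internally inconsistent in a few places (its grand totals exceed
its own per-system enumerations, and two stated overlap counts differ from
what its tables yield); those are reported as discrepancies, never silently
reconciled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .annotation import AnnotatedActivity
from .data_io import CellSystem, HitCountTable, SignedActivitySet, load_fixture, load_panel

__all__ = [
    "SharedActivityReport",
    "CompoundSummary",
    "optimal_dose",
    "activity_set_from_annotations",
    "shared_activities",
    "summarize_compound",
    "reproduce_reference_report",
    "REFERENCE_CLAIMS",
]


@dataclass(frozen=True)
class SharedActivityReport:
    """Direction-matched shared activities between two compounds."""

    compound_a: str
    compound_b: str
    dose_label_a: str
    dose_label_b: str
    matches: frozenset[tuple[str, str, str]]
    n_panel_systems: int

    @property
    def n_matches(self) -> int:
        return len(self.matches)

    @property
    def systems_with_matches(self) -> frozenset[str]:
        return frozenset(s for s, _, _ in self.matches)

    @property
    def systems_fraction(self) -> float:
        return len(self.systems_with_matches) / self.n_panel_systems

    @property
    def systems_percent(self) -> int:
        """Rounded to the nearest integer, matching the reference formatting."""
        return round(100.0 * self.systems_fraction)


@dataclass(frozen=True)
class CompoundSummary:
    """Activity count and system coverage for one compound."""

    compound: str
    n_activities: int
    n_systems: int
    systems_fraction: float

    @property
    def systems_percent(self) -> int:
        return round(100.0 * self.systems_fraction)


def optimal_dose(
    table: HitCountTable, tie_break: Literal["lowest", "highest"] = "lowest"
) -> float:
    """The tested concentration with the most biomarker hits.

    Ties go to the lowest dose by default (conservative dosing convention).
    """
    if not table.counts:
        raise ValueError(f"{table.compound}: empty hit-count table")
    best = max(table.counts.values())
    candidates = sorted(d for d, n in table.counts.items() if n == best)
    return candidates[0] if tie_break == "lowest" else candidates[-1]


def activity_set_from_annotations(
    activities: Iterable[AnnotatedActivity], compound: str, dose_label: str
) -> SignedActivitySet:
    """Collapse annotated activities to an order-free signed activity set."""
    entries = frozenset((a.system, a.biomarker, a.direction) for a in activities)
    return SignedActivitySet(compound, dose_label, entries)


def shared_activities(
    a: SignedActivitySet, b: SignedActivitySet, panel: list[CellSystem] | None = None
) -> SharedActivityReport:
    """Direction-matched intersection of two signed activity sets."""
    panel = panel if panel is not None else load_panel()
    return SharedActivityReport(
        compound_a=a.compound,
        compound_b=b.compound,
        dose_label_a=a.dose_label,
        dose_label_b=b.dose_label,
        matches=a.entries & b.entries,
        n_panel_systems=len(panel),
    )


def summarize_compound(
    activities: SignedActivitySet, panel: list[CellSystem] | None = None
) -> CompoundSummary:
    panel = panel if panel is not None else load_panel()
    return CompoundSummary(
        compound=activities.compound,
        n_activities=len(activities),
        n_systems=len(activities.systems),
        systems_fraction=len(activities.systems) / len(panel),
    )


# ---------------------------------------------------------------------------
# reference-claim reproduction
# ---------------------------------------------------------------------------

#: Claims printed in the reference study, transcribed as inputs to the
#: pass/discrepancy check.  "source" distinguishes the summary-table totals
#: (which include activities only shown in an unpublished appendix) from the
#: results-text overlap statements.
REFERENCE_CLAIMS: dict[str, dict] = {
    # grand totals and system coverage (summary table)
    "C15:0_total_activities": {"stated": 36, "source": "summary table"},
    "rapamycin_total_activities": {"stated": 32, "source": "summary table"},
    "metformin_total_activities": {"stated": 17, "source": "summary table"},
    "acarbose_total_activities": {"stated": 5, "source": "summary table"},
    "EPA_total_activities": {"stated": 7, "source": "summary table"},
    "C15:0_active_systems": {"stated": 10, "source": "summary table"},
    "rapamycin_active_systems": {"stated": 12, "source": "summary table"},
    "metformin_active_systems": {"stated": 7, "source": "summary table"},
    "acarbose_active_systems": {"stated": 3, "source": "summary table"},
    "EPA_active_systems": {"stated": 4, "source": "summary table"},
    # optimal doses (hit-count table)
    "C15:0_optimal_dose_uM": {"stated": 17, "source": "hit-count table"},
    "rapamycin_optimal_dose_uM": {"stated": 9, "source": "hit-count table"},
    "metformin_optimal_dose_uM": {"stated": 5000, "source": "hit-count table"},
    "acarbose_optimal_dose_uM": {"stated": 30, "source": "hit-count table"},
    # dose-dependent overlaps (results text)
    "C15:0_rapamycin_dd_shared_activities": {"stated": 12, "source": "results text"},
    "C15:0_rapamycin_dd_shared_systems": {"stated": 7, "source": "results text"},
    "C15:0_metformin_dd_shared_activities": {"stated": 4, "source": "results text"},
    "C15:0_metformin_dd_shared_systems": {"stated": 2, "source": "results text"},
    "C15:0_acarbose_dd_shared_activities": {"stated": 1, "source": "results text"},
    # optimal-dose overlaps (results text)
    "C15:0_rapamycin_optimal_shared_activities": {"stated": 24, "source": "results text"},
    "C15:0_rapamycin_optimal_shared_systems": {"stated": 10, "source": "results text"},
    "C15:0_metformin_optimal_shared_activities": {"stated": 11, "source": "results text"},
    "C15:0_metformin_optimal_shared_systems": {"stated": 5, "source": "results text"},
}


def _claim(computed) -> dict:
    return {"computed": computed}


def reproduce_reference_report() -> dict:
    """Recompute every reference claim from the packaged table transcriptions.

    Returns ``{"claims": {name: {stated, computed, status, source}},
    "n_pass": int, "n_discrepancy": int}``.  ``status`` is "pass" when the
    recomputed value equals the printed claim and "discrepancy" otherwise;
    known internal inconsistencies of the printed tables surface here as
    discrepancies by design.
    """
    panel = load_panel()
    table2 = load_fixture("table2")
    table3 = load_fixture("table3")
    table4 = load_fixture("table4")

    computed: dict[str, float | int] = {}

    for compound, activity_set in table2.items():
        summary = summarize_compound(activity_set, panel)
        computed[f"{compound}_total_activities"] = summary.n_activities
        computed[f"{compound}_active_systems"] = summary.n_systems
    for compound, hit_table in table3.items():
        computed[f"{compound}_optimal_dose_uM"] = optimal_dose(hit_table)

    dd_rapa = shared_activities(table2["C15:0"], table2["rapamycin"], panel)
    dd_met = shared_activities(table2["C15:0"], table2["metformin"], panel)
    dd_aca = shared_activities(table2["C15:0"], table2["acarbose"], panel)
    computed["C15:0_rapamycin_dd_shared_activities"] = dd_rapa.n_matches
    computed["C15:0_rapamycin_dd_shared_systems"] = len(dd_rapa.systems_with_matches)
    computed["C15:0_metformin_dd_shared_activities"] = dd_met.n_matches
    computed["C15:0_metformin_dd_shared_systems"] = len(dd_met.systems_with_matches)
    computed["C15:0_acarbose_dd_shared_activities"] = dd_aca.n_matches

    opt_rapa = shared_activities(table4["C15:0"], table4["rapamycin"], panel)
    opt_met = shared_activities(table4["C15:0"], table4["metformin"], panel)
    computed["C15:0_rapamycin_optimal_shared_activities"] = opt_rapa.n_matches
    computed["C15:0_rapamycin_optimal_shared_systems"] = len(opt_rapa.systems_with_matches)
    computed["C15:0_metformin_optimal_shared_activities"] = opt_met.n_matches
    computed["C15:0_metformin_optimal_shared_systems"] = len(opt_met.systems_with_matches)

    claims: dict[str, dict] = {}
    n_pass = n_disc = 0
    for name, ref in REFERENCE_CLAIMS.items():
        value = computed[name]
        status = "pass" if value == ref["stated"] else "discrepancy"
        n_pass += status == "pass"
        n_disc += status == "discrepancy"
        claims[name] = {
            "stated": ref["stated"],
            "computed": value,
            "status": status,
            "source": ref["source"],
        }
    return {"claims": claims, "n_pass": n_pass, "n_discrepancy": n_disc}
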