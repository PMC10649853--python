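"""Data model and tabular I/O for phenotypic-profiling panels.

The central container is :class:`CompoundProfile`: for one compound, the
log10 ratio of every (cell system, biomarker) readout at every tested
concentration, relative to vehicle controls.  All downstream rules (envelope
classification, hit calling, dose-dependent annotation) operate on this
log10-ratio scale; no raw-signal processing happens in this package.

Also here: historical vehicle-control tables, signed activity sets (the unit
of cross-compound comparison), per-dose hit-count tables, biomarker-name
canonicalization, and loaders for the packaged transcriptions of the
reference study's printed summary tables.
"""

from __future__ import annotations

import csv
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CellSystem",
    "CompoundProfile",
    "VehicleControlSet",
    "SignedActivitySet",
    "HitCountTable",
    "ProfileParseError",
    "canonical_system",
    "canonical_biomarker",
    "load_panel",
    "panel_ids",
    "read_profile_table",
    "write_profile_table",
    "read_controls_table",
    "write_controls_table",
    "load_fixture",
]

PROFILE_COLUMNS = ("compound", "system", "biomarker", "readout_class", "dose_uM", "log10_ratio")
CONTROL_COLUMNS = ("system", "biomarker", "log10_ratio")
ACTIVITY_COLUMNS = ("compound", "dose_label", "system", "biomarker", "direction")

READOUT_CLASSES = frozenset({"soluble", "cell_associated", "proliferation", "viability"})
DIRECTIONS = frozenset({"up", "down"})

#: Qualified canonical names for the proliferation readout of each system that
#: runs a low-density proliferation format; a bare "proliferation" (or "cell
#: proliferation") in one of these systems resolves to the qualified name.
PROLIFERATION_BY_SYSTEM: Mapping[str, str] = {
    "3C": "endothelial cell proliferation",
    "4H": "endothelial cell proliferation",
    "SAg": "T cell proliferation",
    "BT": "B cell proliferation",
    "CASM3C": "coronary artery proliferation",
    "HDF3CGF": "fibroblast proliferation",
}


class ProfileParseError(ValueError):
    """Malformed profile/control table; the message names the offending line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellSystem:
    """One stimulated primary-cell (co-)culture context of the panel."""

    id: str
    description: str = ""
    disease_relevance: str = ""


@dataclass
class VehicleControlSet:
    """Historical vehicle-control log10 ratios, per (system, biomarker)."""

    samples: dict[tuple[str, str], list[float]] = field(default_factory=dict)

    def add(self, system: str, biomarker: str, value: float) -> None:
        self.samples.setdefault((system, biomarker), []).append(float(value))

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class CompoundProfile:
    """Dose x system x biomarker matrix of log10 ratios for one compound.

    ``doses`` is the full ascending tested grid; ``excluded_doses`` marks
    concentrations removed by broad-cytotoxicity exclusion.  An excluded dose
    keeps its grid position (so a removed interior dose breaks consecutiveness
    for run-based annotation) but contributes no hits or supporting doses.
    """

    compound: str
    doses: tuple[float, ...]
    values: dict[tuple[str, str, float], float]
    readout_class: dict[tuple[str, str], str] = field(default_factory=dict)
    excluded_doses: frozenset[float] = frozenset()

    def __post_init__(self) -> None:
        self.doses = tuple(float(d) for d in self.doses)
        if len(self.doses) < 2:
            raise ValueError(f"{self.compound}: need >= 2 doses, got {len(self.doses)}")
        if any(b >= a for b, a in zip(self.doses, self.doses[1:])):
            raise ValueError(f"{self.compound}: doses must be strictly ascending: {self.doses}")
        for key in self.readouts():
            self.readout_class.setdefault(key, "soluble")
        missing = [
            (s, b, d)
            for (s, b) in self.readouts()
            for d in self.doses
            if (s, b, d) not in self.values
        ]
        if missing:
            raise ValueError(
                f"{self.compound}: {len(missing)} missing dose values, e.g. {missing[0]}"
            )

    def readouts(self) -> list[tuple[str, str]]:
        """Sorted distinct (system, biomarker) pairs present in the profile."""
        return sorted({(s, b) for (s, b, _) in self.values})

    def series(self, system: str, biomarker: str) -> list[float]:
        """Values for one readout in ascending-dose order (full grid)."""
        return [self.values[(system, biomarker, d)] for d in self.doses]

    def class_of(self, system: str, biomarker: str) -> str:
        return self.readout_class.get((system, biomarker), "soluble")

    def with_excluded(self, doses: Iterable[float]) -> "CompoundProfile":
        return CompoundProfile(
            compound=self.compound,
            doses=self.doses,
            values=dict(self.values),
            readout_class=dict(self.readout_class),
            excluded_doses=self.excluded_doses | frozenset(float(d) for d in doses),
        )

    @property
    def active_doses(self) -> tuple[float, ...]:
        return tuple(d for d in self.doses if d not in self.excluded_doses)


@dataclass(frozen=True)
class SignedActivitySet:
    """A compound's set of (system, canonical biomarker, direction) activities.

    Order-free set semantics; the unit of cross-compound overlap analysis.
    Opposite directions for the same (system, biomarker) are allowed (a
    U-shaped response crossing zero yields both) but never occur in the
    packaged table transcriptions.
    """

    compound: str
    dose_label: str
    entries: frozenset[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for _, _, direction in self.entries:
            if direction not in DIRECTIONS:
                raise ValueError(f"bad direction {direction!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def systems(self) -> frozenset[str]:
        return frozenset(s for s, _, _ in self.entries)

    def in_system(self, system: str) -> frozenset[tuple[str, str, str]]:
        return frozenset(e for e in self.entries if e[0] == system)

    def conflicting_pairs(self) -> set[tuple[str, str]]:
        """(system, biomarker) pairs listed with both directions."""
        seen: dict[tuple[str, str], set[str]] = defaultdict(set)
        for s, b, d in self.entries:
            seen[(s, b)].add(d)
        return {k for k, v in seen.items() if len(v) > 1}


@dataclass(frozen=True)
class HitCountTable:
    """Per-dose biomarker hit counts for one compound."""

    compound: str
    counts: Mapping[float, int]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", {float(d): int(n) for d, n in sorted(self.counts.items())}
        )
        if any(n < 0 for n in self.counts.values()):
            raise ValueError(f"{self.compound}: negative hit count")


# ---------------------------------------------------------------------------
# name canonicalization
# ---------------------------------------------------------------------------


def _fold(name: str) -> str:
    return "".join(ch for ch in name.casefold() if ch not in " -_\t")


def _load_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}
    with _fixture_path("biomarker_synonyms.tsv").open(encoding="utf-8") as fh:
        for row in _tsv_rows(fh, ("variant", "canonical"))[0]:
            table[_fold(row["variant"])] = row["canonical"]
            # canonical forms map to themselves, making lookup idempotent
            table.setdefault(_fold(row["canonical"]), row["canonical"])
    return table


def canonical_system(raw: str) -> str:
    """Canonical panel system id; '/Mphg' (table spelling) folds to 'lMphg'."""
    name = raw.strip()
    return "lMphg" if name in {"/Mphg", "lMphg", "Mphg"} else name


def canonical_biomarker(raw: str, system: str | None = None) -> str:
    """Deterministic canonical identifier for a biomarker name.

    Resolves the synonym dictionary after case/hyphen/whitespace folding; a
    bare "proliferation" is qualified by its system's proliferation format
    when known.  Unknown names pass through with whitespace collapsed (a
    warning is emitted), so the mapping is total and idempotent.
    """
    if not raw or not raw.strip():
        raise ValueError("empty biomarker name")
    name = " ".join(raw.split())
    key = _fold(name)
    if key in {"proliferation", "cellproliferation"} and system is not None:
        qualified = PROLIFERATION_BY_SYSTEM.get(canonical_system(system))
        if qualified is not None:
            return qualified
    synonyms = _synonym_table()
    if key in synonyms:
        return synonyms[key]
    if key not in _known_passthrough():
        warnings.warn(f"unknown biomarker name {name!r}: passing through", stacklevel=2)
        _known_passthrough().add(key)
    return name


_SYNONYMS: dict[str, str] | None = None
_PASSTHROUGH: set[str] = set()


def _synonym_table() -> dict[str, str]:
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    return _SYNONYMS


def _known_passthrough() -> set[str]:
    return _PASSTHROUGH


# ---------------------------------------------------------------------------
# low-level TSV helpers
# ---------------------------------------------------------------------------


def _tsv_rows(
    fh: Iterable[str], columns: Sequence[str]
) -> tuple[list[dict[str, str]], list[int]]:
    """Parse a commented TSV with a fixed header; returns rows + line numbers."""
    reader = csv.reader(fh, delimiter="\t")
    header: list[str] | None = None
    rows: list[dict[str, str]] = []
    linenos: list[int] = []
    for lineno, row in enumerate(reader, start=1):
        if not row or (row[0].startswith("#")):
            continue
        if header is None:
            header = [c.strip() for c in row]
            if header != list(columns):
                raise ProfileParseError(
                    f"line {lineno}: expected header {list(columns)}, got {header}"
                )
            continue
        if len(row) != len(columns):
            raise ProfileParseError(
                f"line {lineno}: expected {len(columns)} fields, got {len(row)}"
            )
        rows.append({c: v.strip() for c, v in zip(columns, row)})
        linenos.append(lineno)
    if header is None:
        raise ProfileParseError("missing header line")
    return rows, linenos


def _parse_float(text: str, lineno: int, what: str) -> float:
    try:
        value = float(text)
    except ValueError:
        raise ProfileParseError(f"line {lineno}: non-numeric {what}: {text!r}") from None
    if value != value or value in (float("inf"), float("-inf")):
        raise ProfileParseError(f"line {lineno}: non-finite {what}: {text!r}")
    return value


# ---------------------------------------------------------------------------
# profile and control tables
# ---------------------------------------------------------------------------


def read_profile_table(
    path: str | Path, *, strict_systems: bool = False, canonicalize: bool = True
) -> CompoundProfile:
    """Read one compound's profile from the documented TSV format.

    One row per readout per dose; duplicate (system, biomarker, dose) rows are
    an error naming the line.  Doses may appear in any order in the file; the
    returned profile is always on the ascending grid.  With ``strict_systems``
    a system id outside the 12-system panel is an error.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        try:
            rows, linenos = _tsv_rows(fh, PROFILE_COLUMNS)
        except ProfileParseError as err:
            raise ProfileParseError(f"{path}: {err}") from None

    if not rows:
        raise ProfileParseError(f"{path}: no data rows")
    compound = rows[0]["compound"]
    values: dict[tuple[str, str, float], float] = {}
    classes: dict[tuple[str, str], str] = {}
    known = set(panel_ids())
    for row, lineno in zip(rows, linenos):
        if row["compound"] != compound:
            raise ProfileParseError(
                f"{path}: line {lineno}: mixed compounds {compound!r} and {row['compound']!r}"
            )
        system = canonical_system(row["system"])
        if strict_systems and system not in known:
            raise ProfileParseError(f"{path}: line {lineno}: unknown system id {row['system']!r}")
        biomarker = (
            canonical_biomarker(row["biomarker"], system) if canonicalize else row["biomarker"]
        )
        rclass = row["readout_class"]
        if rclass not in READOUT_CLASSES:
            raise ProfileParseError(f"{path}: line {lineno}: unknown readout_class {rclass!r}")
        dose = _parse_float(row["dose_uM"], lineno, "dose_uM")
        ratio = _parse_float(row["log10_ratio"], lineno, "log10_ratio")
        key = (system, biomarker, dose)
        if key in values:
            raise ProfileParseError(
                f"{path}: line {lineno}: duplicate row for ({system}, {biomarker}, {dose:g})"
            )
        prev = classes.setdefault((system, biomarker), rclass)
        if prev != rclass:
            raise ProfileParseError(
                f"{path}: line {lineno}: readout_class of ({system}, {biomarker}) "
                f"changed from {prev!r} to {rclass!r}"
            )
        values[key] = ratio

    doses = tuple(sorted({d for (_, _, d) in values}))
    try:
        return CompoundProfile(compound, doses, values, classes)
    except ValueError as err:
        raise ProfileParseError(f"{path}: {err}") from None


def write_profile_table(profile: CompoundProfile, path: str | Path) -> None:
    """Write a profile in the documented TSV format (round-trips exactly)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PROFILE_COLUMNS)
        for system, biomarker in profile.readouts():
            for dose in profile.doses:
                writer.writerow(
                    [
                        profile.compound,
                        system,
                        biomarker,
                        profile.class_of(system, biomarker),
                        repr(dose),
                        repr(profile.values[(system, biomarker, dose)]),
                    ]
                )


def read_controls_table(path: str | Path, *, canonicalize: bool = True) -> VehicleControlSet:
    """Read historical vehicle-control replicates (one row per replicate)."""
    path = Path(path)
    controls = VehicleControlSet()
    with path.open(encoding="utf-8") as fh:
        try:
            rows, linenos = _tsv_rows(fh, CONTROL_COLUMNS)
        except ProfileParseError as err:
            raise ProfileParseError(f"{path}: {err}") from None
    for row, lineno in zip(rows, linenos):
        system = canonical_system(row["system"])
        biomarker = (
            canonical_biomarker(row["biomarker"], system) if canonicalize else row["biomarker"]
        )
        controls.add(system, biomarker, _parse_float(row["log10_ratio"], lineno, "log10_ratio"))
    return controls


def write_controls_table(controls: VehicleControlSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CONTROL_COLUMNS)
        for (system, biomarker), samples in sorted(controls.samples.items()):
            for value in samples:
                writer.writerow([system, biomarker, repr(value)])


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("table2", "table3", "table4")
_FIXTURE_FILES = {
    "table2": "table2_dose_dependent.tsv",
    "table3": "table3_hit_counts.tsv",
    "table4": "table4_optimal_dose.tsv",
}


def _fixture_path(filename: str):
    return resources.files("phenoprofiler").joinpath("fixtures", filename)


def load_panel() -> list[CellSystem]:
    """The 12-system reference panel with descriptions."""
    with _fixture_path("systems.tsv").open(encoding="utf-8") as fh:
        rows, _ = _tsv_rows(fh, ("id", "description", "disease_relevance"))
    systems = [CellSystem(r["id"], r["description"], r["disease_relevance"]) for r in rows]
    ids = [s.id for s in systems]
    if len(set(ids)) != len(ids):
        raise ProfileParseError("duplicate system ids in panel fixture")
    return systems


def panel_ids() -> tuple[str, ...]:
    return tuple(s.id for s in load_panel())


def load_fixture(name: str) -> dict[str, SignedActivitySet] | dict[str, HitCountTable]:
    """Load a packaged transcription of one of the reference summary tables.

    ``table2`` (dose-dependent annotated activities) and ``table4``
    (optimal-dose significant activities) return ``{compound:
    SignedActivitySet}`` with systems and biomarkers canonicalized; ``table3``
    (per-dose hit counts) returns ``{compound: HitCountTable}``.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    filename = _FIXTURE_FILES[name]
    with _fixture_path(filename).open(encoding="utf-8") as fh:
        if name == "table3":
            rows, linenos = _tsv_rows(fh, ("compound", "dose_uM", "hits"))
            counts: dict[str, dict[float, int]] = defaultdict(dict)
            for row, lineno in zip(rows, linenos):
                dose = _parse_float(row["dose_uM"], lineno, "dose_uM")
                counts[row["compound"]][dose] = int(row["hits"])
            return {c: HitCountTable(c, t) for c, t in counts.items()}

        rows, _ = _tsv_rows(fh, ACTIVITY_COLUMNS)
    grouped: dict[str, set[tuple[str, str, str]]] = defaultdict(set)
    labels: dict[str, str] = {}
    for row in rows:
        system = canonical_system(row["system"])
        entry = (system, canonical_biomarker(row["biomarker"], system), row["direction"])
        grouped[row["compound"]].add(entry)
        labels[row["compound"]] = row["dose_label"]
    out: dict[str, SignedActivitySet] = {}
    for compound, entries in grouped.items():
        activity_set = SignedActivitySet(compound, labels[compound], frozenset(entries))
        conflicts = activity_set.conflicting_pairs()
        if conflicts:
            raise ProfileParseError(
                f"fixture {name}: conflicting directions for {sorted(conflicts)}"
            )
        out[compound] = activity_set
    return out
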