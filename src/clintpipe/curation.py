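"""Rule-based curation of CL_int measurement entries.

Two parallel pipelines are built from the same entry stream:

* **non_curated** — basic filtering (value present, HLM sample, CL_int unit)
  followed by naive automatic unit conversion trusting the recorded unit,
  then per-compound class resolution.  This is what a purely automatic
  database export produces, including its characteristic failure mode: a
  per-mg-microsome value recorded under a per-g-liver unit inflates by
  1000/45 (42 -> 933.3 uL/min/mg) and the compound drifts into the unstable
  class.
* **curated** — additionally enforces the assay protocol (37 C, pH 7.4, no
  inhibitors, NADPH cofactor) and cross-checks each recorded value/unit
  against the original-publication record, recomputing mis-converted values
  and replacing transcription errors before resolution.

Every input entry ends in exactly one terminal CurationAction per mode, so
ledger counts always reconcile with the input count.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from statistics import geometric_mean
from typing import Iterable, Sequence

from .io_chem import MeasurementEntry, CompoundRecord, canonical_smiles
from .pk_model import (
    STABLE_CUTOFF,
    UNSTABLE_CUTOFF,
    StabilityClass,
    UnitConversionError,
    convert_units,
)

__all__ = [
    "CurationAction",
    "CurationConfig",
    "CurationResult",
    "filter_basic",
    "filter_protocol",
    "cross_check",
    "classes_consistent_with",
    "resolve_compound",
    "build_datasets",
]

_ALL_CLASSES = frozenset({StabilityClass.STABLE, StabilityClass.MODERATE, StabilityClass.UNSTABLE})


@dataclass(frozen=True)
class CurationAction:
    """Terminal disposition of one entry in one pipeline mode."""

    entry_id: str
    action: str  # kept | protocol_rejected | unit_rejected | value_replaced |
    #              unit_recalculated | qualifier_removed | ambiguity_removed
    reason: str = ""
    old_value: float | None = None
    new_value: float | None = None


@dataclass(frozen=True)
class CurationConfig:
    """Protocol requirements and cutoffs for a curation run."""

    mode: str = "curated"  # curated | non_curated
    required_temperature_C: float = 37.0
    temperature_tol: float = 0.5
    required_pH: float = 7.4
    ph_tol: float = 0.05
    required_cofactor: str = "NADPH"
    required_sample_type: str = "HLM"
    stable_cutoff: float = STABLE_CUTOFF
    unstable_cutoff: float = UNSTABLE_CUTOFF
    value_match_rtol: float = 0.01  # relative tolerance before value_replaced fires
    missing_protocol_policy: str = "strict"  # strict: missing field -> rejected

    def __post_init__(self) -> None:
        if self.mode not in {"curated", "non_curated"}:
            raise ValueError(f"unknown curation mode {self.mode!r}")
        if self.missing_protocol_policy not in {"strict", "lenient"}:
            raise ValueError(f"unknown missing_protocol_policy {self.missing_protocol_policy!r}")


@dataclass
class CurationResult:
    """Curated compound set plus the full per-entry action ledger."""

    mode: str
    records: list[CompoundRecord]
    ledger: list[CurationAction]
    unverifiable_entry_ids: list[str] = field(default_factory=list)

    @property
    def n_input_entries(self) -> int:
        return len(self.ledger)

    def action_counts(self) -> dict[str, int]:
        counts: dict[str, int] = defaultdict(int)
        for a in self.ledger:
            counts[a.action] += 1
        return dict(counts)


def filter_basic(
    entries: Sequence[MeasurementEntry], config: CurationConfig
) -> tuple[list[MeasurementEntry], list[CurationAction]]:
    """Reject entries lacking a value, off-sample, or with non-CL_int units."""
    kept: list[MeasurementEntry] = []
    rejected: list[CurationAction] = []
    for e in entries:
        if e.value is None:
            rejected.append(CurationAction(e.entry_id, "unit_rejected", "missing experimental value"))
        elif e.sample_type.upper() != config.required_sample_type.upper():
            rejected.append(
                CurationAction(e.entry_id, "unit_rejected", f"sample type {e.sample_type!r} is not {config.required_sample_type}")
            )
        elif not e.unit.recognised:
            rejected.append(CurationAction(e.entry_id, "unit_rejected", f"non-CLint unit {e.unit.unit!r}"))
        else:
            kept.append(e)
    return kept, rejected


def _protocol_violation(e: MeasurementEntry, config: CurationConfig) -> str | None:
    strict = config.missing_protocol_policy == "strict"
    if e.temperature_C is None:
        if strict:
            return "temperature not recorded"
    elif abs(e.temperature_C - config.required_temperature_C) > config.temperature_tol:
        return f"temperature {e.temperature_C} C != {config.required_temperature_C} C"
    if e.pH is None:
        if strict:
            return "pH not recorded"
    elif abs(e.pH - config.required_pH) > config.ph_tol:
        return f"pH {e.pH} != {config.required_pH}"
    if e.inhibitor_present is None:
        if strict:
            return "inhibitor status not recorded"
    elif e.inhibitor_present:
        return "inhibitor present"
    if e.cofactor is None:
        if strict:
            return "cofactor not recorded"
    elif config.required_cofactor.upper() not in e.cofactor.upper():
        return f"cofactor {e.cofactor!r} lacks {config.required_cofactor}"
    return None


def filter_protocol(
    entries: Sequence[MeasurementEntry], config: CurationConfig
) -> tuple[list[MeasurementEntry], list[CurationAction]]:
    """Enforce 37 C / pH 7.4 / no inhibitors / NADPH (curated mode only)."""
    kept: list[MeasurementEntry] = []
    rejected: list[CurationAction] = []
    for e in entries:
        violation = _protocol_violation(e, config)
        if violation is None:
            kept.append(e)
        else:
            rejected.append(CurationAction(e.entry_id, "protocol_rejected", violation))
    return kept, rejected


def cross_check(
    entry: MeasurementEntry, config: CurationConfig
) -> tuple[MeasurementEntry, CurationAction | None, bool]:
    """Cross-check one entry against its original-publication record.

    Returns ``(entry, action, unverifiable)``.  If the recorded unit differs
    from the source unit, the value is recomputed from the source record
    (action ``unit_recalculated``); if units agree but values disagree beyond
    the relative tolerance, the source value is adopted (``value_replaced``).
    ``action`` is None when the entry is kept unchanged; ``unverifiable`` is
    True when no source record exists to check against.
    """
    if entry.source_value is None or entry.source_unit is None:
        return entry, None, True
    if entry.unit.basis != entry.source_unit.basis:
        corrected = entry.with_value(entry.source_value, entry.source_unit)
        action = CurationAction(
            entry.entry_id,
            "unit_recalculated",
            f"recorded unit {entry.unit.unit!r} differs from source unit {entry.source_unit.unit!r}",
            old_value=entry.value,
            new_value=entry.source_value,
        )
        return corrected, action, False
    denom = max(abs(entry.source_value), 1e-30)
    if abs((entry.value or 0.0) - entry.source_value) / denom > config.value_match_rtol:
        corrected = entry.with_value(entry.source_value, entry.source_unit)
        action = CurationAction(
            entry.entry_id,
            "value_replaced",
            "recorded value disagrees with the original publication",
            old_value=entry.value,
            new_value=entry.source_value,
        )
        return corrected, action, False
    return entry, None, False


def classes_consistent_with(
    qualifier: str, clint: float, config: CurationConfig
) -> frozenset[StabilityClass]:
    """Classes a (possibly bounded) normalized CL_int value could belong to.

    An ``=`` entry pins a single class; an inequality contributes the set of
    classes its half-line intersects, e.g. ">20" -> {moderate, unstable} but
    ">=300" -> {unstable}.
    """
    lo, hi = config.stable_cutoff, config.unstable_cutoff
    if qualifier == "=":
        if clint < lo:
            return frozenset({StabilityClass.STABLE})
        if clint < hi:
            return frozenset({StabilityClass.MODERATE})
        return frozenset({StabilityClass.UNSTABLE})
    # Which class intervals [0,lo), [lo,hi), [hi,inf) does the half-line meet?
    out: set[StabilityClass] = set()
    if qualifier in {">", ">="}:
        if clint < lo:
            out.add(StabilityClass.STABLE)
        if clint < hi:
            out.add(StabilityClass.MODERATE)
        out.add(StabilityClass.UNSTABLE)
        return frozenset(out)
    if qualifier in {"<", "<="}:
        closed = qualifier == "<="
        if clint > 0 or closed:  # "<0" is an empty bound
            out.add(StabilityClass.STABLE)
        if clint > lo or (closed and clint >= lo):
            out.add(StabilityClass.MODERATE)
        if clint > hi or (closed and clint >= hi):
            out.add(StabilityClass.UNSTABLE)
        return frozenset(out)
    raise ValueError(f"unknown qualifier {qualifier!r}")


def resolve_compound(
    entries: Sequence[tuple[MeasurementEntry, float]], config: CurationConfig
) -> tuple[StabilityClass | None, float | None, str]:
    """Resolve one compound's unit-normalized entries to a class, or remove it.

    ``entries`` pairs each surviving entry with its normalized CL_int in
    uL/min/mg.  Each entry contributes the set of classes consistent with its
    value and qualifier; the compound is kept iff the intersection of those
    sets is a single class.  Returns ``(stability, representative_clint,
    reason)``; stability None means removal with the reason given.  The
    representative CL_int is the geometric mean of the exact-valued entries
    (only the class matters downstream).
    """
    if not entries:
        return None, None, "no classifiable entries"
    sets = [classes_consistent_with(e.qualifier, clint, config) for e, clint in entries]
    common = frozenset(_ALL_CLASSES)
    for s in sets:
        common = common & s
    if len(common) != 1:
        if len(common) == 0:
            return None, None, "entries belong to more than one category"
        return None, None, "qualifier bound does not pin a single category"
    cls = next(iter(common))
    exact = [clint for e, clint in entries if e.qualifier == "="]
    if exact:
        rep = geometric_mean([max(v, 1e-12) for v in exact])
    else:
        rep = entries[0][1]  # qualifier-only compound: the bound value itself
    return cls, rep, ""


def _naive_convert(
    entries: Sequence[MeasurementEntry],
) -> tuple[list[tuple[MeasurementEntry, float]], list[CurationAction]]:
    converted: list[tuple[MeasurementEntry, float]] = []
    rejected: list[CurationAction] = []
    for e in entries:
        try:
            converted.append((e, convert_units(e.value, e.unit)))
        except UnitConversionError as exc:
            rejected.append(CurationAction(e.entry_id, "unit_rejected", exc.reason))
    return converted, rejected


def build_datasets(
    entries: Sequence[MeasurementEntry], config: CurationConfig
) -> CurationResult:
    """Run the full pipeline for one mode and return records plus ledger.

    non_curated: basic filter -> naive conversion -> per-compound resolution.
    curated: basic filter -> protocol filter -> source cross-check -> naive
    conversion of the (possibly corrected) value -> resolution.
    """
    ledger: list[CurationAction] = []
    unverifiable: list[str] = []

    kept, rejected = filter_basic(entries, config)
    ledger.extend(rejected)

    if config.mode == "curated":
        kept, rejected = filter_protocol(kept, config)
        ledger.extend(rejected)
        checked: list[MeasurementEntry] = []
        correction_by_id: dict[str, CurationAction] = {}
        for e in kept:
            e2, action, unv = cross_check(e, config)
            checked.append(e2)
            if action is not None:
                correction_by_id[e2.entry_id] = action
            if unv:
                unverifiable.append(e.entry_id)
        kept = checked
    else:
        correction_by_id = {}

    converted, rejected = _naive_convert(kept)
    ledger.extend(rejected)

    by_compound: dict[str, list[tuple[MeasurementEntry, float]]] = defaultdict(list)
    smiles_by_compound: dict[str, str] = {}
    for e, clint in converted:
        by_compound[e.compound_id].append((e, clint))
        smiles_by_compound.setdefault(e.compound_id, e.smiles)

    records: list[CompoundRecord] = []
    for cid in sorted(by_compound):
        group = by_compound[cid]
        cls, rep, reason = resolve_compound(group, config)
        if cls is None:
            for e, _ in group:
                corr = correction_by_id.pop(e.entry_id, None)
                ledger.append(
                    CurationAction(e.entry_id, "ambiguity_removed", reason,
                                   old_value=corr.old_value if corr else None,
                                   new_value=corr.new_value if corr else None)
                )
            continue
        for e, _ in group:
            corr = correction_by_id.pop(e.entry_id, None)
            if corr is not None:
                ledger.append(corr)
            else:
                ledger.append(CurationAction(e.entry_id, "kept", ""))
        can = canonical_smiles(smiles_by_compound[cid])
        records.append(
            CompoundRecord(
                compound_id=cid,
                smiles=can if can is not None else smiles_by_compound[cid],
                clint=rep,
                stability=cls,
            )
        )

    result = CurationResult(mode=config.mode, records=records, ledger=ledger, unverifiable_entry_ids=unverifiable)
    if len(ledger) != len(entries):
        raise AssertionError(
            f"ledger conservation violated: {len(ledger)} actions for {len(entries)} entries"
        )
    if not records:
        import warnings

        warnings.warn(f"curation in mode {config.mode!r} produced an empty dataset", stacklevel=2)
    return result
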