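"""Readers and writers for entry tables, structures and labelled datasets.

Entry tables are CSV/TSV exports in the style of open ADME databases: one row
per CL_int measurement with unit, qualifier and assay-protocol metadata plus
the original-publication value used for cross-checking.  Column names are
mapped through a config-declared dictionary rather than hard-coded, so both
real exports and synthetic tables parse.  Structures move through SDF (V2000)
or SMILES files via RDKit; labelled datasets round-trip as SDF with data tags
plus a CSV sidecar.

Readers never mutate values or units — normalization belongs to curation.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from rdkit import Chem, RDLogger

from .pk_model import StabilityClass, UnitSpec

RDLogger.DisableLog("rdApp.*")  # rejects are reported explicitly, not via stderr

__all__ = [
    "MeasurementEntry",
    "CompoundRecord",
    "DEFAULT_COLUMN_MAP",
    "canonical_smiles",
    "read_entries",
    "write_entries",
    "read_structures",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class MeasurementEntry:
    """One database record of a CL_int measurement."""

    entry_id: str
    compound_id: str
    smiles: str
    value: float | None
    unit: UnitSpec
    qualifier: str = "="
    temperature_C: float | None = None
    pH: float | None = None
    cofactor: str | None = None
    inhibitor_present: bool | None = None
    sample_type: str = "HLM"
    source_ref: str = ""
    source_value: float | None = None
    source_unit: UnitSpec | None = None

    def with_value(self, value: float, unit: UnitSpec) -> "MeasurementEntry":
        return replace(self, value=value, unit=unit)


@dataclass
class CompoundRecord:
    """A structure with its resolved class label and dataset assignment."""

    compound_id: str
    smiles: str
    clint: float
    stability: StabilityClass
    partition: str = "unassigned"  # train | test | unassigned


#: Column mapping used when the config does not declare one.  Keys are the
#: entry fields, values the column headers in the file.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "entry_id": "entry_id",
    "compound_id": "compound_id",
    "smiles": "smiles",
    "value": "value",
    "unit": "unit",
    "qualifier": "qualifier",
    "temperature_C": "temperature_C",
    "pH": "pH",
    "cofactor": "cofactor",
    "inhibitor_present": "inhibitor_present",
    "sample_type": "sample_type",
    "source_ref": "source_ref",
    "source_value": "source_value",
    "source_unit": "source_unit",
}

_MANDATORY = ("entry_id", "compound_id", "smiles", "value", "unit")

_QUALIFIERS = {"=", ">", "<", ">=", "<=", "≥", "≤"}
_QUALIFIER_ALIASES = {"≥": ">=", "≤": "<="}


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES via RDKit, or None if the string does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _opt_float(raw: object) -> float | None:
    if raw is None:
        return None
    s = str(raw).strip()
    if s == "" or s.lower() in {"na", "nan", "none"}:
        return None
    v = float(s)
    return v if math.isfinite(v) else None


def _opt_bool(raw: object) -> bool | None:
    if raw is None:
        return None
    s = str(raw).strip().lower()
    if s in {"", "na", "nan", "none"}:
        return None
    if s in {"1", "true", "yes", "y"}:
        return True
    if s in {"0", "false", "no", "n"}:
        return False
    raise ValueError(f"cannot interpret boolean field {raw!r}")


def read_entries(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    dialect: str = "infer",
) -> tuple[list[MeasurementEntry], list[dict]]:
    """Parse an entry table into MeasurementEntry objects.

    Returns ``(entries, malformed)``: malformed rows are collected with their
    1-based row numbers and the parse error, never silently dropped.  Rows
    with unparseable or missing values are still returned as entries with
    ``value=None`` (the basic curation filter rejects them with a reason);
    only rows that cannot be interpreted at all land in ``malformed``.
    """
    path = Path(path)
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    sep = "\t" if (dialect == "tsv" or (dialect == "infer" and path.suffix.lower() in {".tsv", ".tab"})) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    missing = [colmap[k] for k in _MANDATORY if colmap[k] not in df.columns]
    if missing:
        raise ValueError(f"entry table {path} lacks mandatory columns: {missing}")

    def col(row: pd.Series, key: str) -> object:
        name = colmap.get(key)
        return row[name] if name in row.index else None

    entries: list[MeasurementEntry] = []
    malformed: list[dict] = []
    for i, row in df.iterrows():
        rownum = int(i) + 2  # header is row 1
        try:
            qualifier = str(col(row, "qualifier") or "=").strip() or "="
            qualifier = _QUALIFIER_ALIASES.get(qualifier, qualifier)
            if qualifier not in _QUALIFIERS:
                raise ValueError(f"unknown qualifier {qualifier!r}")
            source_unit_raw = str(col(row, "source_unit") or "").strip()
            entries.append(
                MeasurementEntry(
                    entry_id=str(col(row, "entry_id")).strip(),
                    compound_id=str(col(row, "compound_id")).strip(),
                    smiles=str(col(row, "smiles")).strip(),
                    value=_opt_float(col(row, "value")),
                    unit=UnitSpec.from_unit(str(col(row, "unit")).strip()),
                    qualifier=qualifier,
                    temperature_C=_opt_float(col(row, "temperature_C")),
                    pH=_opt_float(col(row, "pH")),
                    cofactor=(str(col(row, "cofactor")).strip() or None),
                    inhibitor_present=_opt_bool(col(row, "inhibitor_present")),
                    sample_type=str(col(row, "sample_type") or "").strip(),
                    source_ref=str(col(row, "source_ref") or "").strip(),
                    source_value=_opt_float(col(row, "source_value")),
                    source_unit=UnitSpec.from_unit(source_unit_raw) if source_unit_raw else None,
                )
            )
        except (ValueError, TypeError) as exc:
            malformed.append({"row": rownum, "error": str(exc)})
    return entries, malformed


def write_entries(entries: Iterable[MeasurementEntry], path: str | Path) -> None:
    """Write entries as a TSV readable back by :func:`read_entries`."""
    path = Path(path)
    fields = list(DEFAULT_COLUMN_MAP)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(fields)
        for e in entries:
            w.writerow(
                [
                    e.entry_id,
                    e.compound_id,
                    e.smiles,
                    "" if e.value is None else repr(e.value),
                    e.unit.unit,
                    e.qualifier,
                    "" if e.temperature_C is None else e.temperature_C,
                    "" if e.pH is None else e.pH,
                    e.cofactor or "",
                    "" if e.inhibitor_present is None else str(e.inhibitor_present).lower(),
                    e.sample_type,
                    e.source_ref,
                    "" if e.source_value is None else repr(e.source_value),
                    e.source_unit.unit if e.source_unit else "",
                ]
            )


_PARTITIONS = {"training": "train", "train": "train", "test": "test", "": "unassigned"}


def read_structures(path: str | Path) -> tuple[dict[str, CompoundRecord], list[dict]]:
    """Read an SDF or SMILES file into records keyed by compound_id.

    SDF data tags recognised: ``compound_id``/``ChEMBL_ID``, ``Dataset``
    (training/test), ``Observed_class`` and ``CLint``.  Unparseable structures
    are reported with their index/ID in the rejects list.  An empty file is an
    error.
    """
    path = Path(path)
    records: dict[str, CompoundRecord] = {}
    rejects: list[dict] = []
    n_seen = 0

    if path.suffix.lower() in {".smi", ".smiles", ".txt"}:
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                n_seen += 1
                parts = line.split()
                smi = parts[0]
                cid = parts[1] if len(parts) > 1 else f"mol{i}"
                can = canonical_smiles(smi)
                if can is None:
                    rejects.append({"compound_id": cid, "smiles": smi, "error": "unparseable SMILES"})
                    continue
                records[cid] = CompoundRecord(cid, can, clint=float("nan"), stability=StabilityClass.STABLE)
    else:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            n_seen += 1
            if mol is None:
                rejects.append({"compound_id": f"sdf_record_{i}", "smiles": "", "error": "unparseable SDF record"})
                continue
            props = mol.GetPropsAsDict()
            cid = str(props.get("compound_id", props.get("ChEMBL_ID", mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}")))
            partition = _PARTITIONS.get(str(props.get("Dataset", "")).strip().lower(), "unassigned")
            cls = str(props.get("Observed_class", "stable")).strip().lower()
            records[cid] = CompoundRecord(
                compound_id=cid,
                smiles=Chem.MolToSmiles(mol),
                clint=float(props.get("CLint", "nan")),
                stability=StabilityClass(cls),
                partition=partition,
            )
    if n_seen == 0:
        raise ValueError(f"structure file {path} contains no molecules")
    return records, rejects


def write_dataset(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Write records as SDF (V2000) with data tags plus a CSV sidecar.

    Tags: compound_id, Dataset (training/test/empty), Observed_class, CLint.
    Round-trip through :func:`read_dataset` preserves id, clint, class and
    partition exactly.
    """
    path = Path(path)
    records = list(records)
    writer = Chem.SDWriter(str(path))
    try:
        for r in records:
            mol = Chem.MolFromSmiles(r.smiles)
            if mol is None:
                raise ValueError(f"record {r.compound_id}: unwritable SMILES {r.smiles!r}")
            mol.SetProp("_Name", r.compound_id)
            mol.SetProp("compound_id", r.compound_id)
            mol.SetProp("Dataset", {"train": "training", "test": "test"}.get(r.partition, ""))
            mol.SetProp("Observed_class", str(r.stability))
            mol.SetProp("CLint", repr(r.clint))
            writer.write(mol)
    finally:
        writer.close()
    sidecar = path.with_suffix(".csv")
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "smiles": [r.smiles for r in records],
            "clint": [r.clint for r in records],
            "stability": [str(r.stability) for r in records],
            "partition": [r.partition for r in records],
        }
    ).to_csv(sidecar, index=False)


def read_dataset(path: str | Path) -> list[CompoundRecord]:
    """Read back an SDF written by :func:`write_dataset`, in file order."""
    records, rejects = read_structures(path)
    if rejects:
        raise ValueError(f"dataset {path} contains unparseable records: {rejects}")
    return list(records.values())
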