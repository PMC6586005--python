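"""Shared fixtures: tiny entry tables and molecule panels, built in memory."""

from __future__ import annotations

import pytest

from clintpipe.io_chem import MeasurementEntry
from clintpipe.pk_model import UnitSpec

UL_MG = UnitSpec.from_unit("uL/min/mg")
ML_G = UnitSpec.from_unit("mL/min/g")
ML_KG = UnitSpec.from_unit("mL/min/kg")


_MIRROR = object()  # default: source record mirrors the recorded value/unit


def make_entry(
    entry_id: str,
    compound_id: str = "CPD1",
    smiles: str = "c1ccccc1O",
    value: float | None = 10.0,
    unit: UnitSpec = UL_MG,
    qualifier: str = "=",
    temperature_C: float | None = 37.0,
    pH: float | None = 7.4,
    cofactor: str | None = "NADPH",
    inhibitor_present: bool | None = False,
    sample_type: str = "HLM",
    source_value=_MIRROR,
    source_unit=_MIRROR,
) -> MeasurementEntry:
    """A protocol-conforming HLM entry unless overridden."""
    if source_value is _MIRROR:
        source_value = value
    if source_unit is _MIRROR:
        source_unit = unit
    return MeasurementEntry(
        entry_id=entry_id,
        compound_id=compound_id,
        smiles=smiles,
        value=value,
        unit=unit,
        qualifier=qualifier,
        temperature_C=temperature_C,
        pH=pH,
        cofactor=cofactor,
        inhibitor_present=inhibitor_present,
        sample_type=sample_type,
        source_ref="REF1",
        source_value=source_value,
        source_unit=source_unit,
    )


@pytest.fixture
def molecule_panel() -> dict[str, str]:
    """20 small drug-like and simple molecules, by name."""
    return {
        "water": "O",
        "methane": "C",
        "ethanol": "CCO",
        "benzene": "c1ccccc1",
        "cyclohexane": "C1CCCCC1",
        "acetic_acid": "CC(=O)O",
        "phenol": "c1ccccc1O",
        "aniline": "Nc1ccccc1",
        "toluene": "Cc1ccccc1",
        "pyridine": "c1ccncc1",
        "naphthalene": "c1ccc2ccccc2c1",
        "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
        "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
        "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
        "paracetamol": "CC(=O)Nc1ccc(O)cc1",
        "glucose": "OCC1OC(O)C(O)C(O)C1O",
        "benzamide": "NC(=O)c1ccccc1",
        "nitrobenzene": "O=[N+]([O-])c1ccccc1",
        "trifluorotoluene": "FC(F)(F)c1ccccc1",
        "morpholine": "C1COCCN1",
    }
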