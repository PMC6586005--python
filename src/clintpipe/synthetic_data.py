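"""Ground-truthed synthetic CL_int entry tables with injected database errors.

The generator emulates what an open-database export of microsomal stability
data looks like, together with the truth needed to score any curation
strategy:

1. **Structures** come from combinatorial assembly of bundled aromatic and
   aliphatic scaffolds with common medicinal-chemistry substituents, filtered
   to a drug-like weight window — no downloads, no licences, deterministic
   under a seed.
2. **True CL_int** follows a latent descriptor-dependent model: log10 CL_int
   is an affine function of lipophilicity (SLogP) and polar surface area,
   plus Gaussian noise, with the affine part quantile-targeted so the class
   mix (stable/moderate/unstable) hits the requested proportions.
3. **Entries** are then corrupted the way real databases are: per-g-liver
   unit misreadings that inflate naive conversions by 1000/45, digit
   transpositions, qualifier ranges (">20"), conflicting duplicate reports,
   and off-protocol measurements (30 C, pH 6.8, or no NADPH) with biased
   values.  Every entry keeps an intact original-publication record so a
   cross-checking curator *can* repair what is repairable, and a corruption
   ledger records every injection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .curation import CurationResult
from .io_chem import MeasurementEntry, canonical_smiles
from .pk_model import StabilityClass, UnitSpec, assign_class

__all__ = [
    "LatentModel",
    "ErrorRates",
    "GeneratorConfig",
    "GroundTruth",
    "generate_compounds",
    "assign_true_clint",
    "corrupt_entries",
    "generate_entry_table",
    "truth_report",
]

_SCAFFOLDS = [
    "c1cc({R1})ccc1{R2}",
    "c1cc({R1})cnc1{R2}",
    "c1ccc2cc({R1})c({R2})cc2c1",
    "c1ccc2nc({R1})cc({R2})c2c1",
    "C1CCN(CC1)c1cc({R2})ccc1{R1}",
    "O1CCN(CC1)c1cc({R2})ccc1{R1}",
    "c1ccc(cc1)c1cc({R2})ccc1{R1}",
    "c1cc({R2})c2c(c1)cc({R1})o2",
    "c1nc({R1})ncc1{R2}",
    "C1CCC(CC1)c1cc({R2})ccc1{R1}",
    "O=C(Nc1cc({R2})ccc1{R1})c1ccccc1",
    "O=S(=O)(N)c1cc({R2})ccc1{R1}",
]

_SUBSTITUENTS = [
    "C",
    "CC",
    "C(C)C",
    "O",
    "OC",
    "OCC",
    "N",
    "N(C)C",
    "F",
    "Cl",
    "Br",
    "C(F)(F)F",
    "C#N",
    "C(=O)O",
    "C(=O)OC",
    "C(=O)N",
    "[N+](=O)[O-]",
    "S(=O)(=O)N",
    "CO",
    "OC(F)F",
]

_MW_RANGE = (150.0, 550.0)


@dataclass(frozen=True)
class LatentModel:
    """Latent structure -> log10 CL_int link.

    Lipophilic compounds clear faster (positive SLogP slope) and polar ones
    slower, echoing the dominance of logP-type descriptors in stability
    models.  The slopes set only the *shape* of the latent score; its
    location and spread are rescaled by quantile targeting so the class mix
    is met.  noise_sd is in log10 units (0.3 ~ a twofold assay spread).
    """

    b_logp: float = 0.8
    b_tpsa: float = -0.9
    noise_sd: float = 0.3
    clip: tuple[float, float] = (0.1, 3000.0)


@dataclass(frozen=True)
class ErrorRates:
    """Corruption probabilities (per compound for the unit misread and the
    conflicting duplicate, per entry otherwise).

    The defaults are calibrated to the error frequencies open CL_int
    collections actually exhibit: roughly two in five records trace back to a
    source whose unit was misinterpreted on deposition, a similar fraction
    were measured under assay protocols other than the 37 C / pH 7.4 / NADPH
    standard, and a few percent each suffer transcription errors, range
    reporting, or conflicting duplicate reports.
    """

    per_g_liver_misinterpretation: float = 0.40
    value_transcription: float = 0.05
    qualifier_range: float = 0.05
    duplicate_conflicting: float = 0.05
    off_protocol: float = 0.40

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def none(cls) -> "ErrorRates":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GeneratorConfig:
    n_compounds: int = 600
    seed: int = 0
    class_mix: tuple[float, float, float] = (0.40, 0.50, 0.10)  # stable/moderate/unstable
    latent_model: LatentModel = field(default_factory=LatentModel)
    error_rates: ErrorRates = field(default_factory=ErrorRates)

    def __post_init__(self) -> None:
        if self.n_compounds < 10:
            raise ValueError("n_compounds must be >= 10")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")


@dataclass
class GroundTruth:
    """Per-compound truth: structure, true CL_int, class, injected corruptions."""

    smiles: dict[str, str]
    clint: dict[str, float]
    stability: dict[str, StabilityClass]
    corruptions: dict[str, list[str]]

    @property
    def compound_ids(self) -> list[str]:
        return list(self.smiles)


def generate_compounds(config: GeneratorConfig) -> dict[str, str]:
    """Assemble ``n_compounds`` unique drug-like structures.

    The scaffold x substituent x substituent space is enumerated in a fixed
    order, shuffled with the seed, validated with RDKit, deduplicated on
    canonical SMILES and filtered to MW 150-550.  Deterministic per seed.
    """
    combos = [
        (s, r1, r2)
        for s in range(len(_SCAFFOLDS))
        for r1 in range(len(_SUBSTITUENTS))
        for r2 in range(len(_SUBSTITUENTS))
    ]
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(combos))
    out: dict[str, str] = {}
    seen: set[str] = set()
    for idx in order:
        s, r1, r2 = combos[idx]
        smi = _SCAFFOLDS[s].replace("{R1}", _SUBSTITUENTS[r1]).replace("{R2}", _SUBSTITUENTS[r2])
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        mw = Descriptors.MolWt(mol)
        if not _MW_RANGE[0] <= mw <= _MW_RANGE[1]:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        out[f"SYN{len(out):05d}"] = can
        if len(out) == config.n_compounds:
            return out
    raise ValueError(
        f"combinatorial space supports at most {len(out)} unique drug-like "
        f"structures; {config.n_compounds} requested"
    )


def assign_true_clint(structures: dict[str, str], config: GeneratorConfig) -> GroundTruth:
    """Draw each compound's true CL_int from the latent descriptor model.

    The latent score z = b_logp*SLogP + b_tpsa*(TopoPSA/100) + noise is
    affinely rescaled so its empirical quantiles put the requested class
    fractions below log10(20) and log10(300); the result is exponentiated and
    clipped.  With noise_sd = 0 the value is a deterministic function of the
    descriptors (the quantile mapping uses no randomness).
    """
    lm = config.latent_model
    ids = list(structures)
    logp = np.empty(len(ids))
    tpsa = np.empty(len(ids))
    for i, cid in enumerate(ids):
        mol = Chem.MolFromSmiles(structures[cid])
        if mol is None:
            raise ValueError(f"unparseable structure for {cid}")
        logp[i] = Crippen.MolLogP(mol)
        tpsa[i] = rdMolDescriptors.CalcTPSA(mol, includeSandP=True)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    noise = rng.normal(0.0, lm.noise_sd, size=len(ids)) if lm.noise_sd > 0 else np.zeros(len(ids))
    z = lm.b_logp * logp + lm.b_tpsa * (tpsa / 100.0) + noise

    p_stable, p_moderate, _ = config.class_mix
    q_lo = float(np.quantile(z, p_stable))
    q_hi = float(np.quantile(z, p_stable + p_moderate))
    t_lo, t_hi = math.log10(20.0), math.log10(300.0)
    if q_hi - q_lo < 1e-12:
        raise ValueError("latent score is degenerate; class_mix unattainable")
    scale = (t_hi - t_lo) / (q_hi - q_lo)
    intercept = t_lo - scale * q_lo
    log_clint = intercept + scale * z
    clint = np.clip(10.0**log_clint, lm.clip[0], lm.clip[1])

    truth = GroundTruth(smiles=dict(structures), clint={}, stability={}, corruptions={})
    for i, cid in enumerate(ids):
        truth.clint[cid] = float(clint[i])
        truth.stability[cid] = assign_class(float(clint[i]))
        truth.corruptions[cid] = []
    return truth


_UL_MG = UnitSpec.from_unit("uL/min/mg")
_ML_G = UnitSpec.from_unit("mL/min/g")


def _clean_entry(eid: str, cid: str, smi: str, value: float, ref: str) -> MeasurementEntry:
    return MeasurementEntry(
        entry_id=eid,
        compound_id=cid,
        smiles=smi,
        value=value,
        unit=_UL_MG,
        qualifier="=",
        temperature_C=37.0,
        pH=7.4,
        cofactor="NADPH",
        inhibitor_present=False,
        sample_type="HLM",
        source_ref=ref,
        source_value=value,
        source_unit=_UL_MG,
    )


def _transpose_digits(value: float, rng: np.random.Generator) -> float:
    """Swap two adjacent significant digits; fall back to a decimal shift."""
    s = f"{value:.6g}"
    digits = [i for i, ch in enumerate(s) if ch.isdigit()]
    for _ in range(8):
        if len(digits) < 2:
            break
        k = int(rng.integers(len(digits) - 1))
        i, j = digits[k], digits[k + 1]
        swapped = list(s)
        swapped[i], swapped[j] = swapped[j], swapped[i]
        cand = float("".join(swapped))
        if cand != value and cand > 0:
            return cand
    return value * 10.0


def corrupt_entries(
    truth: GroundTruth, config: GeneratorConfig
) -> tuple[list[MeasurementEntry], list[dict]]:
    """Expand the truth into a corrupted entry table plus an injection ledger.

    Each compound yields 1-3 entries whose clean value is its true CL_int in
    uL/min/mg.  The unit misreading is drawn *per compound*: when the source
    publication reported per-g-liver-style units, every database entry
    derived from it inherits the misread, so the compound's entries inflate
    consistently under naive conversion instead of conflicting each other
    away.  Transcription, qualifier and off-protocol corruptions fire per
    entry (at most one each); conflicting duplicates are added per compound.
    The original-publication record (source_value/source_unit) stays intact
    except where the *source itself* is the problem: conflicting duplicates
    and off-protocol measurements are faithfully recorded wrong numbers,
    which only protocol checks or ambiguity resolution can catch.
    """
    rates = config.error_rates
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    entries: list[MeasurementEntry] = []
    ledger: list[dict] = []
    serial = 0

    def log(cid: str, eid: str, kind: str, detail: str) -> None:
        truth.corruptions[cid].append(kind)
        ledger.append({"compound_id": cid, "entry_id": eid, "corruption": kind, "detail": detail})

    for cid in truth.compound_ids:
        smi = truth.smiles[cid]
        value = truth.clint[cid]
        cls = truth.stability[cid]
        n_entries = int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))
        # the unit misread is a property of the source publication, shared by
        # every entry deposited from it
        misread_compound = rng.random() < rates.per_g_liver_misinterpretation
        for _ in range(n_entries):
            eid = f"E{serial:06d}"
            serial += 1
            ref = f"REF{int(rng.integers(10_000, 99_999))}"
            e = _clean_entry(eid, cid, smi, value, ref)
            u = rng.random(3)
            if misread_compound:
                # recorded under a per-g-liver unit; the number itself is right
                e = replace(e, unit=_ML_G)
                log(cid, eid, "per_g_liver_misinterpretation",
                    f"value {value:.4g} recorded as mL/min/g")
            elif u[0] < rates.value_transcription:
                wrong = _transpose_digits(value, rng)
                e = replace(e, value=wrong)
                log(cid, eid, "value_transcription", f"{value:.6g} -> {wrong:.6g}")
            elif u[1] < rates.qualifier_range:
                if cls is StabilityClass.STABLE:
                    qual, bound = "<", 300.0
                elif cls is StabilityClass.MODERATE:
                    qual, bound = ">", 20.0
                else:
                    qual, bound = ">", 300.0
                e = replace(e, qualifier=qual, value=bound, source_value=bound)
                log(cid, eid, "qualifier_range", f"reported as {qual}{bound:g}")
            elif u[2] < rates.off_protocol:
                mode = int(rng.integers(3))
                biased = value * 0.2  # slower turnover off protocol
                if mode == 0:
                    e = replace(e, temperature_C=30.0)
                elif mode == 1:
                    e = replace(e, pH=6.8)
                else:
                    e = replace(e, cofactor=None)
                e = replace(e, value=biased, source_value=biased)
                log(cid, eid, "off_protocol",
                    ["temperature 30 C", "pH 6.8", "no NADPH"][mode] + f", biased value {biased:.4g}")
            entries.append(e)

        if rng.random() < rates.duplicate_conflicting:
            eid = f"E{serial:06d}"
            serial += 1
            conflicting = {
                StabilityClass.STABLE: 500.0,
                StabilityClass.MODERATE: 5.0,
                StabilityClass.UNSTABLE: 50.0,
            }[cls]
            e = _clean_entry(eid, cid, smi, conflicting, f"REF{int(rng.integers(10_000, 99_999))}")
            entries.append(e)
            log(cid, eid, "duplicate_conflicting", f"conflicting report {conflicting:g}")
    return entries, ledger


def generate_entry_table(config: GeneratorConfig) -> tuple[list[MeasurementEntry], GroundTruth, list[dict]]:
    """Structures -> truth -> corrupted entries, in one deterministic call."""
    structures = generate_compounds(config)
    truth = assign_true_clint(structures, config)
    entries, ledger = corrupt_entries(truth, config)
    return entries, truth, ledger


def truth_report(
    truth: GroundTruth,
    curated: CurationResult,
    non_curated: CurationResult,
) -> dict:
    """Score each curation mode's resolved labels against the truth.

    *Recovery* is the fraction of resolved compounds whose class matches the
    truth (label quality); *coverage* the fraction of truth compounds that
    survived resolution at all.  A per-corruption-type recovery breakdown
    shows which injected error each mode absorbs.
    """
    report: dict = {"modes": {}}
    for res in (curated, non_curated):
        labels = {r.compound_id: r.stability for r in res.records}
        unknown = set(labels) - set(truth.stability)
        if unknown:
            raise ValueError(f"resolved compounds absent from truth: {sorted(unknown)[:5]}")
        matches = sum(1 for cid, cls in labels.items() if truth.stability[cid] == cls)
        by_type: dict[str, dict] = {}
        for kind in (
            "per_g_liver_misinterpretation",
            "value_transcription",
            "qualifier_range",
            "duplicate_conflicting",
            "off_protocol",
        ):
            affected = [cid for cid, ks in truth.corruptions.items() if kind in ks]
            resolved = [cid for cid in affected if cid in labels]
            ok = sum(1 for cid in resolved if truth.stability[cid] == labels[cid])
            by_type[kind] = {
                "n_affected": len(affected),
                "n_resolved": len(resolved),
                "recovery": ok / len(resolved) if resolved else None,
            }
        report["modes"][res.mode] = {
            "n_truth": len(truth.stability),
            "n_resolved": len(labels),
            "coverage": len(labels) / len(truth.stability),
            "recovery": matches / len(labels) if labels else None,
            "by_corruption": by_type,
        }
    return report
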