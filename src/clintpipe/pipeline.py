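"""End-to-end experiment: curation contrast on a common network-based split.

The experiment mirrors the two-arm design the package exists to test:

1. Build the *curated* and *non-curated* datasets from the same entry stream.
2. Cluster the curated dataset's descriptor profiles into a correlation
   network, take the largest cluster as the training set and the remaining
   clusters as the (deliberately dissimilar) test set.
3. Remove the test compounds from the non-curated pool, so both arms are
   evaluated on the identical test set.
4. Within each arm: filter features on training rows, select all-relevant
   features with the shadow-feature screen on training rows only, tune and
   train the classifiers, and evaluate on the held-out test set.

The returned report carries, per arm and algorithm, the resample metrics and
the test-set evaluation (confusion, accuracy, kappa, per-class stats,
critical mis-prediction), plus a comparison table and a reproducibility
manifest.  Everything is deterministic under the master seed, which fans out
to named substreams for simulation, selection and model fitting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boruta_select import BorutaConfig, boruta_run, selected_features
from .curation import CurationConfig, CurationResult, build_datasets
from .descriptors import DescriptorMatrix, FingerprintConfig, build_matrix, filter_features
from .evaluation import evaluate
from .io_chem import MeasurementEntry
from .modeling import ModelConfig, tune_and_train
from .synthetic_data import ErrorRates, GeneratorConfig, generate_entry_table, truth_report
from .wgcna_split import NetworkConfig, split_compounds

__all__ = ["PipelineConfig", "RunManifest", "run_experiment"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full experiment needs; schema-checked on construction."""

    n_compounds: int = 600
    seed: int = 0
    error_rates: ErrorRates = field(default_factory=ErrorRates)
    fingerprint_nbits: int = 4096
    network: NetworkConfig = field(default_factory=NetworkConfig)
    boruta_max_runs: int = 100
    boruta_trees: int = 500
    boruta_importance: str = "permutation"
    algorithms: tuple[str, ...] = ("rf", "adaboost", "svm_radial", "svm_linear")
    tune_length: int = 10
    rf_trees: int = 500
    fixed_hyperparameters: dict | None = None

    def substream(self, name: str) -> int:
        """Named 31-bit seed derived from the master seed."""
        h = hashlib.blake2b(f"{self.seed}:{name}".encode(), digest_size=4).digest()
        return int.from_bytes(h, "little") % (2**31 - 1)


@dataclass
class RunManifest:
    """Reproducibility record: config hash, seeds, per-stage counts."""

    config_hash: str
    package_version: str
    seed: int
    stage_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(type(o))

    payload = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _mode_matrix(matrix: DescriptorMatrix, ids: list[str]) -> DescriptorMatrix:
    pos = {cid: i for i, cid in enumerate(matrix.compound_ids)}
    rows = [pos[cid] for cid in ids]
    return DescriptorMatrix(ids, list(matrix.feature_names), matrix.values[rows], list(matrix.provenance))


def run_experiment(
    config: PipelineConfig,
    entries: list[MeasurementEntry] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the two-arm curation experiment and return the full report.

    When ``entries`` is None the synthetic generator supplies them (with
    ground truth, in which case a truth-recovery section is included).
    """
    manifest = RunManifest(_config_hash(config), __version__, config.seed)
    counts = manifest.stage_counts

    truth = None
    injection_ledger: list[dict] = []
    if entries is None:
        gen = GeneratorConfig(
            n_compounds=config.n_compounds,
            seed=config.substream("simulate"),
            error_rates=config.error_rates,
        )
        entries, truth, injection_ledger = generate_entry_table(gen)
    counts["input_entries"] = len(entries)

    curated = build_datasets(entries, CurationConfig(mode="curated"))
    non_curated = build_datasets(entries, CurationConfig(mode="non_curated"))
    counts["curated_compounds"] = len(curated.records)
    counts["non_curated_compounds"] = len(non_curated.records)

    # one structure-only descriptor matrix over every compound either arm kept
    structures: dict[str, str] = {}
    for res in (curated, non_curated):
        for r in res.records:
            structures.setdefault(r.compound_id, r.smiles)
    full = build_matrix(structures, fingerprint=FingerprintConfig(nbits=config.fingerprint_nbits))
    counts["descriptor_columns"] = len(full.feature_names)

    # network split on the curated dataset (standardized, filtered columns)
    curated_ids = [r.compound_id for r in curated.records]
    cur_matrix, _ = filter_features(_mode_matrix(full, curated_ids))
    Xc = cur_matrix.values
    Xc = (Xc - Xc.mean(axis=0)) / Xc.std(axis=0)
    split = split_compounds(Xc, curated_ids, config.network)
    test_ids = set(split.test_ids)
    counts["train_compounds_curated"] = len(split.train_ids)
    counts["test_compounds"] = len(split.test_ids)

    curated_labels = {r.compound_id: str(r.stability) for r in curated.records}
    test_order = [cid for cid in split.compound_ids if cid in test_ids]
    y_test = np.array([curated_labels[cid] for cid in test_order])

    arms = {
        "curated": [r.compound_id for r in curated.records if r.compound_id not in test_ids],
        "non_curated": [r.compound_id for r in non_curated.records if r.compound_id not in test_ids],
    }
    labels_by_mode = {
        "curated": curated_labels,
        "non_curated": {r.compound_id: str(r.stability) for r in non_curated.records},
    }
    counts["train_compounds_non_curated"] = len(arms["non_curated"])

    results: dict = {"modes": {}}
    for mode, train_ids in arms.items():
        y_train = np.array([labels_by_mode[mode][cid] for cid in train_ids])
        train_m = _mode_matrix(full, train_ids)
        train_f, _ = filter_features(train_m)  # filter decided on training rows only
        bconf = BorutaConfig(
            max_runs=config.boruta_max_runs,
            rf_trees=config.boruta_trees,
            seed=config.substream(f"boruta:{mode}"),
            importance=config.boruta_importance,
        )
        decisions = boruta_run(train_f.values, y_train, train_f.feature_names, bconf)
        selected = selected_features(decisions)
        if not selected:  # degenerate screen: fall back to all filtered features
            selected = list(train_f.feature_names)
        col_idx = [train_f.feature_names.index(n) for n in selected]
        X_train = train_f.values[:, col_idx]

        test_m = _mode_matrix(full, test_order)
        name_pos = {n: j for j, n in enumerate(test_m.feature_names)}
        X_test = test_m.values[:, [name_pos[n] for n in selected]]

        mode_report: dict = {
            "n_train": len(train_ids),
            "n_selected_features": len(selected),
            "models": {},
        }
        for algo in config.algorithms:
            mconf = ModelConfig(
                algorithm=algo,
                tune_length=config.tune_length,
                seed=config.substream(f"model:{mode}:{algo}"),
                rf_trees=config.rf_trees,
                fixed_hyperparameters=(config.fixed_hyperparameters or {}).get(algo)
                if config.fixed_hyperparameters
                else None,
            )
            fit = tune_and_train(X_train, y_train, selected, mconf)
            pred = fit.predict(X_test)
            report = evaluate(y_test, pred)
            mode_report["models"][algo] = {
                "chosen_parameters": fit.params,
                "resample_accuracy": fit.resample_accuracy,
                "resample_kappa": fit.resample_kappa,
                "test": report.to_dict(),
            }
        results["modes"][mode] = mode_report

    comparison = [
        {
            "mode": mode,
            "algorithm": algo,
            "resample_accuracy": m["resample_accuracy"],
            "resample_kappa": m["resample_kappa"],
            "test_accuracy": m["test"]["accuracy"],
            "test_kappa": m["test"]["kappa"],
            "critical_mispredict_pct": m["test"]["critical_mispredict_pct"],
        }
        for mode, rep in results["modes"].items()
        for algo, m in rep["models"].items()
    ]

    out = {
        "manifest": manifest.to_dict(),
        "curation": {
            "curated": curated.action_counts(),
            "non_curated": non_curated.action_counts(),
        },
        "split": {
            "cluster_sizes": split.cluster_sizes,
            "n_train": len(split.train_ids),
            "n_test": len(split.test_ids),
        },
        "results": results,
        "comparison": comparison,
    }
    if truth is not None:
        out["truth_recovery"] = truth_report(truth, curated, non_curated)
        out["n_injected_corruptions"] = len(injection_ledger)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(out, indent=2, sort_keys=True))
        pd.DataFrame(comparison).to_csv(out_dir / "comparison.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2, sort_keys=True))
    return out
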