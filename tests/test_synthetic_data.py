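"""Synthetic structure generation, latent CL_int model, corruption machinery."""

import numpy as np
import pytest
from rdkit import Chem

from clintpipe.curation import CurationConfig, build_datasets
from clintpipe.pk_model import StabilityClass, assign_class
from clintpipe.synthetic_data import (
    ErrorRates,
    GeneratorConfig,
    LatentModel,
    assign_true_clint,
    corrupt_entries,
    generate_compounds,
    generate_entry_table,
    truth_report,
)

NO_ERRORS = ErrorRates.none()


class TestGenerateCompounds:
    def test_requested_count_unique_and_parseable(self):
        structures = generate_compounds(GeneratorConfig(n_compounds=50, seed=1))
        assert len(structures) == 50
        canon = {Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in structures.values()}
        assert len(canon) == 50

    def test_deterministic_per_seed(self):
        a = generate_compounds(GeneratorConfig(n_compounds=40, seed=9))
        b = generate_compounds(GeneratorConfig(n_compounds=40, seed=9))
        assert a == b
        c = generate_compounds(GeneratorConfig(n_compounds=40, seed=10))
        assert a != c

    def test_descriptors_vary_across_library(self):
        from clintpipe.descriptors import compute_physchem

        structures = generate_compounds(GeneratorConfig(n_compounds=60, seed=2))
        rows = [compute_physchem(Chem.MolFromSmiles(s)) for s in structures.values()]
        assert np.std([r["SLogP"] for r in rows]) > 0
        assert np.std([r["TopoPSA"] for r in rows]) > 0

    def test_exhausted_space_error_states_maximum(self):
        with pytest.raises(ValueError, match="at most"):
            generate_compounds(GeneratorConfig(n_compounds=100_000, seed=0))


class TestAssignTrueClint:
    def test_noise_free_model_is_deterministic_in_descriptors(self):
        cfg = GeneratorConfig(n_compounds=40, seed=4, latent_model=LatentModel(noise_sd=0.0))
        structures = generate_compounds(cfg)
        t1 = assign_true_clint(structures, cfg)
        t2 = assign_true_clint(structures, cfg)
        assert t1.clint == t2.clint

    def test_class_mix_hit_by_quantile_targeting(self):
        cfg = GeneratorConfig(n_compounds=500, seed=5)
        truth = assign_true_clint(generate_compounds(cfg), cfg)
        stable_frac = sum(s is StabilityClass.STABLE for s in truth.stability.values()) / 500
        assert 0.35 <= stable_frac <= 0.45

    def test_labels_consistent_with_class_assignment(self):
        cfg = GeneratorConfig(n_compounds=80, seed=6)
        truth = assign_true_clint(generate_compounds(cfg), cfg)
        for cid, clint in truth.clint.items():
            assert truth.stability[cid] is assign_class(clint)


class TestCorruptEntries:
    def test_zero_rates_give_clean_identical_modes(self):
        cfg = GeneratorConfig(n_compounds=40, seed=7, error_rates=NO_ERRORS)
        entries, truth, ledger = generate_entry_table(cfg)
        assert not ledger
        assert all(e.value == truth.clint[e.compound_id] for e in entries)
        cur = build_datasets(entries, CurationConfig("curated"))
        non = build_datasets(entries, CurationConfig("non_curated"))
        assert [(r.compound_id, r.stability) for r in cur.records] == [
            (r.compound_id, r.stability) for r in non.records
        ]

    def test_full_misread_rate_inflates_every_naive_conversion(self):
        from clintpipe.pk_model import convert_units

        rates = ErrorRates(per_g_liver_misinterpretation=1.0, value_transcription=0,
                           qualifier_range=0, duplicate_conflicting=0, off_protocol=0)
        cfg = GeneratorConfig(n_compounds=30, seed=8, error_rates=rates)
        entries, truth, _ = generate_entry_table(cfg)
        for e in entries:
            naive = convert_units(e.value, e.unit)
            assert naive == pytest.approx(truth.clint[e.compound_id] * 1000 / 45)

    def test_moderate_compound_misread_flips_to_unstable_only_uncurated(self):
        """Miniature of the documented database story: a true CL_int of ~42
        recorded under mL/min/g becomes unstable naively, moderate curated."""
        rates = ErrorRates(per_g_liver_misinterpretation=1.0, value_transcription=0,
                           qualifier_range=0, duplicate_conflicting=0, off_protocol=0)
        cfg = GeneratorConfig(n_compounds=60, seed=9, error_rates=rates)
        entries, truth, _ = generate_entry_table(cfg)
        moderates = {c for c, s in truth.stability.items() if s is StabilityClass.MODERATE}
        cur = {r.compound_id: r.stability for r in build_datasets(entries, CurationConfig("curated")).records}
        non = {r.compound_id: r.stability for r in build_datasets(entries, CurationConfig("non_curated")).records}
        for cid in moderates:
            assert cur[cid] is StabilityClass.MODERATE
            assert non[cid] is StabilityClass.UNSTABLE

    def test_corruption_ledger_matches_truth_annotations(self):
        cfg = GeneratorConfig(n_compounds=50, seed=10)
        entries, truth, ledger = generate_entry_table(cfg)
        assert len(ledger) == sum(len(v) for v in truth.corruptions.values())


class TestTruthReport:
    def test_zero_corruption_perfect_recovery(self):
        cfg = GeneratorConfig(n_compounds=40, seed=11, error_rates=NO_ERRORS)
        entries, truth, _ = generate_entry_table(cfg)
        cur = build_datasets(entries, CurationConfig("curated"))
        non = build_datasets(entries, CurationConfig("non_curated"))
        report = truth_report(truth, cur, non)
        assert report["modes"]["curated"]["recovery"] == 1.0
        assert report["modes"]["non_curated"]["recovery"] == 1.0

    def test_curated_recovery_dominates_across_seeds(self):
        """Cross-checking repairs unit and transcription errors, so curated
        label quality is at least non-curated for every seed."""
        for seed in range(10):
            cfg = GeneratorConfig(n_compounds=120, seed=seed)
            entries, truth, _ = generate_entry_table(cfg)
            cur = build_datasets(entries, CurationConfig("curated"))
            non = build_datasets(entries, CurationConfig("non_curated"))
            modes = truth_report(truth, cur, non)["modes"]
            assert modes["curated"]["recovery"] >= modes["non_curated"]["recovery"]

    def test_removed_fraction_grows_with_conflicting_duplicates(self):
        coverages = []
        for rate in (0.0, 0.3, 0.9):
            rates = ErrorRates(per_g_liver_misinterpretation=0, value_transcription=0,
                               qualifier_range=0, duplicate_conflicting=rate, off_protocol=0)
            cfg = GeneratorConfig(n_compounds=100, seed=12, error_rates=rates)
            entries, truth, _ = generate_entry_table(cfg)
            cur = build_datasets(entries, CurationConfig("curated"))
            non = build_datasets(entries, CurationConfig("non_curated"))
            coverages.append(truth_report(truth, cur, non)["modes"]["curated"]["coverage"])
        assert coverages[0] >= coverages[1] >= coverages[2]
        assert coverages[2] < coverages[0]
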