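"""Filtering, cross-checking and ambiguity-resolution rules."""

import numpy as np
import pytest

from clintpipe.curation import (
    CurationConfig,
    build_datasets,
    classes_consistent_with,
    cross_check,
    filter_basic,
    filter_protocol,
    resolve_compound,
)
from clintpipe.pk_model import StabilityClass, UnitSpec, assign_class

from .conftest import ML_G, ML_KG, UL_MG, make_entry

CURATED = CurationConfig(mode="curated")
NON_CURATED = CurationConfig(mode="non_curated")


class TestFilterBasic:
    def test_rejections_and_keeps(self):
        entries = [
            make_entry("E1", unit=UnitSpec.from_unit("%")),
            make_entry("E2", value=None),
            make_entry("E3", sample_type="RLM"),
            make_entry("E4"),
        ]
        kept, rejected = filter_basic(entries, CURATED)
        assert [e.entry_id for e in kept] == ["E4"]
        reasons = {a.entry_id: a.reason for a in rejected}
        assert "non-CLint unit" in reasons["E1"]
        assert "value" in reasons["E2"]
        assert "RLM" in reasons["E3"]


class TestFilterProtocol:
    @pytest.mark.parametrize(
        "kwargs,kept",
        [
            ({}, True),
            ({"temperature_C": 30.0}, False),
            ({"pH": 6.8}, False),
            ({"inhibitor_present": True}, False),
            ({"cofactor": None}, False),  # strict: missing field rejected
            ({"temperature_C": 37.4}, True),  # within +-0.5 C
            ({"pH": 7.44}, True),  # within +-0.05
        ],
    )
    def test_protocol_enforcement(self, kwargs, kept):
        entries = [make_entry("E1", **kwargs)]
        got_kept, got_rej = filter_protocol(entries, CURATED)
        assert bool(got_kept) is kept
        assert bool(got_rej) is not kept

    def test_lenient_policy_keeps_missing_fields(self):
        cfg = CurationConfig(mode="curated", missing_protocol_policy="lenient")
        kept, _ = filter_protocol([make_entry("E1", cofactor=None)], cfg)
        assert kept


class TestCrossCheck:
    def test_transcribed_value_replaced_from_source(self):
        """A 933.3 record whose source says 42 is corrected to 42."""
        e = make_entry("E1", value=933.3, source_value=42.0)
        fixed, action, unverifiable = cross_check(e, CURATED)
        assert fixed.value == 42.0
        assert action.action == "value_replaced"
        assert not unverifiable

    def test_agreeing_record_kept(self):
        e = make_entry("E1", value=42.0, source_value=42.0)
        fixed, action, _ = cross_check(e, CURATED)
        assert action is None and fixed.value == 42.0

    def test_unit_mismatch_recalculated_from_source(self):
        """Recorded mL/min/kg 18.9 with a per-kg source recomputes to 20.0."""
        e = make_entry("E1", value=2.0, unit=UL_MG, source_value=18.9, source_unit=ML_KG)
        fixed, action, _ = cross_check(e, CURATED)
        assert action.action == "unit_recalculated"
        from clintpipe.pk_model import convert_units

        assert convert_units(fixed.value, fixed.unit) == pytest.approx(20.0)

    def test_missing_source_flagged_unverifiable(self):
        e = make_entry("E1", source_value=None, source_unit=None)
        fixed, action, unverifiable = cross_check(e, CURATED)
        assert action is None and unverifiable


class TestQualifierClassSets:
    @pytest.mark.parametrize(
        "qualifier,value,expected",
        [
            (">", 20.0, {StabilityClass.MODERATE, StabilityClass.UNSTABLE}),
            (">", 300.0, {StabilityClass.UNSTABLE}),
            (">=", 300.0, {StabilityClass.UNSTABLE}),
            ("<", 20.0, {StabilityClass.STABLE}),
            ("<=", 20.0, {StabilityClass.STABLE, StabilityClass.MODERATE}),
            ("=", 42.0, {StabilityClass.MODERATE}),
        ],
    )
    def test_known_bounds(self, qualifier, value, expected):
        assert classes_consistent_with(qualifier, value, CURATED) == expected

    @pytest.mark.parametrize("qualifier", [">", ">=", "<", "<="])
    @pytest.mark.parametrize("bound", [0.0, 5.0, 19.9, 20.0, 150.0, 299.9, 300.0, 1000.0])
    def test_against_enumeration_oracle(self, qualifier, bound):
        """Class set equals brute-force enumeration over a dense value grid."""
        grid = np.concatenate([np.linspace(0, 2000, 40001), [bound, bound + 1e-9, max(bound - 1e-9, 0)]])
        ops = {">": np.greater, ">=": np.greater_equal, "<": np.less, "<=": np.less_equal}
        feasible = grid[ops[qualifier](grid, bound)]
        oracle = {assign_class(v) for v in feasible}
        assert classes_consistent_with(qualifier, bound, CURATED) == oracle


class TestResolveCompound:
    def test_agreeing_entries_keep_class(self):
        group = [(make_entry("E1", value=15.0), 15.0), (make_entry("E2", value=18.0), 18.0)]
        cls, rep, _ = resolve_compound(group, CURATED)
        assert cls is StabilityClass.STABLE
        assert rep == pytest.approx(np.sqrt(15 * 18))  # geometric mean

    def test_cross_class_conflict_removed(self):
        group = [(make_entry("E1", value=42.0), 42.0), (make_entry("E2", value=933.3), 933.3)]
        cls, _, reason = resolve_compound(group, CURATED)
        assert cls is None and "category" in reason

    def test_bound_pinning_single_class_kept(self):
        group = [(make_entry("E1", qualifier=">", value=300.0), 300.0)]
        cls, _, _ = resolve_compound(group, CURATED)
        assert cls is StabilityClass.UNSTABLE

    def test_ambiguous_bound_alone_removed(self):
        group = [(make_entry("E1", qualifier=">", value=20.0), 20.0)]
        cls, _, _ = resolve_compound(group, CURATED)
        assert cls is None

    def test_bound_corroborated_by_exact_entry_kept(self):
        group = [
            (make_entry("E1", qualifier=">", value=20.0), 20.0),
            (make_entry("E2", value=42.0), 42.0),
        ]
        cls, _, _ = resolve_compound(group, CURATED)
        assert cls is StabilityClass.MODERATE


class TestBuildDatasets:
    def _fixture(self):
        entries = []
        # 6 clean compounds
        for i in range(6):
            entries.append(make_entry(f"K{i}", compound_id=f"CPD{i}", value=10.0 + i))
        # 2 off-protocol
        entries.append(make_entry("P1", compound_id="OFF1", temperature_C=30.0))
        entries.append(make_entry("P2", compound_id="OFF2", cofactor=None))
        # one per-g-liver misinterpretation: true 42, recorded as mL/min/g
        entries.append(
            make_entry("M1", compound_id="MIS1", value=42.0, unit=ML_G, source_value=42.0, source_unit=UL_MG)
        )
        return entries

    def test_protocol_violations_split_the_modes(self):
        entries = self._fixture()
        curated = build_datasets(entries, CURATED)
        non_curated = build_datasets(entries, NON_CURATED)
        curated_ids = {r.compound_id for r in curated.records}
        non_ids = {r.compound_id for r in non_curated.records}
        assert {"OFF1", "OFF2"}.isdisjoint(curated_ids)
        assert {"OFF1", "OFF2"} <= non_ids

    def test_misread_unit_flips_class_only_without_curation(self):
        """The canonical 42 -> 933.3 story: unstable naively, moderate curated."""
        entries = self._fixture()
        curated = {r.compound_id: r.stability for r in build_datasets(entries, CURATED).records}
        non = {r.compound_id: r.stability for r in build_datasets(entries, NON_CURATED).records}
        assert non["MIS1"] is StabilityClass.UNSTABLE
        assert curated["MIS1"] is StabilityClass.MODERATE

    @pytest.mark.parametrize("mode", ["curated", "non_curated"])
    def test_ledger_conservation(self, mode):
        entries = self._fixture()
        result = build_datasets(entries, CurationConfig(mode=mode))
        assert len(result.ledger) == len(entries)
        assert sum(result.action_counts().values()) == len(entries)

    def test_duplicate_agreeing_entries_do_not_change_labels(self):
        entries = [make_entry("E1", compound_id="A", value=10.0)]
        base = build_datasets(entries, CURATED).records[0].stability
        dup = entries + [make_entry("E2", compound_id="A", value=12.0)]
        assert build_datasets(dup, CURATED).records[0].stability is base

    def test_empty_output_warns(self):
        entries = [make_entry("E1", value=None)]
        with pytest.warns(UserWarning, match="empty"):
            build_datasets(entries, CURATED)


class TestUnstableFractionMonotonicity:
    def test_nondecreasing_in_misread_rate(self):
        """Naive conversion inflates values, so more misreads mean a larger
        non-curated unstable fraction."""
        from clintpipe.synthetic_data import ErrorRates, GeneratorConfig, generate_entry_table

        fractions = []
        for rate in (0.0, 0.3, 0.8):
            rates = ErrorRates(per_g_liver_misinterpretation=rate, value_transcription=0,
                               qualifier_range=0, duplicate_conflicting=0, off_protocol=0)
            entries, _, _ = generate_entry_table(
                GeneratorConfig(n_compounds=150, seed=11, error_rates=rates)
            )
            records = build_datasets(entries, NON_CURATED).records
            fractions.append(
                sum(r.stability is StabilityClass.UNSTABLE for r in records) / len(records)
            )
        assert fractions[0] <= fractions[1] <= fractions[2]
        assert fractions[2] > fractions[0]
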