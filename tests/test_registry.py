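"""Parameter-registry bookkeeping: counts, segmentation, offsets, groups."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiotwin import registry as reg


class TestHomogeneousRegistry:
    def test_total_size(self, homogeneous_registry):
        assert homogeneous_registry.size == 100

    def test_category_breakdown(self, homogeneous_registry):
        counts = homogeneous_registry.category_counts()
        assert counts == {
            "global-hemodynamic": 3,
            "pulmonary-systemic": 12,
            "valve": 8,
            "pericardium": 3,
            "mechanical-activation": 4,
            "myocardial-tissue": 70,
        }

    def test_tissue_split_by_wall(self, homogeneous_registry):
        by_wall = {}
        for s in homogeneous_registry:
            if s.category == "myocardial-tissue":
                by_wall[s.wall] = by_wall.get(s.wall, 0) + 1
        assert by_wall == {"septum-LVFW": 28, "RV": 14, "LA": 14, "RA": 14}

    def test_ranges_nested(self, homogeneous_registry):
        for s in homogeneous_registry:
            lo, hi = s.msm_range
            plo, phi = s.pso_bounds
            assert plo <= lo <= hi <= phi


class TestSegmentation:
    @pytest.mark.parametrize("n_seg,expected", [(2, 100), (6, 160), (18, 340)])
    def test_sizes(self, homogeneous_registry, n_seg, expected):
        assert reg.apply_segmentation(homogeneous_registry, n_seg).size == expected

    def test_rejects_single_segment(self, homogeneous_registry):
        with pytest.raises(reg.RegistryError):
            reg.apply_segmentation(homogeneous_registry, 1)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(n_seg=st.integers(min_value=2, max_value=30))
    def test_size_formula(self, n_seg):
        registry = reg.build_homogeneous_registry()
        segmented = reg.apply_segmentation(registry, n_seg)
        assert segmented.size == 100 + 14 * n_seg - 28 + (n_seg - 2)
        # brute-force recount by category
        lv = [s for s in segmented
              if s.wall == "septum-LVFW" and s.scope == "regional"]
        assert len(lv) == 14 * n_seg
        dts = [s for s in segmented if s.name == "dT"]
        assert len(dts) == n_seg - 2


class TestGlobalOffsets:
    def test_six_segment_with_offsets(self, registry6):
        assert reg.add_global_offsets(registry6).size == 174

    def test_exactly_14_offsets_added(self, registry6):
        added = reg.add_global_offsets(registry6)
        gos = [s for s in added if s.scope == "global-offset"]
        assert len(gos) == len(reg.LV_TISSUE_TYPES) == 14

    def test_idempotent(self, registry6):
        once = reg.add_global_offsets(registry6)
        twice = reg.add_global_offsets(once)
        assert twice.size == once.size

    def test_no_regional_tissue_unchanged(self, homogeneous_registry):
        globals_only = homogeneous_registry.select(["q0", "p0"])
        assert reg.add_global_offsets(globals_only).size == globals_only.size


class TestExpansion:
    def test_final_subset_is_75(self, registry6):
        sub = reg.build_estimation_subset(
            registry6, ["q0", "dTauAv", "ADO_LV", "dT", "AmRef", "Ls0Pas", "k1"])
        assert sub.size == 3 + 4 * 6
        expanded = reg.expand_subset(sub)
        assert expanded.size == 75
        assert expanded.n_seg == 18

    def test_regional_group_triplicates(self, registry6):
        sub = reg.build_estimation_subset(registry6, ["k1"])
        expanded = reg.expand_subset(sub)
        assert len(expanded.groups()["k1"]) == 18

    def test_globals_carried_once(self, registry6):
        sub = registry6.select(["q0", "dTauAv"])
        assert reg.expand_subset(sub).size == 2

    def test_group_count_preserved(self, registry6):
        sub = reg.build_estimation_subset(registry6, ["q0", "dT", "k1"])
        assert set(reg.expand_subset(sub).groups()) == set(sub.groups())

    def test_unmapped_segment_rejected(self, registry6):
        sub = reg.build_estimation_subset(registry6, ["dT"])
        with pytest.raises(reg.RegistryError):
            reg.expand_subset(sub, {0: (0, 1, 2)})


class TestDemotion:
    def test_regional_group_becomes_offset(self, registry18):
        sub = reg.build_estimation_subset(registry18, ["q0", "k1"])
        assert len([s for s in sub if s.name == "k1"]) == 18
        demoted = reg.demote_to_global_offset(sub, "k1")
        assert not demoted.has_group("k1")
        assert demoted.has_group("k1_GO")
        assert sub.size - demoted.size == 17  # 18 specs -> 1 offset

    def test_global_fixed_to_reference(self, registry6):
        sub = registry6.select(["q0", "p0"])
        demoted = reg.demote_to_global_offset(sub, "q0")
        assert demoted.size == sub.size - 1
        assert demoted.fixed["q0"] == sub.get("q0").reference_value

    def test_double_demotion_flagged(self, registry6):
        sub = reg.build_estimation_subset(registry6, ["q0", "k1"])
        once = reg.demote_to_global_offset(sub, "k1")
        with pytest.raises(reg.RegistryError):
            reg.demote_to_global_offset(once, "k1")

    def test_unknown_group_rejected(self, registry6):
        with pytest.raises(reg.RegistryError):
            reg.demote_to_global_offset(registry6, "nonexistent")


def test_yaml_round_trip(tmp_path, registry6):
    sub = reg.build_estimation_subset(registry6, ["q0", "dT"])
    path = tmp_path / "subset.yaml"
    sub.to_yaml(path)
    back = reg.ParameterSubset.from_yaml(path)
    assert back.size == sub.size
    assert back.n_seg == sub.n_seg
    for a, b in zip(back, sub):
        assert a == b


def test_forward_model_names_resolve(registry6):
    """Every parameter the bundled model consumes exists in the registry."""
    from cardiotwin.forward_model import _REQUIRED_GLOBALS, _REQUIRED_SEGMENTAL
    names = {s.name for s in registry6}
    for name in _REQUIRED_GLOBALS:
        assert name in names
    for name in _REQUIRED_SEGMENTAL:
        if name == "dT":  # delays beyond the first two walls
            continue
        assert name in names
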