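"""Characterization factors and the canonical polymer CF dataset."""

import numpy as np
import pandas as pd
import pytest

from plastifate import (EffectParameters, FateFactors, canonical_cf_lookup,
                        comparative_metrics, endpoint_cf, load_canonical_cfs,
                        midpoint_cf, recipe_species_yr,
                        validate_canonical_dataset)
from plastifate.characterization import (POLYMERS, SHAPES, SIZES_UM,
                                         compute_cf_records, _round_half_up)
from plastifate.errors import CanonicalLookupError
from plastifate.fate import DEMO_FATE_PARAMETERS


class TestCFChain:
    def test_zero_fate_gives_zero_cf(self):
        eff = EffectParameters()
        assert midpoint_cf(FateFactors(0.0, 0.0), eff) == 0.0
        assert endpoint_cf(0.0, eff) == 0.0
        assert recipe_species_yr(0.0, eff) == 0.0

    def test_midpoint_worked_example(self):
        ff = FateFactors(ff_water=2.131, ff_sediment=65.57)
        eff = EffectParameters(eef_water=1000.0, eef_sediment=100.0)
        assert midpoint_cf(ff, eff) == pytest.approx(8688.0, abs=5.0)

    def test_midpoint_linear_in_eefs(self):
        ff = FateFactors(1.7, 42.0)
        eff = EffectParameters(eef_water=500.0, eef_sediment=80.0)
        doubled = EffectParameters(eef_water=1000.0, eef_sediment=160.0)
        assert midpoint_cf(ff, doubled) == pytest.approx(
            2.0 * midpoint_cf(ff, eff), rel=1e-12)

    def test_endpoint_matches_canonical_ratio(self):
        """SF/depth defaults reproduce the constant endpoint/midpoint ratio
        of the canonical table (PAF·day -> PDF·yr conversion explicit)."""
        eff = EffectParameters()
        assert endpoint_cf(5.01e7, eff) == pytest.approx(1.363e3, rel=0.01)

    def test_endpoint_requires_positive_depth(self):
        with pytest.raises(ValueError):
            EffectParameters(water_depth=0.0)

    def test_recipe_conversion(self):
        assert recipe_species_yr(5.01e3) == pytest.approx(1.733e-6, abs=1e-9)

    def test_recipe_linear(self):
        assert recipe_species_yr(10.0) == pytest.approx(
            10.0 * recipe_species_yr(1.0), rel=1e-12)


class TestCanonicalDataset:
    def test_full_grid_is_present(self):
        df = load_canonical_cfs()
        assert len(df) == 45
        assert set(df["polymer"]) == set(POLYMERS)
        assert set(df["shape"]) == set(SHAPES)
        assert set(df["size_um"]) == set(SIZES_UM)

    @pytest.mark.parametrize("polymer,shape,size,level,expected", [
        ("PCL", "sphere", 5000, "midpoint", 5.01e7),
        ("PCL", "sphere", 5000, "endpoint", 1.36e3),
        ("PLA", "sphere", 5000, "midpoint", 1.84e8),
        ("PLA", "sphere", 5000, "endpoint", 5.01e3),
        ("PBSA", "film", 1, "midpoint", 2.25e5),
        ("PCL", "sphere", 1, "midpoint", 3.24e3),
        ("PLA", "film", 5000, "midpoint", 1.97e8),
    ])
    def test_lookup_returns_printed_values(self, polymer, shape, size, level,
                                           expected):
        assert canonical_cf_lookup(polymer, shape, size, level) == expected

    def test_unknown_key_lists_valid_space(self):
        with pytest.raises(CanonicalLookupError, match="valid keys"):
            canonical_cf_lookup("PET", "sphere", 100, "midpoint")
        with pytest.raises(CanonicalLookupError):
            canonical_cf_lookup("PCL", "sphere", 42, "midpoint")
        with pytest.raises(CanonicalLookupError):
            canonical_cf_lookup("PCL", "sphere", 100, "damage")

    def test_extrema(self):
        mid = load_canonical_cfs()["midpoint_paf_m3_day_per_kg"]
        assert mid.min() == 3.24e3
        assert mid.max() == 1.97e8


class TestComparativeMetrics:
    def test_size_effect_maximum_for_fast_degrader(self):
        """Fast-degrading small spheres: 1 µm vs 5000 µm differs by 99.99%."""
        m = comparative_metrics()
        pcl_sphere = m.size_effect_pct.query(
            "polymer == 'PCL' and shape == 'sphere'")["pct_smaller"].iloc[0]
        assert _round_half_up(pcl_sphere, 2) == 99.99
        assert _round_half_up(m.max_size_effect_pct, 2) == 99.99

    def test_degradability_reduction_vs_slow_polymer(self):
        m = comparative_metrics()
        assert _round_half_up(m.max_reduction_vs_pla["PCL"]) == 99

    def test_shape_effect_for_smallest_particles(self):
        m = comparative_metrics()
        pla_1um_sphere = m.shape_vs_film_pct.query(
            "polymer == 'PLA' and size_um == 1 and shape == 'sphere'"
        )["pct_below_film"].iloc[0]
        assert _round_half_up(pla_1um_sphere) == 54

    def test_incomplete_grid_rejected(self):
        df = load_canonical_cfs().iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            comparative_metrics(df)

    def test_ratios_invariant_to_effect_scaling(self):
        """Comparative percentages are identical at midpoint and endpoint
        level: the EEF/SF/depth factors cancel in every ratio."""
        mid = comparative_metrics(level="midpoint")
        end = comparative_metrics(level="endpoint")
        # the two levels are tabulated to 3 significant figures, so the
        # percentages can differ by up to ~0.5 points from rounding alone
        assert np.allclose(
            mid.reduction_vs_pla_pct["pct_reduction_vs_pla"],
            end.reduction_vs_pla_pct["pct_reduction_vs_pla"], atol=0.5)


class TestValidateCanonicalDataset:
    def test_shipped_dataset_passes_all_assertions(self):
        report = validate_canonical_dataset()
        assert report.passed, report.failures

    def test_endpoint_midpoint_ratio_is_constant(self):
        df = load_canonical_cfs()
        ratio = df["endpoint_pdf_m2_yr_per_kg"] / df["midpoint_paf_m3_day_per_kg"]
        assert ((ratio / ratio.median() - 1.0).abs() < 0.01).all()
        assert ratio.median() == pytest.approx(2.72e-5, rel=0.005)

    def test_transposed_cell_is_named(self):
        df = load_canonical_cfs().copy()
        i = df.query("polymer=='PCL' and shape=='sphere' and size_um==100").index[0]
        j = df.query("polymer=='PCL' and shape=='sphere' and size_um==1000").index[0]
        col = "midpoint_paf_m3_day_per_kg"
        df.loc[i, col], df.loc[j, col] = df.loc[j, col], df.loc[i, col]
        report = validate_canonical_dataset(df)
        assert not report.passed
        assert any("PCL" in f and "sphere" in f for f in report.failures)

    def test_empty_dataset_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            validate_canonical_dataset(load_canonical_cfs().iloc[:0])


class TestComputedCFs:
    def test_computed_table_monotone_and_labelled(self):
        """CFs computed from the demo fate/effect parameters reproduce the
        structural regularities: larger and slower-degrading particles have
        larger CFs."""
        df = compute_cf_records(
            {"PLA": 0.87, "PBSA": 1.98, "PCL": 25.95},
            DEMO_FATE_PARAMETERS, EffectParameters())
        assert (df["source"] == "computed").all()
        report = validate_canonical_dataset(df)
        size_fail = [f for f in report.failures if "monotonicity" in f]
        shape_fail = [f for f in report.failures if "shape ordering" in f]
        degr_fail = [f for f in report.failures if "degradability" in f]
        assert not size_fail and not shape_fail and not degr_fail

    def test_cf_monotone_decreasing_in_ssdr(self):
        cfs = [
            compute_cf_records({"X": vd}, DEMO_FATE_PARAMETERS,
                               EffectParameters())
            ["midpoint_paf_m3_day_per_kg"].sum()
            for vd in (0.5, 5.0, 50.0)
        ]
        assert cfs[0] > cfs[1] > cfs[2]
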