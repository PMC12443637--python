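"""Longitudinal statistics: time effects, the ΔT metric and its
standardized screen."""

import numpy as np
import pandas as pd
import pytest

from replicamap.errors import ParameterError
from replicamap.longitudinal import (
    build_series,
    delta_t,
    time_effect,
    treatment_effect,
    tumour_abundance,
)


def _series(rows):
    return pd.DataFrame(
        rows, columns=["species_mz", "brain_id", "timepoint", "arm", "abundance"]
    )


def _full_series(values_by_species, brains=("B1", "B2", "B3")):
    """values_by_species: mz -> {(timepoint, arm): value or per-brain list}."""
    rows = []
    for mz, cells in values_by_species.items():
        for (tp, arm), v in cells.items():
            vals = v if np.ndim(v) else [v] * len(brains)
            for b, val in zip(brains, vals):
                rows.append((mz, b, tp, arm, val))
    return _series(rows)


class TestTumourAbundance:
    def test_region_mean(self):
        from replicamap.core import CommonRepresentation
        from replicamap.regions import RegionLabels

        rep = CommonRepresentation(
            matrix=np.array([[1.0], [3.0], [10.0]]),
            feature_mz=np.array([700.0]),
            coords=np.array([[0, 0], [1, 0], [2, 0]]),
        )
        labels = RegionLabels(
            labels=np.array([0, 0, 1]), coords=rep.coords, pixel_size=100.0,
            region_names={0: "T", 1: "GM"},
        )
        table = tumour_abundance(rep, labels, "T")
        assert table["abundance"][0] == 2.0
        assert not table["undetectable"][0]

    def test_all_zero_species_flagged(self):
        from replicamap.core import CommonRepresentation
        from replicamap.regions import RegionLabels

        rep = CommonRepresentation(
            matrix=np.zeros((2, 1)), feature_mz=np.array([700.0]),
            coords=np.array([[0, 0], [1, 0]]),
        )
        labels = RegionLabels(
            labels=np.array([0, 0]), coords=rep.coords, pixel_size=100.0,
            region_names={0: "T"},
        )
        table = tumour_abundance(rep, labels, "T")
        assert table["abundance"][0] == 0.0 and table["undetectable"][0]

    def test_absent_region_rejected(self):
        from replicamap.core import CommonRepresentation
        from replicamap.regions import RegionLabels

        rep = CommonRepresentation(
            matrix=np.ones((2, 1)), feature_mz=np.array([700.0]),
            coords=np.array([[0, 0], [1, 0]]),
        )
        labels = RegionLabels(
            labels=np.array([0, 0]), coords=rep.coords, pixel_size=100.0,
            region_names={0: "GM"},
        )
        with pytest.raises(ParameterError):
            tumour_abundance(rep, labels, "T")


class TestTimeEffect:
    def test_identical_timepoints_not_significant(self):
        series = _full_series({700.0: {("D0", "T0"): [1, 2, 3], ("D5", "T0"): [1, 2, 3]}})
        result = time_effect(series)
        row = result.table.iloc[0]
        assert row["log2_ratio"] == pytest.approx(0.0, abs=1e-9)
        assert not row["significant"]

    def test_eightfold_increase_called(self):
        series = _full_series({700.0: {("D0", "T0"): [1, 1, 1], ("D5", "T0"): [8, 8, 8]}})
        result = time_effect(series)
        row = result.table.iloc[0]
        assert row["log2_ratio"] == pytest.approx(3.0, abs=5e-3)
        assert row["p_time"] < 0.01
        assert row["significant"]

    def test_undetectable_at_d5_reported_separately(self):
        series = _full_series({700.0: {("D0", "T0"): [2, 2, 2], ("D5", "T0"): [0, 0, 0]}})
        result = time_effect(series)
        row = result.table.iloc[0]
        assert row["undetectable_d5"] and not row["significant"]

    def test_requires_two_brains(self):
        series = _series([(700.0, "B1", "D0", "T0", 1.0), (700.0, "B1", "D5", "T0", 2.0)])
        with pytest.raises(ParameterError):
            time_effect(series)

    def test_anova_p_matches_statsmodels(self):
        """Cross-check the hand-rolled regression F-test against statsmodels."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(0)
        d0, d5 = rng.normal(1.0, 0.2, 3), rng.normal(2.0, 0.2, 3)
        series = _full_series({700.0: {("D0", "T0"): d0, ("D5", "T0"): d5}})
        p_ours = time_effect(series).table["p_time"][0]
        df = pd.DataFrame(
            {"y": np.concatenate([d0, d5]), "t": [0, 0, 0, 1, 1, 1]}
        )
        anova = sm.stats.anova_lm(ols("y ~ t", df).fit(), typ=2)
        assert p_ours == pytest.approx(anova.loc["t", "PR(>F)"], rel=1e-9)

    def test_phantom_recovery(self, longitudinal_data):
        """Planted temporal shifts are called; untouched species are not."""
        series = longitudinal_data["series"]
        tables = longitudinal_data["tables"]
        centres = longitudinal_data["axis"].centres

        def to_bin(mzs):
            return {float(centres[int(np.argmin(np.abs(centres - m)))]) for m in mzs}

        result = time_effect(series)
        planted = to_bin(tables["time_effects"])
        treated = to_bin(tables["treatment_effects"])
        called = set(result.significant_mz)
        assert len(called & planted) >= 0.9 * len(planted)
        nulls = result.table[~result.table["species_mz"].isin(planted | treated)]
        assert nulls["significant"].mean() <= 0.01


class TestDeltaT:
    def test_arm_independent_drift_cancels_exactly(self):
        series = _full_series({
            700.0: {("D0", "T0"): 5.0, ("D5", "T0"): 7.5,
                    ("D0", "T1"): 4.0, ("D5", "T1"): 6.5},
            701.0: {("D0", "T0"): 1.0, ("D5", "T0"): 1.0,
                    ("D0", "T1"): 1.0, ("D5", "T1"): 1.0},
        })
        result = delta_t(series)
        table = result.table.set_index("species_mz")
        assert table.loc[700.0, "delta_t"] == 0.0  # ΔT0 = ΔT1 = 2.5
        assert table.loc[701.0, "delta_t"] == 0.0

    def test_hand_computed_cells(self):
        series = _full_series({
            700.0: {("D0", "T0"): 5.0, ("D5", "T0"): 5.0,
                    ("D0", "T1"): 5.0, ("D5", "T1"): 1.0},
            701.0: {("D0", "T0"): 2.0, ("D5", "T0"): 2.0,
                    ("D0", "T1"): 2.0, ("D5", "T1"): 2.0},
            702.0: {("D0", "T0"): 1.0, ("D5", "T0"): 1.0,
                    ("D0", "T1"): 1.0, ("D5", "T1"): 3.0},
        })
        table = delta_t(series).table.set_index("species_mz")
        assert table.loc[700.0, "delta_t0"] == 0.0
        assert table.loc[700.0, "delta_t1"] == -4.0
        assert table.loc[700.0, "delta_t"] == -4.0

    def test_z_scores_standardized(self, longitudinal_data):
        table = delta_t(longitudinal_data["series"]).table
        z = table.loc[table["in_universe"], "z_delta"]
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=0) - 1.0) < 1e-9

    def test_missing_cell_excludes_brain_for_species(self):
        series = _full_series({
            700.0: {("D0", "T0"): 1.0, ("D5", "T0"): 2.0,
                    ("D0", "T1"): 1.0, ("D5", "T1"): 2.0},
        })
        series = series[~((series["brain_id"] == "B3") & (series["timepoint"] == "D5")
                          & (series["arm"] == "T1"))]
        table = delta_t(series).table
        assert table["n_brains"][0] == 2
        assert table["n_brains_excluded"][0] == 1

    def test_zeroed_species_most_negative(self, longitudinal_data):
        """The species forced to zero in treated tumours dominates the screen."""
        table = delta_t(longitudinal_data["series"]).table
        centres = longitudinal_data["axis"].centres
        bin_692 = float(centres[int(np.argmin(np.abs(centres - 692.45)))])
        most_negative = table.loc[table["z_delta"].idxmin(), "species_mz"]
        assert most_negative == bin_692


class TestTreatmentEffect:
    def test_global_scaling_leaves_calls_unchanged(self, longitudinal_data):
        series = longitudinal_data["series"]
        doubled = series.copy()
        doubled["abundance"] *= 2.0
        a = treatment_effect(series).table["significant"]
        b = treatment_effect(doubled).table["significant"]
        assert (a == b).all()

    def test_thresholds_monotone(self, longitudinal_data):
        series = longitudinal_data["series"]
        strict = set(treatment_effect(series, p_threshold=0.001, z_threshold=1.0).significant_mz)
        loose = set(treatment_effect(series, p_threshold=0.01, z_threshold=0.5).significant_mz)
        assert strict <= loose

    def test_phantom_recovery_and_null_rate(self, longitudinal_data):
        series = longitudinal_data["series"]
        tables = longitudinal_data["tables"]
        centres = longitudinal_data["axis"].centres

        def to_bin(mzs):
            return {float(centres[int(np.argmin(np.abs(centres - m)))]) for m in mzs}

        result = treatment_effect(series)
        planted = to_bin(tables["treatment_effects"])
        time_planted = to_bin(tables["time_effects"])
        called = set(result.significant_mz)
        assert len(called & planted) >= 0.9 * len(planted)
        nulls = result.table[~result.table["species_mz"].isin(planted | time_planted)]
        assert nulls["significant"].mean() <= 0.02

    def test_recovered_signs_match_planted_direction(self, longitudinal_data):
        series = longitudinal_data["series"]
        tables = longitudinal_data["tables"]
        centres = longitudinal_data["axis"].centres
        effects = {
            float(centres[int(np.argmin(np.abs(centres - m)))]): f
            for m, f in tables["treatment_effects"].items()
        }
        result = treatment_effect(series)
        recovered = result.table[result.table["species_mz"].isin(effects)
                                 & result.table["significant"]]
        for _, row in recovered.iterrows():
            decreasing = effects[row["species_mz"]] < 1.0
            assert (row["delta_t"] < 0) == decreasing

    def test_interaction_and_paired_modes_concordant(self, longitudinal_data):
        series = longitudinal_data["series"]
        tables = longitudinal_data["tables"]
        centres = longitudinal_data["axis"].centres
        planted = [
            float(centres[int(np.argmin(np.abs(centres - m)))])
            for m in tables["treatment_effects"]
        ]
        a = treatment_effect(series, mode="interaction").table.set_index("species_mz")
        b = treatment_effect(series, mode="paired").table.set_index("species_mz")
        agree = (a.loc[planted, "significant"] == b.loc[planted, "significant"]).mean()
        assert agree >= 0.9

    def test_null_simulation_false_call_rate(self):
        """No planted effect, 3 brains: calls stay at or below 2%."""
        rng = np.random.default_rng(0)
        species = {}
        for i in range(300):
            base = rng.exponential(1.0)
            species[600.0 + i] = {
                (tp, arm): base * rng.normal(1.0, 0.05, 3)
                for tp in ("D0", "D5") for arm in ("T0", "T1")
            }
        series = _full_series(species)
        result = treatment_effect(series)
        assert result.table["significant"].mean() <= 0.02
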