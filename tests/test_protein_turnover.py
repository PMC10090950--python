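"""Tests for the TMT-SILAM proteome processing pipeline."""

import numpy as np
import pandas as pd
import pytest

from trail.protein_turnover import (
    QualityConfig,
    assign_deciles,
    filter_coverage,
    fit_protein_kt,
    normalize_to_t0,
    process_reporter_table,
    relative_abundance,
)
from trail.synthetic_data import SimConfig, simulate_proteome_timecourse

TIMES = [0.0, 2.0, 4.0, 8.0, 16.0, 32.0]


def make_table(psm_vectors: dict[str, list[int]]) -> pd.DataFrame:
    rows = []
    for pid, psms in psm_vectors.items():
        for j, (t, psm) in enumerate(zip(TIMES, psms)):
            rows.append({
                "protein_id": pid, "replicate": 1, "channel": f"ch{j}",
                "timepoint_days": t, "reporter_sn": 100.0 * np.exp(-0.2 * t),
                "psm_count": psm,
            })
    return pd.DataFrame(rows)


class TestFilterCoverage:
    def test_toy_table_brute_force(self):
        vectors = {
            "A": [3, 3, 3, 3, 3, 3],   # boundary inclusive -> retained
            "B": [4, 4, 4, 4, 4, 4],   # retained
            "C": [3, 2, 3, 3, 3, 3],   # one channel below -> dropped
            "D": [0, 0, 0, 0, 0, 0],   # dropped
            "E": [5, 5, 5, 5, 5, 1],   # last channel below -> dropped
        }
        out = filter_coverage(make_table(vectors), QualityConfig())
        assert sorted(out["protein_id"].unique()) == ["A", "B"]

    def test_missing_channel_drops_replicate(self):
        table = make_table({"A": [3] * 6, "B": [3] * 6})
        table = table[~((table.protein_id == "B") & (table.channel == "ch2"))]
        out = filter_coverage(table, QualityConfig())
        assert sorted(out["protein_id"].unique()) == ["A"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            filter_coverage(make_table({}).head(0), QualityConfig())


class TestNormalizeToT0:
    def test_division_by_t0(self):
        table = make_table({"A": [3] * 6})
        table.loc[table.timepoint_days == 8.0, "reporter_sn"] = 50.0
        table.loc[table.timepoint_days == 0.0, "reporter_sn"] = 100.0
        out = normalize_to_t0(table)
        assert out.loc[out.timepoint_days == 8.0, "frac_unlabeled"].iat[0] == pytest.approx(0.5)
        assert out.loc[out.timepoint_days == 0.0, "frac_unlabeled"].iat[0] == 1.0

    def test_constant_channels_give_unit_series(self):
        table = make_table({"A": [3] * 6})
        table["reporter_sn"] = 77.0
        out = normalize_to_t0(table)
        assert np.allclose(out["frac_unlabeled"], 1.0)

    def test_idempotence(self):
        table = make_table({"A": [3] * 6})
        once = normalize_to_t0(table)
        once2 = once.copy()
        once2["reporter_sn"] = once2["frac_unlabeled"]
        twice = normalize_to_t0(once2)
        assert np.allclose(once["frac_unlabeled"].values, twice["frac_unlabeled"].values)

    def test_zero_t0_excluded(self):
        table = make_table({"A": [3] * 6, "B": [3] * 6})
        table.loc[(table.protein_id == "B") & (table.timepoint_days == 0.0), "reporter_sn"] = 0.0
        out = normalize_to_t0(table)
        assert sorted(out["protein_id"].unique()) == ["A"]


class TestFitProteinKt:
    def test_recovery_and_qc_pass(self):
        cfg = SimConfig(n_proteins=20, rate_median=0.3, rate_sigma=1e-9,
                        baseline_max=0.0, noise_sigma=0.01, seed=7)
        table, truth = simulate_proteome_timecourse(cfg)
        fits = process_reporter_table(table)
        merged = fits.merge(truth, on="protein_id", suffixes=("_est", "_true"))
        assert (merged["passed"]).mean() > 0.9
        ok = merged[merged.passed]
        assert np.all(np.abs(ok.k_t_est - ok.k_t_true) / ok.k_t_true < 0.05)

    def test_low_tstat_fails_gate(self):
        # sub-threshold t-statistic: flat noisy series barely decaying
        rng = np.random.default_rng(5)
        rows = []
        for rep in (1, 2):
            for j, t in enumerate(TIMES):
                rows.append({
                    "protein_id": "X", "replicate": rep, "channel": f"ch{j}",
                    "timepoint_days": t,
                    "reporter_sn": 100.0 * (1 + rng.normal(0, 0.12)),
                    "psm_count": 5,
                })
        df = normalize_to_t0(pd.DataFrame(rows))
        fits = fit_protein_kt(df, QualityConfig())
        row = fits.iloc[0]
        assert (not row.passed) or row.t_stat > 3

    def test_single_replicate_fails_gate(self):
        table = make_table({"A": [5] * 6})
        fits = fit_protein_kt(normalize_to_t0(table), QualityConfig(min_replicates=2))
        assert not fits.iloc[0].passed
        fits1 = fit_protein_kt(normalize_to_t0(table), QualityConfig(min_replicates=1))
        assert fits1.iloc[0].passed

    def test_qc_pass_fraction_decreases_with_noise(self):
        fracs = []
        for sigma in (0.01, 0.05, 0.15):
            cfg = SimConfig(n_proteins=60, noise_sigma=sigma, seed=9)
            table, _ = simulate_proteome_timecourse(cfg)
            fits = process_reporter_table(table)
            fracs.append(fits["passed"].mean())
        assert fracs[0] >= fracs[1] >= fracs[2]


class TestAssignDeciles:
    def test_ten_distinct_values(self):
        deciles = assign_deciles(np.arange(10, 0, -1.0))
        assert sorted(deciles) == list(range(1, 11))
        assert deciles[0] == 10  # largest rate -> fastest decile

    def test_all_tied_still_partitions(self):
        deciles = assign_deciles(np.ones(25))
        counts = np.bincount(deciles, minlength=11)[1:]
        assert counts.max() - counts.min() <= 1

    def test_matches_sort_and_slice_oracle(self, rng):
        k = rng.lognormal(0, 1, 100)
        deciles = assign_deciles(k)
        order = np.argsort(k, kind="stable")
        oracle = np.empty(100, dtype=int)
        for i, chunk in enumerate(np.array_split(order, 10)):
            oracle[chunk] = i + 1
        assert np.array_equal(deciles, oracle)

    def test_monotone_transform_invariance(self, rng):
        k = rng.lognormal(0, 1, 57)
        assert np.array_equal(assign_deciles(k), assign_deciles(np.log(k)))
        assert np.array_equal(assign_deciles(k), assign_deciles(k ** 3))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            assign_deciles(np.arange(9))


class TestRelativeAbundance:
    def test_identical_replicates_geometric_mean(self):
        rows = []
        for bio in (1, 2):
            for ch in ("a", "b"):
                for pid, val in (("P1", 200.0), ("P2", 200.0)):
                    rows.append({"protein_id": pid, "bio_replicate": bio,
                                 "channel": ch, "intensity": val})
        score = relative_abundance(pd.DataFrame(rows), {"P1": 100, "P2": 100})
        # equal everything -> both proteins at the replicate maximum (1.0)
        assert np.allclose(score.values, 1.0)

    def test_three_protein_hand_computed(self):
        # single bio replicate, two channels with unequal sums
        rows = [
            {"protein_id": "P1", "bio_replicate": 1, "channel": "a", "intensity": 100.0},
            {"protein_id": "P2", "bio_replicate": 1, "channel": "a", "intensity": 200.0},
            {"protein_id": "P3", "bio_replicate": 1, "channel": "a", "intensity": 700.0},
            {"protein_id": "P1", "bio_replicate": 1, "channel": "b", "intensity": 220.0},
            {"protein_id": "P2", "bio_replicate": 1, "channel": "b", "intensity": 380.0},
            {"protein_id": "P3", "bio_replicate": 1, "channel": "b", "intensity": 1400.0},
        ]
        lengths = {"P1": 100, "P2": 200, "P3": 700}
        # hand computation: channel sums 1000 and 2000, mean 1500
        # -> channel a scaled by 1.5, channel b by 0.75
        a = np.array([150.0, 300.0, 1050.0])
        b = np.array([165.0, 285.0, 1050.0])
        gm = np.sqrt(a * b) / np.array([100, 200, 700])
        expected = gm / gm.max()
        score = relative_abundance(pd.DataFrame(rows), lengths)
        assert np.allclose(score.loc[["P1", "P2", "P3"]].values, expected)

    def test_length_normalization(self):
        rows = [
            {"protein_id": "P1", "bio_replicate": 1, "channel": "a", "intensity": 200.0},
            {"protein_id": "P2", "bio_replicate": 1, "channel": "a", "intensity": 200.0},
        ]
        score = relative_abundance(pd.DataFrame(rows), {"P1": 100, "P2": 200})
        assert score["P1"] / score["P2"] == pytest.approx(2.0)
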