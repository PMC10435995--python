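"""TPP pipeline: normalization, batch removal, scores, testing, melt fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from thermoshift import syndata, tpp
from thermoshift.tpp import (
    IntensityCube,
    abundance_score,
    call_hits,
    compare_profiles,
    fit_melting,
    log2fc,
    melt_shift,
    normalize,
    read_cube,
    remove_batch,
    stability_score,
)
from thermoshift.tpp import test_scores as run_test_scores

from conftest import make_cube


def random_fc(rng, n_proteins=20, temps=(37, 40.4, 44, 48, 52, 56), reps=("r1", "r2")):
    cols = pd.MultiIndex.from_product([temps, reps],
                                      names=["temperature_c", "replicate"])
    return pd.DataFrame(
        rng.normal(0, 1, (n_proteins, len(cols))),
        index=[f"P{i}" for i in range(n_proteins)],
        columns=cols,
    )


class TestCubeValidation:
    def test_incomplete_ladder_coverage_rejected(self):
        cube, _ = make_cube(n_proteins=5)
        chans = cube.channels.drop(cube.channels.index[0])
        inten = cube.intensities.drop(columns=cube.intensities.columns[0])
        with pytest.raises(ValueError, match="ladder"):
            IntensityCube(inten, chans)

    def test_duplicate_protein_ids_rejected(self):
        cube, _ = make_cube(n_proteins=5)
        inten = cube.intensities.copy()
        inten.index = ["P"] * 5
        with pytest.raises(ValueError, match="duplicate"):
            IntensityCube(inten, cube.channels)

    def test_tsv_round_trip_with_peptide_filter(self, tmp_path):
        cube, _ = make_cube(n_proteins=6)
        inten = cube.intensities.copy()
        inten.insert(0, "unique_peptides", [1, 2, 3, 1, 5, 2])
        inten.rename_axis("protein").to_csv(tmp_path / "x.tsv", sep="\t")
        cube.channels.rename_axis("channel").to_csv(tmp_path / "m.tsv", sep="\t")
        loaded = read_cube(tmp_path / "x.tsv", tmp_path / "m.tsv")
        assert len(loaded.intensities) == 4  # two rows below 2 peptides dropped


class TestNormalize:
    def test_aligned_channels_share_exact_medians(self):
        cube, _ = make_cube(noise_cv=0.0, frac_stabilized=0, frac_destabilized=0)
        norm = normalize(cube)
        for temp, grp in norm.channels.groupby("temperature_c"):
            meds = norm.intensities[list(grp.index)].median()
            assert np.ptp(meds.to_numpy()) < 1e-9

    def test_scaled_channel_recalibrated(self):
        # odd protein count: the median is a data point, so the per-channel
        # equal-median contract survives the log transform exactly
        cube, _ = make_cube(n_proteins=51, noise_cv=0.05)
        skewed = cube.intensities.copy()
        victim = skewed.columns[3]
        skewed[victim] *= 2.0
        norm = normalize(IntensityCube(skewed, cube.channels))
        for temp, grp in norm.channels.groupby("temperature_c"):
            meds = norm.intensities[list(grp.index)].median()
            assert np.ptp(meds.to_numpy()) < 1e-9

    def test_ranks_preserved_within_channels(self, rng):
        cube, _ = make_cube(noise_cv=0.1, seed=7)
        norm = normalize(cube)
        for col in cube.intensities.columns:
            before = stats.rankdata(cube.intensities[col])
            after = stats.rankdata(norm.intensities[col])
            assert np.array_equal(before, after)

    def test_single_channel_temperature_named_in_error(self):
        # a one-plex cube has exactly one channel per temperature
        rng = np.random.default_rng(0)
        temps = [37.0, 44.0, 50.0, 56.0]
        chans = pd.DataFrame(
            {
                "channel": [f"c{t}" for t in temps],
                "temperature_c": temps,
                "condition": "treatment",
                "replicate": "r1",
                "batch": "b1",
            }
        ).set_index("channel")
        inten = pd.DataFrame(
            rng.uniform(10, 100, (5, 4)), columns=chans.index,
            index=[f"P{i}" for i in range(5)],
        )
        with pytest.raises(ValueError, match="37"):
            normalize(IntensityCube(inten, chans))

    def test_glog_offset_still_monotone(self):
        cube, _ = make_cube(noise_cv=0.05, seed=3)
        norm = normalize(cube, glog_c=100.0)
        col = norm.intensities.columns[0]
        before = stats.rankdata(cube.intensities[col])
        after = stats.rankdata(norm.intensities[col])
        assert np.array_equal(before, after)


class TestRemoveBatch:
    def test_single_batch_identity(self):
        cube, _ = make_cube()
        chans = cube.channels.copy()
        chans["batch"] = "b1"
        norm = normalize(IntensityCube(cube.intensities, chans))
        out = remove_batch(norm)
        pd.testing.assert_frame_equal(out.intensities, norm.intensities)

    def test_injected_offset_removed(self):
        cube, _ = make_cube(noise_cv=0.0, frac_stabilized=0, frac_destabilized=0,
                            batch_effects={"r2": 0.5})
        norm = normalize(cube)
        out = remove_batch(norm)
        ch = out.channels
        for temp in out.ladder:
            cols1 = ch[(ch["batch"] == "r1") & (ch["temperature_c"] == temp)].index
            cols2 = ch[(ch["batch"] == "r2") & (ch["temperature_c"] == temp)].index
            diff = (
                out.intensities[cols2].mean(axis=1)
                - out.intensities[cols1].mean(axis=1)
            )
            assert np.abs(diff.to_numpy()).max() < 1e-9

    def test_condition_effect_preserved_in_balanced_design(self):
        cube, _ = make_cube(noise_cv=0.05, frac_stabilized=0.2, seed=11,
                            batch_effects={"r1": -0.3, "r2": 0.3})
        norm = normalize(cube)
        out = remove_batch(norm)
        ch = norm.channels
        for temp in norm.ladder:
            t_cols = ch[(ch["condition"] == "treatment")
                        & (ch["temperature_c"] == temp)].index
            v_cols = ch[(ch["condition"] == "vehicle")
                        & (ch["temperature_c"] == temp)].index
            before = (norm.intensities[t_cols].mean(axis=1)
                      - norm.intensities[v_cols].mean(axis=1))
            after = (out.intensities[t_cols].mean(axis=1)
                     - out.intensities[v_cols].mean(axis=1))
            assert np.abs((before - after).to_numpy()).max() < 1e-9

    def test_confounded_batches_rejected(self):
        cube, _ = make_cube()
        chans = cube.channels.copy()
        chans["batch"] = chans["condition"]  # batch == condition: unidentifiable
        norm = normalize(IntensityCube(cube.intensities, chans))
        with pytest.raises(ValueError, match="confounded"):
            remove_batch(norm)


class TestLog2fc:
    def test_identical_conditions_zero_matrix(self):
        cube, _ = make_cube(noise_cv=0.0, frac_stabilized=0, frac_destabilized=0)
        fc = log2fc(normalize(cube))
        assert np.all(fc.to_numpy() == 0.0)

    def test_doubling_one_temperature_gives_unit_fc(self):
        # doubling treatment over vehicle on the normalized cube: fc exactly 1
        # (doubling the raw channel instead would be undone by calibration,
        # which treats channel-wide scale as a labelling artifact)
        cube, _ = make_cube(noise_cv=0.0, frac_stabilized=0, frac_destabilized=0)
        norm = normalize(cube)
        ch = norm.channels
        target = ch[(ch["condition"] == "treatment")
                    & (ch["temperature_c"] == 45.0)].index
        inten = norm.intensities.copy()
        inten[target] += 1.0  # log2 scale
        fc = log2fc(norm.copy_with(inten, log_scale=True))
        assert fc[45.0].to_numpy() == pytest.approx(1.0, abs=1e-9)
        assert fc[37.0].to_numpy() == pytest.approx(0.0, abs=1e-9)

    def test_matches_elementwise_log_ratio_oracle(self):
        cube, _ = make_cube(noise_cv=0.1, seed=13)
        norm = normalize(cube)
        fc = log2fc(norm)
        ch = norm.channels
        for temp in (37.0, 53.0):
            for rep in ("r1", "r2"):
                sel = ch[(ch["temperature_c"] == temp) & (ch["replicate"] == rep)]
                t_col = sel[sel["condition"] == "treatment"].index[0]
                v_col = sel[sel["condition"] == "vehicle"].index[0]
                oracle = norm.intensities[t_col] - norm.intensities[v_col]
                assert fc[(temp, rep)].to_numpy() == pytest.approx(
                    oracle.to_numpy(), abs=1e-12
                )

    def test_unpaired_replicates_listed(self):
        cube, _ = make_cube()
        chans = cube.channels.copy()
        mask = (chans["condition"] == "treatment") & (chans["replicate"] == "r2")
        chans.loc[mask, "replicate"] = "r9"
        norm = normalize(IntensityCube(cube.intensities, chans))
        with pytest.raises(ValueError, match="r9"):
            log2fc(norm)

    def test_raw_cube_rejected(self):
        cube, _ = make_cube()
        with pytest.raises(ValueError, match="normalized"):
            log2fc(cube)


class TestScores:
    def test_abundance_is_mean_of_two_lowest_temperatures(self, rng):
        fc = random_fc(rng)
        ab = abundance_score(fc)
        oracle = (fc[37].to_numpy() + fc[40.4].to_numpy()) / 2
        assert ab.to_numpy() == pytest.approx(oracle, abs=1e-12)

    def test_worked_example_two_values(self):
        fc = random_fc(np.random.default_rng(0), n_proteins=1)
        fc.loc[:, :] = 0.0
        fc.loc["P0", (37, "r1")] = 0.1
        fc.loc["P0", (40.4, "r1")] = 0.3
        assert abundance_score(fc).loc["P0", "r1"] == pytest.approx(0.2)

    def test_step_profile_stability_eight(self):
        temps = syndata.LADDER
        cols = pd.MultiIndex.from_product([temps, ["r1"]],
                                          names=["temperature_c", "replicate"])
        fc = pd.DataFrame([[0, 0, 1, 1, 1, 1, 1, 1, 1, 1]], index=["P0"],
                          columns=cols, dtype=float)
        ab = abundance_score(fc)
        st_ = stability_score(fc, ab)
        assert ab.loc["P0", "r1"] == 0.0
        assert st_.loc["P0", "r1"] == pytest.approx(8.0)

    def test_constant_profile_stability_zero(self):
        fc = random_fc(np.random.default_rng(1))
        fc.loc[:, :] = 0.37
        assert stability_score(fc).to_numpy() == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        arrays(np.float64, (7, 12), elements=st.floats(-5, 5, allow_nan=False))
    )
    def test_algebraic_identity_sum_fc(self, values):
        temps = (37, 40.4, 44, 48, 52, 56)
        cols = pd.MultiIndex.from_product([temps, ["r1", "r2"]],
                                          names=["temperature_c", "replicate"])
        fc = pd.DataFrame(values, columns=cols)
        ab = abundance_score(fc)
        st_ = stability_score(fc, ab)
        total = fc.T.groupby(level="replicate").sum().T
        assert total.to_numpy() == pytest.approx(
            (st_ + len(temps) * ab).to_numpy(), abs=1e-12
        )

    def test_condition_wide_shift_moves_abundance_not_stability(self, rng):
        fc = random_fc(rng)
        shifted = fc + 0.7  # constant added to every temperature
        assert not np.allclose(abundance_score(shifted), abundance_score(fc))
        assert stability_score(shifted).to_numpy() == pytest.approx(
            stability_score(fc).to_numpy(), abs=1e-10
        )

    def test_high_temperature_uplift_gives_positive_stability(self, rng):
        fc = random_fc(rng) * 0.01
        uplifted = fc.copy()
        high = [t for t in fc.columns.get_level_values(0).unique() if t > 41]
        for t in high:
            uplifted[t] += 0.5
        st_ = stability_score(uplifted)
        assert np.all(st_.to_numpy() > stability_score(fc).to_numpy())

    def test_mismatched_protein_sets_rejected(self, rng):
        fc = random_fc(rng)
        ab = abundance_score(fc).iloc[:-2]
        with pytest.raises(ValueError, match="proteins"):
            stability_score(fc, ab)


class TestTestScores:
    def test_zero_prior_matches_ordinary_t(self, rng):
        st_ = pd.DataFrame(rng.normal(0, 1, (50, 4)))
        table = run_test_scores(st_, prior_df=0)
        t_ref, p_ref = stats.ttest_1samp(st_.to_numpy(), 0.0, axis=1)
        assert table["stat"].to_numpy() == pytest.approx(t_ref, abs=1e-10)
        assert table["p"].to_numpy() == pytest.approx(p_ref, abs=1e-10)

    def test_all_zero_protein_gets_p_one(self, rng):
        st_ = pd.DataFrame(rng.normal(0, 1, (30, 3)))
        st_.iloc[0] = 0.0
        table = run_test_scores(st_)
        assert table["p"].iloc[0] == 1.0
        assert table["stat"].iloc[0] == 0.0

    def test_z_contract_mean_zero_sd_one(self, rng):
        st_ = pd.DataFrame(rng.normal(0.3, 1, (200, 2)))
        table = run_test_scores(st_)
        z = table["z"].to_numpy()
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=0) - 1) < 1e-9

    def test_single_replicate_advises_replication(self, rng):
        with pytest.raises(ValueError, match="replicate"):
            run_test_scores(pd.DataFrame(rng.normal(size=(10, 1))))

    def test_empirical_fdr_option_runs(self, rng):
        st_ = pd.DataFrame(rng.normal(0, 1, (100, 3)))
        table = run_test_scores(st_, fdr_method="empirical")
        assert ((table["fdr"] >= 0) & (table["fdr"] <= 1)).all()


class TestCallHits:
    def table(self, fdrs):
        return pd.DataFrame({"stability_score": 1.0, "fdr": fdrs})

    def test_equal_thresholds_mean_no_candidates(self):
        out = call_hits(self.table([0.005, 0.03, 0.5]), 0.05, 0.05)
        assert "candidate" not in set(out["class"])

    def test_intermediate_fdr_is_candidate(self):
        out = call_hits(self.table([0.03]), 0.01, 0.05)
        assert out["class"].iloc[0] == "candidate"

    def test_monotone_in_fdr(self):
        out = call_hits(self.table([0.001, 0.03, 0.2]), 0.01, 0.05)
        assert out["class"].tolist() == ["hit", "candidate", "not_significant"]

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            call_hits(self.table([0.5]), 0.05, 0.01)


class TestFitMelting:
    def test_noiseless_round_trip_recovers_tm(self):
        cube, truth = make_cube(
            n_proteins=10, ladder=syndata.LADDER, noise_cv=0.0,
            frac_stabilized=0, frac_destabilized=0, seed=21,
        )
        norm = normalize(cube)
        protein = truth.index[0]
        fit = fit_melting(norm, protein, "vehicle")
        # relative-to-37C scaling biases tm slightly; refit tolerance is loose
        assert fit.tm == pytest.approx(truth.loc[protein, "tm"], abs=0.5)
        assert fit.r2 > 0.999

    def test_flat_profile_flagged_not_raised(self):
        cube, _ = make_cube(n_proteins=5, noise_cv=0.0,
                            frac_stabilized=0, frac_destabilized=0)
        inten = cube.intensities.copy()
        inten.iloc[0] = 1000.0  # no melting at all
        norm = normalize(IntensityCube(inten, cube.channels))
        fit = fit_melting(norm, inten.index[0], "vehicle")
        assert not fit.ok
        assert "non-sigmoidal" in fit.message

    def test_noisy_tm_within_one_degree_of_grid_oracle(self):
        errs = []
        for seed in range(10):
            cube, truth = make_cube(
                n_proteins=5, ladder=syndata.LADDER, noise_cv=0.05,
                frac_stabilized=0, frac_destabilized=0, seed=seed,
            )
            norm = normalize(cube)
            protein = truth.index[0]
            fit = fit_melting(norm, protein, "vehicle")
            errs.append(abs(fit.tm - truth.loc[protein, "tm"]))
        assert np.median(errs) < 1.0

    def test_melt_shift_recovers_injected_delta(self):
        cube, truth = make_cube(
            n_proteins=50, ladder=syndata.LADDER, noise_cv=0.0,
            frac_stabilized=0.1, frac_destabilized=0, delta_tm_stabilized=4.0,
            seed=3,
        )
        norm = normalize(cube)
        protein = truth[truth["class"] == "stabilized"].index[0]
        delta, fit_t, fit_v = melt_shift(norm, protein)
        assert delta == pytest.approx(4.0, abs=0.3)

    def test_unknown_protein_rejected(self):
        cube, _ = make_cube(n_proteins=5)
        with pytest.raises(ValueError, match="protein"):
            fit_melting(normalize(cube), "NOPE", "vehicle")


class TestCompareProfiles:
    def make_table(self, rng, proteins):
        return pd.DataFrame(
            {"stability_score": rng.normal(size=len(proteins)),
             "fdr": rng.random(len(proteins))},
            index=pd.Index(proteins, name="protein"),
        )

    def test_self_join_z_identical(self, rng):
        t = self.make_table(rng, [f"P{i}" for i in range(20)])
        joined = compare_profiles(t, t)
        assert joined["z_a"].to_numpy() == pytest.approx(joined["z_b"].to_numpy())

    def test_disjoint_tables_rejected(self, rng):
        a = self.make_table(rng, ["A1", "A2"])
        b = self.make_table(rng, ["B1", "B2"])
        with pytest.raises(ValueError, match="shared"):
            compare_profiles(a, b)

    def test_shared_target_positive_in_both_experiments(self):
        tables = []
        for seed in (5, 6):
            cube, truth = make_cube(
                n_proteins=100, ladder=syndata.LADDER, seed=seed,
                frac_stabilized=0.05, frac_destabilized=0.0,
            )
            table = tpp.score_cube(cube)
            # force one common protein name to be a true target in both
            target = truth[truth["class"] == "stabilized"].index[0]
            table = table.rename(index={target: "SHARED_TARGET"})
            tables.append(table)
        joined = compare_profiles(tables[0], tables[1])
        assert joined.loc["SHARED_TARGET", "z_a"] > 0
        assert joined.loc["SHARED_TARGET", "z_b"] > 0
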