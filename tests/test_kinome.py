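import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from astrokin import synthetic
from astrokin.kinome import (confidence_tier, global_phospho_test, harmonize,
                             krsa, peptide_lfc, peptide_signal, quartile_of,
                             rank_enrichment_scorer, substrate_shift_scorer)


def _run(rows):
    return pd.DataFrame(rows, columns=["peptide", "sample", "group", "chip",
                                       "exposure_ms", "intensity"])


class TestPeptideSignal:
    def test_exact_line_value(self):
        """intensity = 2 * exposure -> slope 2 -> value log2(200)."""
        rows = [("p1", "s1", "case", "c1", t, 2.0 * t) for t in (10, 20, 50, 100, 200)]
        out = peptide_signal(_run(rows))
        assert out["value"][0] == pytest.approx(np.log2(200.0))
        assert not out["flagged"][0]

    def test_flat_intensity_floors_to_zero_with_flag(self):
        rows = [("p1", "s1", "case", "c1", t, 77.0) for t in (10, 20, 50)]
        out = peptide_signal(_run(rows))
        assert out["value"][0] == 0.0 and out["flagged"][0]

    def test_two_point_minimal_run_is_legal(self):
        rows = [("p1", "s1", "case", "c1", 10, 30.0),
                ("p1", "s1", "case", "c1", 200, 600.0)]
        assert len(peptide_signal(_run(rows))) == 1

    def test_single_exposure_rejected(self):
        rows = [("p1", "s1", "case", "c1", 10, 1.0),
                ("p1", "s1", "case", "c1", 10, 2.0)]
        with pytest.raises(ValueError, match="exposures"):
            peptide_signal(_run(rows))

    def test_planted_two_fold_slope_ratio_gives_unit_lfc(self, kinome_fixture):
        """Case slope = 2x control for active-kinase substrates -> LFC ~ 1."""
        stats = kinome_fixture["stats"].set_index("peptide")
        subs = sorted(kinome_fixture["map"]["K000"])
        assert stats.loc[subs, "lfc"].mean() == pytest.approx(1.0, abs=0.1)


class TestPeptideLfc:
    def _values(self, case, control):
        rows = []
        for i, v in enumerate(case):
            rows.append({"peptide": "p", "sample": f"case-{i}", "group": "case",
                         "chip": f"chip-{i}", "value": v, "flagged": False})
        for i, v in enumerate(control):
            rows.append({"peptide": "p", "sample": f"control-{i}",
                         "group": "control", "chip": f"chip-{i}", "value": v,
                         "flagged": False})
        return pd.DataFrame(rows)

    def test_identical_groups_zero_not_significant(self):
        out = peptide_lfc(self._values([1.0, 1.0], [1.0, 1.0]))
        assert out["lfc"][0] == 0.0 and not out["significant"][0]

    def test_boundary_exactly_point_two_not_significant(self):
        out = peptide_lfc(self._values([1.2], [1.0]))
        assert out["lfc"][0] == pytest.approx(0.2)
        assert not out["significant"][0]
        out = peptide_lfc(self._values([1.2000001], [1.0]))
        assert out["significant"][0]

    def test_max_abs_chip_identified(self):
        vals = self._values([1.0, 2.0], [0.0, 0.0])
        out = peptide_lfc(vals)
        assert out["max_lfc_chip"][0] == "chip-1"

    def test_planted_substrates_called_significant(self, kinome_fixture):
        """shift 1.0, noise 0.1: nearly all active-kinase substrates pass 0.2."""
        stats = kinome_fixture["stats"].set_index("peptide")
        subs = sorted(kinome_fixture["map"]["K000"] | kinome_fixture["map"]["K001"])
        called = stats.loc[subs, "significant"].sum()
        assert called >= len(subs) - 2


class TestGlobalPhosphoTest:
    def test_identical_samples_p_one(self):
        t, p = global_phospho_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (t, p) == (0.0, 1.0)

    def test_large_separation_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, 3)
        b = rng.normal(10, 0.1, 3)
        _, p = global_phospho_test(a, b)
        assert p < 1e-4

    def test_group_swap_antisymmetry(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 2.5, 4.0]
        t1, p1 = global_phospho_test(a, b)
        t2, p2 = global_phospho_test(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


class TestKrsa:
    def test_everything_significant_degenerate_null(self):
        chip = {f"p{i}" for i in range(10)}
        res = krsa(chip, chip, {"K": {"p0", "p1"}}, n_iter=200, seed=0)
        assert np.isnan(res["z"][0])

    def test_null_matches_hypergeometric_moments(self):
        """20-peptide chip, 5 substrates, |sig| = 4: null mean and variance
        agree with Hypergeom(20, 5, 4) within 3 Monte-Carlo SEs."""
        chip = {f"p{i:02d}" for i in range(20)}
        kmap = {"KA": {f"p{i:02d}" for i in range(5)}}
        sig = {"p00", "p03", "p07", "p11"}
        res = krsa(sig, chip, kmap, n_iter=5000, seed=3)
        m, v = sps.hypergeom.mean(20, 5, 4), sps.hypergeom.var(20, 5, 4)
        se_mean = np.sqrt(v / 5000)
        assert abs(res["null_mean"][0] - m) < 3 * se_mean
        # variance of the sample variance via normal approx: ~ v^2 * 2/(n-1)
        se_var = v * np.sqrt(2 / 4999)
        assert abs(res["null_sd"][0] ** 2 - v) < 3 * se_var

    def test_planted_kinase_in_top_quartile(self, kinome_fixture):
        stats = kinome_fixture["stats"]
        sig = set(stats.loc[stats["significant"], "peptide"])
        res = krsa(sig, set(stats["peptide"]), kinome_fixture["map"], seed=5)
        z = res.set_index("kinase")["z"]
        assert z["K000"] >= z.quantile(0.75)

    def test_kinase_off_chip_excluded(self):
        chip = {"p0", "p1", "p2"}
        with pytest.warns(UserWarning, match="KGONE"):
            res = krsa({"p0"}, chip, {"KGONE": {"q9"}, "K": {"p1"}}, n_iter=200, seed=0)
        assert list(res["kinase"]) == ["K"]


class TestScorerStandIns:
    def test_enrichment_hand_2x2(self):
        """a=3 sig substrates, 4 sig total, 5 substrates, N=20."""
        peptides = [f"p{i:02d}" for i in range(20)]
        sig = set(peptides[:4])
        stats = pd.DataFrame({"peptide": peptides,
                              "lfc": 0.0,
                              "significant": [p in sig for p in peptides]})
        kmap = {"K": set(peptides[:3]) | set(peptides[10:12])}  # overlap 3 of 5
        res = rank_enrichment_scorer(stats, kmap)
        assert res["pvalue"][0] == pytest.approx(0.03199174406604747)

    def test_enrichment_extreme_table_minimal_p(self):
        peptides = [f"p{i}" for i in range(30)]
        stats = pd.DataFrame({"peptide": peptides, "lfc": 0.0,
                              "significant": [i < 6 for i in range(30)]})
        kmap = {"Khit": set(peptides[:6]), "Knull": set(peptides[10:16])}
        res = rank_enrichment_scorer(stats, kmap).set_index("kinase")
        assert res.loc["Khit", "pvalue"] == res["pvalue"].min()

    def test_substrate_shift_degenerate_cases(self):
        stats = pd.DataFrame({"peptide": ["a", "b", "c"], "lfc": [0.0, 0.0, 0.0],
                              "significant": False})
        res = substrate_shift_scorer(stats, {"K": {"a", "b", "c"}})
        assert res["t"][0] == 0.0
        stats["lfc"] = 1.0
        res = substrate_shift_scorer(stats, {"K": {"a", "b", "c"}})
        assert res["abs_t"][0] == pytest.approx(1e6) and res["capped"][0]

    def test_substrate_shift_power(self):
        """Planted shift 0.5, sd 0.2, 10 substrates: p < 0.01 in >= 9/10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            peptides = [f"p{i}" for i in range(40)]
            lfc = rng.normal(0, 0.2, 40)
            lfc[:10] += 0.5
            stats = pd.DataFrame({"peptide": peptides, "lfc": lfc,
                                  "significant": np.abs(lfc) > 0.2})
            res = substrate_shift_scorer(stats, {"K": set(peptides[:10])})
            hits += res["pvalue"][0] < 0.01
        assert hits >= 9


class TestHarmonize:
    QUART_REP = {1: 0.2, 2: 0.4, 3: 0.6, 4: 0.9}

    def test_rule_matches_direct_transcription_on_all_64_triples(self):
        """Exhaustive oracle over every (KRSA, UKA, KEA3) quartile triple."""
        for qk, qu, qe in itertools.product((1, 2, 3, 4), repeat=3):
            if qk == qu == qe == 4:
                expected = "high"
            elif qk == 4 and qu >= 3 and qe >= 3:
                expected = "medium"
            else:
                expected = "low"
            assert confidence_tier(qk, qu, qe) == expected, (qk, qu, qe)

    def test_tiering_on_constructed_percentiles(self):
        """10 kinases ranked so the target lands at percentiles (0.9, 0.6, 0.7):
        KRSA Q4 with the others Q3 gives medium; top everywhere gives high;
        KRSA below Q4 gives low."""
        ks = [f"k{i}" for i in range(10)]
        krsa_t = pd.Series(dict(zip(ks, range(10))), dtype=float)     # k8 pct 0.9
        uka_order = ["k0", "k1", "k2", "k3", "k4", "k8", "k5", "k6", "k7", "k9"]
        kea_order = ["k0", "k1", "k2", "k3", "k4", "k5", "k8", "k6", "k7", "k9"]
        uka_t = pd.Series({k: i for i, k in enumerate(uka_order)}, dtype=float)
        kea_t = pd.Series({k: i for i, k in enumerate(kea_order)}, dtype=float)
        tables = {"krsa": krsa_t, "uka": uka_t, "kea3": kea_t}
        out = harmonize(tables, dict.fromkeys(tables, True)).set_index("kinase")
        assert out.loc["k8", ["krsa_pct", "uka_pct", "kea3_pct"]].tolist() == \
            pytest.approx([0.9, 0.6, 0.7])
        assert out.loc["k8", "confidence"] == "medium"
        assert out.loc["k9", "confidence"] == "high"     # pct 1.0 everywhere
        assert out.loc["k5", "confidence"] == "low"      # KRSA pct 0.6 -> Q3
        assert out.loc["k8", "mean_score"] == pytest.approx(np.mean([0.9, 0.6, 0.7]))

    def test_orientation_flag_leaves_percentiles_unchanged(self):
        scores = pd.Series({"a": 0.01, "b": 0.5, "c": 0.9})
        t1 = harmonize({"x": scores, "y": scores, "z": scores},
                       {"x": False, "y": False, "z": False})
        t2 = harmonize({"x": -scores, "y": -scores, "z": -scores},
                       {"x": True, "y": True, "z": True})
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_kinase_low_and_flagged(self):
        tables = {"krsa": pd.Series({"k1": 1.0, "k2": 0.5}),
                  "uka": pd.Series({"k1": 1.0}),
                  "kea3": pd.Series({"k1": 1.0, "k2": 0.5})}
        out = harmonize(tables, dict.fromkeys(tables, True)).set_index("kinase")
        assert out.loc["k2", "confidence"] == "low"
        assert bool(out.loc["k2", "flagged_missing"])
        assert out.loc["k1", "confidence"] == "high"

    def test_quartile_binning(self):
        assert list(quartile_of([0.2, 0.26, 0.5, 0.51, 0.75, 0.76, 1.0])) == \
            [1, 2, 2, 3, 3, 4, 4]
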