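import dataclasses
import math

import numpy as np
import pytest

from pulsechase import (Genotype, InsufficientDataError, TurnoverSimConfig,
                        ValidationError, common_proteins,
                        compare_mean_normalized_intensity,
                        peptide_level_comparison, persistence_calls,
                        rollup_protein_heavy, simulate_turnover,
                        split_profiles, turnover_profiles)
from pulsechase.turnover import ProteinTurnoverProfile, profiles_from_frame, profiles_to_frame

from _oracles import brute_all_times_persisters, brute_turnover
from _random_tables import random_peptide_table
from conftest import make_record


def _profile(protein, genotype, ratios, anchor=100.0):
    return ProteinTurnoverProfile(protein=protein, genotype=Genotype(genotype),
                                  anchor_heavy=anchor, ratios=dict(ratios),
                                  n_peptides={0.0: 3, **{t: 3 for t in ratios}})


class TestRollup:
    def test_arithmetic_mean_of_matching_peptides(self):
        records = [make_record(peptide=f"PEP{i}K", heavy=h)
                   for i, h in enumerate((10.0, 20.0, 30.0))]
        assert rollup_protein_heavy(records, "P1", 0.0, "MUT") == pytest.approx(20.0)

    def test_singleton_peptide_is_included(self):
        records = [make_record(heavy=7.0)]
        assert rollup_protein_heavy(records, "P1", 0.0, "MUT") == pytest.approx(7.0)

    def test_absent_is_none_not_zero(self):
        records = [make_record(heavy=7.0, t=0.0)]
        assert rollup_protein_heavy(records, "P1", 5.0, "MUT") is None
        assert rollup_protein_heavy(records, "P9", 0.0, "MUT") is None

    def test_zero_heavy_records_do_not_contribute(self):
        records = [make_record(peptide="AK", heavy=10.0),
                   make_record(peptide="CK", heavy=0.0, light=5.0)]
        assert rollup_protein_heavy(records, "P1", 0.0, "MUT") == pytest.approx(10.0)

    def test_noiseless_rollup_matches_truth_closed_form(self, noiseless_config):
        records, truth = simulate_turnover(noiseless_config)
        prot = truth.proteins.iloc[0]
        ions = truth.peptides.loc[truth.peptides.protein == prot.protein, "ion_factor"]
        E = noiseless_config.label_efficiency
        for t in (0.0, 5.0):
            expected = prot.abundance * ions.mean() * E * np.exp(-prot.k_ctrl * t)
            got = rollup_protein_heavy(records, prot.protein, t, "CTRL")
            assert got == pytest.approx(expected, rel=1e-9)


class TestProfiles:
    def test_simple_ratio(self):
        records = ([make_record(peptide="AK", heavy=100.0, t=0.0)]
                   + [make_record(peptide="AK", heavy=44.0, t=5.0)])
        prof = turnover_profiles(records)
        assert len(prof) == 1
        assert prof[0].ratios == {5.0: pytest.approx(0.44)}

    def test_ratio_at_or_above_one_dropped_and_protein_excluded(self):
        records = [make_record(peptide="AK", heavy=100.0, t=0.0),
                   make_record(peptide="AK", heavy=130.0, t=1.0)]
        assert turnover_profiles(records + [make_record(peptide="ZK", protein="PX",
                                                        heavy=10.0, t=0.0),
                                            make_record(peptide="ZK", protein="PX",
                                                        heavy=5.0, t=1.0)]) \
            [0].protein == "PX"  # P1's only ratio is 1.3 -> P1 excluded entirely

    def test_protein_without_anchor_dropped(self):
        records = [make_record(heavy=50.0, t=5.0),
                   make_record(peptide="ZK", protein="PX", heavy=10.0, t=0.0),
                   make_record(peptide="ZK", protein="PX", heavy=5.0, t=5.0)]
        profs = turnover_profiles(records)
        assert [p.protein for p in profs] == ["PX"]

    def test_no_anchor_records_at_all_is_an_error(self):
        with pytest.raises(ValidationError):
            turnover_profiles([make_record(t=5.0)])

    def test_noiseless_ratios_equal_exp_minus_kt(self, noiseless_config):
        records, truth = simulate_turnover(noiseless_config)
        rates = truth.proteins.set_index("protein")
        for prof in turnover_profiles(records):
            k = rates.loc[prof.protein,
                          "k_mut" if prof.genotype is Genotype.MUT else "k_ctrl"]
            for t, r in prof.ratios.items():
                assert r == pytest.approx(math.exp(-k * t), rel=1e-9)

    def test_scaling_one_run_changes_ratios_scaling_all_runs_does_not(self):
        base = [make_record(peptide="AK", heavy=100.0, t=0.0),
                make_record(peptide="AK", heavy=40.0, t=5.0)]
        ratio = turnover_profiles(base)[0].ratios[5.0]
        all_scaled = [dataclasses.replace(r, heavy_area=r.heavy_area * 3) for r in base]
        assert turnover_profiles(all_scaled)[0].ratios[5.0] == pytest.approx(ratio)
        one_scaled = [dataclasses.replace(r, heavy_area=r.heavy_area * (0.5 if r.chase_time else 1))
                      for r in base]
        assert turnover_profiles(one_scaled)[0].ratios[5.0] != pytest.approx(ratio)

    def test_frame_round_trip(self, small_peptide_records):
        profiles = turnover_profiles(small_peptide_records)
        again = profiles_from_frame(profiles_to_frame(profiles))
        assert {(p.protein, p.genotype): p.ratios for p in profiles} == \
            {(p.protein, p.genotype): p.ratios for p in again}


class TestPersistence:
    def test_common_proteins_set_algebra(self):
        mut = {"A": _profile("A", "MUT", {5.0: 0.5}),
               "B": _profile("B", "MUT", {1.0: 0.9})}
        ctrl = {"A": _profile("A", "CTRL", {5.0: 0.4}),
                "C": _profile("C", "CTRL", {5.0: 0.4})}
        assert common_proteins(mut, ctrl, 5.0) == {"A"}
        assert common_proteins(mut, ctrl, 1.0) == set()
        assert common_proteins(mut, mut, 5.0) == {"A"}

    def test_exact_ties_do_not_persist(self):
        mut = {p: _profile(p, "MUT", {5.0: 0.5}) for p in "ABC"}
        ctrl = {p: _profile(p, "CTRL", {5.0: 0.5}) for p in "ABC"}
        res = persistence_calls(mut, ctrl, [5.0])
        assert res.fractions[5.0] == 0.0
        assert res.all_times_set == []

    def test_persists_all_requires_every_time_point(self):
        mut = {"A": _profile("A", "MUT", {1.0: 0.9, 5.0: 0.6}),
               "B": _profile("B", "MUT", {1.0: 0.9, 5.0: 0.3})}
        ctrl = {"A": _profile("A", "CTRL", {1.0: 0.8, 5.0: 0.5}),
                "B": _profile("B", "CTRL", {1.0: 0.8, 5.0: 0.5})}
        res = persistence_calls(mut, ctrl, [1.0, 5.0])
        by_prot = {c.protein: c for c in res.calls}
        assert by_prot["A"].persists_all
        assert not by_prot["B"].persists_all          # loses at t=5
        assert res.venn[(1.0, 5.0)] == ["A"]
        assert res.venn[(1.0,)] == ["B"]

    def test_slowed_proteins_persist_at_low_noise(self):
        cfg = TurnoverSimConfig(n_proteins=60, peptides_per_protein=(6, 10),
                                noise_cv=0.01, dropout_midpoint=0.0,
                                frac_slowed=0.25, rate_factor=0.5, seed=21)
        records, truth = simulate_turnover(cfg)
        mut, ctrl = split_profiles(turnover_profiles(records))
        res = persistence_calls(mut, ctrl, [1.0, 5.0, 21.0])
        slowed = set(truth.proteins.loc[truth.proteins.slowed, "protein"])
        assert slowed, "fixture must contain slowed proteins"
        # every slowed protein that is comparable at all times must be called
        callable_ = slowed & set.intersection(
            *[common_proteins(mut, ctrl, t) for t in (1.0, 5.0, 21.0)])
        assert callable_ <= set(res.all_times_set)

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(2024)
        times = (1.0, 5.0, 21.0)
        for _ in range(10):
            records = random_peptide_table(rng, max_proteins=8)
            try:
                mut, ctrl = split_profiles(turnover_profiles(records))
            except ValidationError:
                continue
            res = persistence_calls(mut, ctrl, times)
            _, brute = brute_turnover(records, times)
            for t in times:
                assert {c.protein for c in res.calls if c.by_time[t].persists} == \
                    brute[t]["persist"]
                assert res.common_counts[t] == len(brute[t]["common"])


class TestStatisticalComparisons:
    def test_identical_profiles_give_p_one_and_zero_difference(self):
        mut = {p: _profile(p, "MUT", {5.0: 0.4 + i / 10}) for i, p in enumerate("ABC")}
        ctrl = {p: _profile(p, "CTRL", dict(mut[p].ratios)) for p in mut}
        out = compare_mean_normalized_intensity(mut, ctrl, 5.0)
        assert out["p_paired"] == pytest.approx(1.0)
        assert out["mean_mut"] == pytest.approx(out["mean_ctrl"])

    def test_paired_t_matches_textbook_formula(self):
        pairs = [(0.6, 0.4), (0.7, 0.45), (0.8, 0.62)]
        mut = {f"P{i}": _profile(f"P{i}", "MUT", {5.0: m}) for i, (m, _) in enumerate(pairs)}
        ctrl = {f"P{i}": _profile(f"P{i}", "CTRL", {5.0: c}) for i, (_, c) in enumerate(pairs)}
        out = compare_mean_normalized_intensity(mut, ctrl, 5.0)
        diffs = np.array([m - c for m, c in pairs])
        t_expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
        assert out["t_stat"] == pytest.approx(t_expected, rel=1e-12)
        assert out["mean_mut"] - out["mean_ctrl"] == pytest.approx(diffs.mean())

    def test_paired_t_requires_two_common_proteins(self):
        mut = {"A": _profile("A", "MUT", {5.0: 0.5})}
        ctrl = {"A": _profile("A", "CTRL", {5.0: 0.4})}
        with pytest.raises(InsufficientDataError):
            compare_mean_normalized_intensity(mut, ctrl, 5.0)

    def test_peptide_level_identical_genotypes_p_one(self):
        records = []
        for genotype in ("MUT", "CTRL"):
            for i in range(3):
                records.append(make_record(peptide=f"PEP{i}K", heavy=100.0,
                                           t=0.0, genotype=genotype))
                records.append(make_record(peptide=f"PEP{i}K", heavy=40.0,
                                           t=5.0, genotype=genotype))
        out = peptide_level_comparison(records, "P1", 5.0)
        assert out["p_unpaired"] == pytest.approx(1.0)

    def test_peptide_level_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        records = []
        for genotype, level in (("MUT", 0.8), ("CTRL", 0.4)):
            for i in range(3):
                records.append(make_record(peptide=f"PEP{i}K", heavy=100.0,
                                           t=0.0, genotype=genotype))
                records.append(make_record(
                    peptide=f"PEP{i}K", heavy=100.0 * (level + rng.normal(0, 0.005)),
                    t=5.0, genotype=genotype))
        out = peptide_level_comparison(records, "P1", 5.0)
        assert out["p_unpaired"] < 0.01
        assert out["mut_values"].mean() > out["ctrl_values"].mean()

    def test_peptide_level_values_are_self_normalized(self, noiseless_config):
        """Noiseless: each peptide value is exp(-k t); ionization cancels."""
        records, truth = simulate_turnover(noiseless_config)
        prot = truth.proteins.iloc[3]
        out = peptide_level_comparison(records, prot.protein, 5.0)
        assert np.allclose(out["mut_values"], np.exp(-prot.k_mut * 5.0), rtol=1e-9)
        assert np.allclose(out["ctrl_values"], np.exp(-prot.k_ctrl * 5.0), rtol=1e-9)

    def test_peptide_level_requires_matched_peptides(self):
        records = [make_record(peptide="AK", heavy=10.0, t=0.0),
                   make_record(peptide="AK", heavy=5.0, t=5.0)]
        with pytest.raises(InsufficientDataError):
            peptide_level_comparison(records, "P1", 5.0)
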