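import math
import statistics
import warnings

import numpy as np
import pytest

from gmhi import (
    GmhiSignature,
    collective_abundance,
    estimate_effective_set_sizes,
    gmhi_score,
    k_extreme,
    load_packaged_signature,
    score_table,
)
from gmhi.profiles import HEALTHY, NONHEALTHY
from gmhi.scoring import normalize_species_name

from conftest import make_table, random_group_table


def make_signature(m_h, m_n, size_h=None, size_n=None, eps=1e-5):
    return GmhiSignature(
        list(m_h), list(m_n), 1.4, 0.10,
        size_h if size_h is not None else float(len(m_h)),
        size_n if size_n is not None else float(len(m_n)),
        pseudo_count=eps)


class TestCollectiveAbundance:
    def test_no_species_present(self):
        psi, r = collective_abundance({"Q": 0.5}, ["A", "B"], 2.0)
        assert (psi, r) == (0.0, 0)

    def test_hand_evaluated_two_of_three(self):
        # (2/3) * (|0.1 ln 0.1| + |0.2 ln 0.2|)
        psi, r = collective_abundance(
            {"A": 0.1, "B": 0.2}, ["A", "B", "C"], 3.0)
        expected = (2 / 3) * (abs(0.1 * math.log(0.1))
                              + abs(0.2 * math.log(0.2)))
        assert r == 2
        assert psi == pytest.approx(expected, abs=1e-12)
        assert psi == pytest.approx(0.368097, abs=1e-6)

    def test_single_species_at_one_gives_zero_psi(self):
        psi, r = collective_abundance({"A": 1.0}, ["A"], 1.0)
        assert r == 1
        assert psi == 0.0

    def test_below_presence_threshold_excluded(self):
        psi, r = collective_abundance({"A": 5e-6}, ["A"], 1.0)
        assert (psi, r) == (0.0, 0)

    def test_nonpositive_effective_size_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            collective_abundance({"A": 0.5}, ["A"], 0.0)

    def test_adding_present_species_never_decreases_psi(self, rng):
        """Monotonicity: a new present member adds a nonnegative term."""
        for _ in range(50):
            abunds = rng.uniform(1e-4, 0.2, size=6)
            sample = {f"s{i}": a for i, a in enumerate(abunds)}
            base_set = [f"s{i}" for i in range(5)]
            psi0, _ = collective_abundance(sample, base_set, 6.0)
            psi1, _ = collective_abundance(sample, base_set + ["s5"], 6.0)
            assert psi1 >= psi0


class TestKExtreme:
    @pytest.mark.parametrize("n,k", [
        (2636, 26), (1711, 17),   # the published group sizes
        (10, 1), (50, 1), (150, 2), (249, 2), (250, 3), (100, 1),
    ])
    def test_closest_integer_with_floor_one(self, n, k):
        assert k_extreme(n) == k

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            k_extreme(0)


class TestEffectiveSetSizes:
    def test_identical_samples(self):
        rows = {f"s{i}": {"A": 0.2, "B": 0.2, "C": 0.2, "D": 0.2, "E": 0.2}
                for i in range(20)}
        groups = {f"s{i}": HEALTHY if i < 10 else NONHEALTHY
                  for i in range(20)}
        table = make_table(rows, groups=groups)
        eff = estimate_effective_set_sizes(
            table, ["A", "B", "C", "D", "E"], ["Z1", "Z2"],
            fallback_to_cardinality=True)
        assert eff.size_h_eff == 5.0
        assert eff.size_n_eff == 2.0  # degenerate R_N=0 falls back to |M_N|

    def test_degenerate_median_errors_without_fallback(self):
        rows = {f"s{i}": {"A": 1.0} for i in range(8)}
        groups = {f"s{i}": HEALTHY if i < 4 else NONHEALTHY for i in range(8)}
        table = make_table(rows, groups=groups)
        with pytest.raises(ValueError, match="fallback"):
            estimate_effective_set_sizes(table, ["A"], ["B"])

    def test_matches_bruteforce_sort_oracle(self, rng):
        table = random_group_table(rng, n_h=25, n_n=15, n_species=20)
        m_h = [f"sp{j}" for j in range(8)]
        m_n = [f"sp{j}" for j in range(8, 16)]
        eff = estimate_effective_set_sizes(
            table, m_h, m_n, fallback_to_cardinality=True)
        # independent oracle: stable python sort on (R_N, -R_H)
        pairs = []
        for sid in table.sample_ids:
            row = table.data.loc[sid]
            r_h = sum(row[s] >= 1e-5 for s in m_h)
            r_n = sum(row[s] >= 1e-5 for s in m_n)
            pairs.append((r_n, -r_h, r_h))
        order = sorted(range(len(pairs)), key=lambda i: pairs[i][:2])
        k_h, k_n = k_extreme(25), k_extreme(15)
        top_rh = [pairs[i][2] for i in order[:k_h]]
        bot_rn = [pairs[i][0] for i in order[-k_n:]]
        expected_h = statistics.median(top_rh) or float(len(m_h))
        expected_n = statistics.median(bot_rn) or float(len(m_n))
        assert eff.size_h_eff == expected_h
        assert eff.size_n_eff == expected_n
        assert (eff.k_h, eff.k_n) == (k_h, k_n)

    def test_empty_group_or_set_rejected(self):
        table = make_table({"a": {"A": 1.0}}, groups={"a": HEALTHY})
        with pytest.raises(ValueError, match="nonempty"):
            estimate_effective_set_sizes(table, ["A"], ["B"])


class TestGmhiScore:
    def test_equal_collective_abundances_give_exact_zero(self):
        sig = make_signature(["A", "B"], ["C", "D"], 2.0, 2.0)
        sample = {"A": 0.1, "B": 0.2, "C": 0.1, "D": 0.2}
        score = gmhi_score(sample, sig)
        assert score.psi_h == score.psi_n > 0
        assert score.h == 0.0
        assert score.label == "neither"

    def test_only_health_prevalent_species_classified_healthy(self):
        sig = make_signature(["A", "B"], ["C"])
        score = gmhi_score({"A": 0.5, "B": 0.5}, sig)
        assert score.h > 0
        assert score.label == "healthy"
        assert (score.r_h, score.r_n) == (2, 0)

    def test_swap_antisymmetry(self, rng):
        sig = make_signature(["A", "B"], ["C", "D", "E"], 1.5, 2.5)
        for _ in range(25):
            vals = rng.uniform(1e-4, 0.3, size=5)
            sample = dict(zip(["A", "B", "C", "D", "E"], vals))
            h = gmhi_score(sample, sig).h
            h_swapped = gmhi_score(sample, sig.swapped()).h
            assert h_swapped == pytest.approx(-h, abs=1e-12)

    def test_zero_pseudocount_infinite_score_with_warning(self):
        sig = make_signature(["A"], ["B"], eps=0.0)
        with pytest.warns(UserWarning, match="inf"):
            score = gmhi_score({"A": 0.5, "X": 0.5}, sig)
        assert score.h == math.inf

    def test_effective_size_rescaling_leaves_h_unchanged(self, rng):
        """h depends only on the psi ratio, so joint scaling cancels."""
        # joint scaling must keep the sizes within their (0, |M|] bounds
        for c in (0.5, 0.75, 0.9):
            sig1 = make_signature(["A", "B"], ["C", "D"], 2.0, 2.0, eps=0.0)
            sig2 = make_signature(["A", "B"], ["C", "D"], 2.0 * c, 2.0 * c,
                                  eps=0.0)
            sample = {"A": 0.15, "B": 0.05, "C": 0.3, "D": 0.1}
            assert gmhi_score(sample, sig2).h == pytest.approx(
                gmhi_score(sample, sig1).h, abs=1e-12)


class TestScoreTable:
    def test_matches_looped_scores(self, rng):
        table = random_group_table(rng, n_h=50, n_n=50, n_species=12)
        sig = make_signature([f"sp{j}" for j in range(4)],
                             [f"sp{j}" for j in range(4, 10)], 3.0, 5.0)
        frame = score_table(table, sig)
        assert list(frame.index) == table.sample_ids
        for sid in table.sample_ids:
            ref = gmhi_score(table.data.loc[sid].to_dict(), sig, sid)
            row = frame.loc[sid]
            assert row["gmhi"] == pytest.approx(ref.h, abs=1e-12)
            assert row["R_H"] == ref.r_h and row["R_N"] == ref.r_n
            assert row["psi_H"] == pytest.approx(ref.psi_h, abs=1e-14)

    def test_all_signature_species_missing_warns_and_zeroes(self):
        table = make_table({"a": {"Q": 1.0}})
        sig = make_signature(["A"], ["B"])
        with pytest.warns(UserWarning, match="none of the signature"):
            frame = score_table(table, sig)
        assert frame.loc["a", "gmhi"] == 0.0
        assert frame.loc["a", "label"] == "neither"

    def test_metaphlan_name_matching(self):
        table = make_table(
            {"a": {"Streptococcus_mitis_oralis_pneumoniae": 0.4, "Q": 0.6}})
        sig = make_signature(["Streptococcus mitis/oralis/pneumoniae"], ["B"])
        frame = score_table(table, sig)
        assert frame.loc["a", "R_H"] == 1


class TestSignatureObject:
    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="both sets"):
            make_signature(["A", "B"], ["B", "C"])

    def test_effective_size_bounds_enforced(self):
        with pytest.raises(ValueError, match="size_h_eff"):
            make_signature(["A"], ["B"], size_h=2.0)

    def test_tsv_round_trip(self, tmp_path):
        sig = make_signature(["A", "B"], ["C"], 1.5, 1.0)
        path = tmp_path / "sig.tsv"
        sig.to_tsv(path)
        back = GmhiSignature.from_tsv(path)
        assert back.m_h == sig.m_h and back.m_n == sig.m_n
        assert back.size_h_eff == sig.size_h_eff
        assert back.theta_f == sig.theta_f


@pytest.fixture(scope="module")
def signature():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return load_packaged_signature()


class TestPackagedSignature:

    def test_species_counts(self, signature):
        assert len(signature.m_h) == 7
        assert len(signature.m_n) == 43
        assert len(signature.m_h) + len(signature.m_n) == 50

    def test_angulatum_prevalences(self, signature):
        assert "Bifidobacterium angulatum" in signature.m_h
        row = signature.prevalence.loc["Bifidobacterium angulatum"]
        assert (row["p_H"], row["p_N"]) == (11.9, 1.5)

    def test_every_species_passes_its_own_thresholds(self, signature):
        """Printed prevalences re-satisfy f>=1.4, d>=0.10 within rounding."""
        prev = signature.prevalence
        for sp in signature.m_h:
            p_h, p_n = prev.loc[sp, "p_H"] / 100, prev.loc[sp, "p_N"] / 100
            # printed percents are rounded to 1 decimal: allow half-ULP slack
            fold_hi = (p_h + 0.0005) / max(p_n - 0.0005, 1e-9)
            assert fold_hi >= 1.4
            assert (p_h - p_n) + 0.001 >= 0.10
        for sp in signature.m_n:
            p_h, p_n = prev.loc[sp, "p_H"] / 100, prev.loc[sp, "p_N"] / 100
            fold_hi = (p_n + 0.0005) / max(p_h - 0.0005, 1e-9)
            assert fold_hi >= 1.4
            assert (p_n - p_h) + 0.001 >= 0.10

    def test_default_effective_sizes_warn(self):
        with pytest.warns(UserWarning, match="effective set sizes"):
            sig = load_packaged_signature()
        assert sig.size_h_eff == 7.0
        assert sig.size_n_eff == 43.0

    def test_user_supplied_effective_sizes(self):
        sig = load_packaged_signature(size_h_eff=5.0, size_n_eff=30.0)
        assert sig.size_h_eff == 5.0

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown packaged"):
            load_packaged_signature("other")


def test_normalize_species_name():
    assert (normalize_species_name("Streptococcus mitis/oralis/pneumoniae")
            == "Streptococcus_mitis_oralis_pneumoniae")
    assert (normalize_species_name("Subdoligranulum sp. 4_3_54A2FAA")
            == "Subdoligranulum_sp_4_3_54A2FAA")
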