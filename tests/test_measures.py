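"""Four-measure scoring: worked examples, properties, independent oracles."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import braycurtis

import mockbench as mb
from mockbench.errors import ParameterError

from conftest import random_profile

POOL = [f"taxon {chr(ord('a') + i)}" for i in range(12)]


# --- straight-from-the-equations oracle (kept independent of the package) ---

def oracle_scores(pred: dict, truth_taxa: set, actual: dict) -> dict:
    tp = {t for t, v in pred.items() if t in truth_taxa and v > 0}
    fp_mass = sum(v for t, v in pred.items() if t not in truth_taxa)
    total = sum(pred.values())
    union = set(pred) | set(actual)
    c = sum(min(pred.get(t, 0.0), actual.get(t, 0.0)) for t in union)
    return {
        "sensitivity": 100 * len(tp) / len(truth_taxa),
        "fpra": 100 * fp_mass / total if total else 0.0,
        "diversity": sum(1 for v in pred.values() if v > 0),
        "similarity": 100 * 2 * c / (total + sum(actual.values())),
    }


def _profile(entries, sample="p", normalize=False):
    return mb.TaxonProfile.from_entries(
        sample, "species", entries, normalize=normalize
    )


class TestSensitivityFpraDiversity:
    def test_sixteen_of_nineteen_rounds_to_84(self, gut20, fixture_16tp_2fp):
        match = mb.match_taxa(fixture_16tp_2fp, gut20)
        value = mb.sensitivity(match, mb.count_taxa(gut20, "species"))
        assert value == pytest.approx(100 * 16 / 19)
        assert round(value) == 84

    def test_identity_and_empty_extremes(self, gut20, species_truth_profile):
        match = mb.match_taxa(species_truth_profile, gut20)
        assert mb.sensitivity(match, 19) == 100
        empty = _profile({})
        with pytest.warns(UserWarning):
            assert mb.fpra(mb.match_taxa(empty, gut20)) == 0
        assert mb.diversity(empty) == 0

    def test_truth_size_zero_rejected(self, gut20, species_truth_profile):
        match = mb.match_taxa(species_truth_profile, gut20)
        with pytest.raises(ParameterError):
            mb.sensitivity(match, 0)

    @pytest.mark.parametrize(
        "pred, truth_taxa, expected",
        [
            ({"a": 0.9, "b": 0.1}, {"a"}, 10.0),
            ({"a": 0.5, "b": 0.3, "c": 0.2}, {"a", "b"}, 20.0),
            ({"a": 1.0}, {"a"}, 0.0),
            ({"b": 1.0}, {"a"}, 100.0),
        ],
    )
    def test_fpra_hand_examples(self, pred, truth_taxa, expected):
        strains = [
            mb.StrainRecord(
                strain_label=t, species_name=t,
                lineage={"phylum": "p", "family": "f", "genus": t, "species": t},
                culture_collection_id="", gram="positive",
                genome_size=1_000_000, copies_16s=1, cell_weight=1.0,
            )
            for t in sorted(truth_taxa)
        ]
        community = mb.CommunityTruth(name="mini", strains=strains)
        match = mb.match_taxa(_profile(pred), community)
        assert mb.fpra(match) == pytest.approx(expected)

    def test_diversity_counts_above_threshold(self):
        profile = _profile({"a": 0.9, "b": 0.0999, "c": 0.001})
        assert mb.diversity(profile) == 3
        assert mb.diversity(profile, detection_threshold=0.01) == 2

    def test_sensitivity_complements_false_negatives(self, gut20, fixture_16tp_2fp):
        match = mb.match_taxa(fixture_16tp_2fp, gut20)
        n = mb.count_taxa(gut20, "species")
        assert mb.sensitivity(match, n) + 100 * len(match.false_negatives) / n \
            == pytest.approx(100)


class TestSimilarity:
    def test_identical_profiles_score_100(self, species_truth_profile):
        assert mb.similarity(species_truth_profile, species_truth_profile) \
            == pytest.approx(100)

    def test_disjoint_profiles_score_0(self):
        assert mb.similarity(_profile({"a": 1.0}), _profile({"b": 1.0})) == 0

    def test_min_sum_hand_example(self):
        left = _profile({"a": 0.6, "b": 0.4})
        right = _profile({"a": 0.4, "b": 0.4, "c": 0.2})
        assert mb.similarity(left, right) == pytest.approx(80.0)

    def test_both_empty_warns_zero(self):
        with pytest.warns(UserWarning):
            assert mb.similarity(_profile({}), _profile({})) == 0

    def test_matches_bray_curtis_complement(self):
        """100·(1−BC) from an independent distance routine, 100 pairs."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = random_profile(rng, POOL)
            q = random_profile(rng, POOL)
            union = sorted(set(p.entries) | set(q.entries))
            u = np.array([p.entries.get(t, 0.0) for t in union])
            v = np.array([q.entries.get(t, 0.0) for t in union])
            expected = 100 * (1 - braycurtis(u, v))
            assert mb.similarity(p, q) == pytest.approx(expected, abs=1e-9)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = random_profile(rng, POOL)
            q = random_profile(rng, POOL)
            s = mb.similarity(p, q)
            assert s == pytest.approx(mb.similarity(q, p))
            assert 0 <= s <= 100 + 1e-9

    def test_moving_mass_to_false_positive_never_helps(self, species_truth_profile):
        """Shifting abundance from a truth taxon to a new taxon cannot
        increase similarity to the truth."""
        base = species_truth_profile
        for donor in list(base.entries)[:5]:
            for shift in (0.01, 0.03, base.entries[donor]):
                entries = dict(base.entries)
                entries[donor] -= shift
                entries["novel contaminant"] = shift
                moved = _profile(entries)
                assert mb.similarity(moved, base) <= \
                    mb.similarity(base, base) + 1e-9


class TestDissimilarityMatrix:
    def test_identical_profiles_zero_matrix(self, species_truth_profile):
        other = _profile(dict(species_truth_profile.entries), sample="copy")
        matrix = mb.dissimilarity_matrix([species_truth_profile, other])
        assert matrix.values == pytest.approx(np.zeros((2, 2)), abs=1e-12)

    def test_symmetric_zero_diagonal_matches_skbio(self):
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(11)
        profiles = [random_profile(rng, POOL) for _ in range(6)]
        for i, p in enumerate(profiles):
            p.sample_id = f"s{i}"
        matrix = mb.dissimilarity_matrix(profiles)
        assert np.allclose(matrix.values, matrix.values.T)
        assert np.allclose(np.diag(matrix.values), 0)
        union = sorted({t for p in profiles for t in p.entries})
        counts = np.array(
            [[p.entries.get(t, 0.0) for t in union] for p in profiles]
        )
        reference = beta_diversity(
            "braycurtis", counts, ids=[p.sample_id for p in profiles]
        )
        assert np.allclose(matrix.values, reference.data, atol=1e-9)

    def test_mixed_ranks_rejected(self, species_truth_profile):
        genus = mb.TaxonProfile.from_entries("g", "genus", {"escherichia": 1.0})
        with pytest.raises(ParameterError):
            mb.dissimilarity_matrix([species_truth_profile, genus])


class TestGramRecovery:
    def test_truth_profile_recovers_strain_split(self, gut20, species_truth_profile):
        pos, neg = mb.gram_recovery(species_truth_profile, gut20)
        assert (pos, neg) == pytest.approx((60.0, 40.0))

    def test_only_negative_taxa(self, gut20):
        profile = _profile({"escherichia coli": 0.5, "bacteroides fragilis": 0.5})
        assert mb.gram_recovery(profile, gut20) == pytest.approx((0.0, 100.0))

    def test_halving_positives_shifts_toward_negative(self, gut20, species_truth_profile):
        gram = gut20.gram_of("species")
        entries = {
            t: (v / 2 if gram[t] == "positive" else v)
            for t, v in species_truth_profile.entries.items()
        }
        pos_before, _ = mb.gram_recovery(species_truth_profile, gut20)
        pos_after, neg_after = mb.gram_recovery(_profile(entries), gut20)
        assert pos_after < pos_before
        assert pos_after + neg_after == pytest.approx(100)

    def test_no_matched_abundance_warns_nan(self, gut20):
        profile = _profile({"unknown bug": 1.0})
        with pytest.warns(UserWarning):
            pos, neg = mb.gram_recovery(profile, gut20)
        assert math.isnan(pos) and math.isnan(neg)


class TestReplicateCv:
    def test_constant_replicates(self):
        assert mb.replicate_cv([3.3, 3.3, 3.3]) == 0

    def test_hand_arithmetic(self):
        # sd(2,4) = sqrt(2), mean 3 -> 47.14%
        assert mb.replicate_cv([2, 4]) == pytest.approx(100 * math.sqrt(2) / 3)
        assert mb.replicate_cv([2, 4]) == pytest.approx(47.14, abs=0.01)

    def test_scale_invariance(self):
        values = [1.2, 3.4, 2.2, 5.0]
        assert mb.replicate_cv([10 * v for v in values]) == \
            pytest.approx(mb.replicate_cv(values))

    def test_degenerate_inputs(self):
        with pytest.raises(ParameterError):
            mb.replicate_cv([1.0])
        with pytest.warns(UserWarning):
            assert math.isnan(mb.replicate_cv([-1.0, 1.0]))


class TestBiasPartition:
    def test_identical_profiles_no_loss(self, species_truth_profile):
        part = mb.bias_partition(
            species_truth_profile, species_truth_profile, species_truth_profile
        )
        assert part.total_loss == pytest.approx(0, abs=1e-9)
        assert part.bioinformatic_loss == pytest.approx(0, abs=1e-9)
        assert part.extraction_loss == pytest.approx(0, abs=1e-9)
        assert part.achievable_ceiling == pytest.approx(100)

    def test_dna_similarity_78_gives_22_loss(self, species_truth_profile):
        """A DNA-reagent profile at 78% similarity to the actual composition
        implies a 22% bioinformatic loss."""
        actual = species_truth_profile
        entries = {t: v * 0.78 for t, v in actual.entries.items()}
        entries["spurious call"] = 0.22
        dna = _profile(entries)
        assert mb.similarity(dna, actual) == pytest.approx(78.0)
        part = mb.bias_partition(dna, dna, actual)
        assert part.bioinformatic_loss == pytest.approx(22.0)

    def test_random_triples_match_pairwise_similarities(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            wc, dna, actual = (random_profile(rng, POOL) for _ in range(3))
            part = mb.bias_partition(wc, dna, actual)
            assert part.total_loss == pytest.approx(
                100 - mb.similarity(wc, actual))
            assert part.bioinformatic_loss == pytest.approx(
                100 - mb.similarity(dna, actual))
            assert part.extraction_loss == pytest.approx(
                100 - mb.similarity(wc, dna))
            assert part.achievable_ceiling == pytest.approx(
                100 - part.extraction_loss)


class TestScoreProfile:
    def test_truth_scored_against_itself(self, gut20, species_truth_profile):
        report = mb.score_profile(species_truth_profile, gut20, basis="cells")
        assert report.sensitivity == 100
        assert report.fpra == 0
        assert report.diversity == 19
        assert report.similarity_to_actual == pytest.approx(100)
        assert report.similarity_to_dna_reference is None
        assert report.gram_positive_fraction + report.gram_negative_fraction \
            == pytest.approx(100)

    def test_fixture_reproduces_printed_panel(self, gut20, fixture_16tp_2fp):
        report = mb.score_profile(fixture_16tp_2fp, gut20, basis="cells")
        assert report.sensitivity_rounded == 84
        assert report.diversity == 18
        assert report.fpra == pytest.approx(5.0)

    def test_replicate_summary_means(self, gut20):
        replicates = mb.simulate_experiment(gut20, mb.study_config(seed=9))
        reports = [
            mb.score_profile(p, gut20, basis="dna_mass") for p in replicates
        ]
        summary = mb.replicate_summary(reports)
        values = [r.fpra for r in reports]
        assert summary.loc["fpra", "mean"] == pytest.approx(np.mean(values))
        assert summary.loc["fpra", "sd"] == pytest.approx(np.std(values, ddof=1))


class TestOracleEquivalence:
    def test_all_measures_match_equation_oracle(self, gut20):
        """1,000 random profiles agree with the straight-from-the-equations
        oracle to 1e-9 on all four measures."""
        truth_taxa = gut20.taxa_at("species")
        actual = mb.expected_profile(gut20, "cells", "species")
        pool = sorted(truth_taxa) + ["zeta exotica", "eta nova", "theta rara"]
        rng = np.random.default_rng(123)
        for _ in range(1000):
            profile = random_profile(rng, pool)
            expected = oracle_scores(profile.entries, truth_taxa, actual.entries)
            match = mb.match_taxa(profile, gut20)
            assert mb.sensitivity(match, len(truth_taxa)) == pytest.approx(
                expected["sensitivity"], abs=1e-9)
            assert mb.fpra(match) == pytest.approx(expected["fpra"], abs=1e-9)
            assert mb.diversity(profile) == expected["diversity"]
            assert mb.similarity(profile, actual) == pytest.approx(
                expected["similarity"], abs=1e-9)
            assert mb.diversity(profile) == \
                len(match.true_positives) + len(match.false_positives)
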