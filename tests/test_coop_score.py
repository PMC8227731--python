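"""Pair enumeration, PMI, background correction, z-scores, significance."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import fixture_library
from oracles import brute_force_pairs
from tfcoop.coop_score import (
    PairKey,
    PairStatistics,
    ScoringConfig,
    background_avg_pmi,
    count_sites_per_tf,
    enumerate_pairs,
    pmi,
    pmi_cor,
    read_pairs_tsv,
    score_corpus,
    significant_pairs,
    write_pairs_tsv,
    zscore_transform,
)
from tfcoop.promoters import PromoterSequence
from tfcoop.site_scanner import BindingSite, ScanProfile


def site(tf, prom, start, end, name="M"):
    return BindingSite(tf, f"{name}:{tf}", prom, start, end, "+", 1.0, 1.0)


class TestPairKey:
    def test_canonical_order(self):
        assert PairKey("STAT6", "GATA4") == PairKey("GATA4", "STAT6")
        k = PairKey("STAT6", "GATA4")
        assert (k.tf_a, k.tf_b) == ("GATA4", "STAT6")

    def test_homotypic_representable_but_flagged(self):
        assert PairKey("MYB", "MYB").homotypic
        assert not PairKey("MYB", "IRF").homotypic


class TestEnumeratePairs:
    @pytest.mark.parametrize(
        "gap, emitted",
        [(5, True), (20, True), (4, False), (21, False), (0, False)],
    )
    def test_gap_boundaries(self, gap, emitted):
        sites = [site("A", "p1", 90, 100), site("B", "p1", 100 + gap, 110 + gap)]
        out = enumerate_pairs(sites, ScoringConfig())
        assert bool(out) is emitted
        if emitted:
            key, prom, d = out[0]
            assert (key, prom, d) == (PairKey("A", "B"), "p1", gap)

    def test_overlapping_sites_excluded(self):
        sites = [site("A", "p1", 0, 10), site("B", "p1", 5, 15)]
        assert enumerate_pairs(sites, ScoringConfig()) == []

    def test_homotypic_skipped_even_across_matrices(self):
        sites = [
            site("A", "p1", 0, 10, name="M1"),
            site("A", "p1", 18, 28, name="M2"),
        ]
        assert enumerate_pairs(sites, ScoringConfig()) == []
        cfg = ScoringConfig(allow_homotypic=True)
        out = enumerate_pairs(sites, cfg)
        assert out == [(PairKey("A", "A"), "p1", 8.0)]

    def test_cross_promoter_pairs_never_emitted(self):
        sites = [site("A", "p1", 0, 10), site("B", "p2", 15, 25)]
        assert enumerate_pairs(sites, ScoringConfig()) == []

    def test_order_invariance(self):
        sites = [site("B", "p1", 105, 115), site("A", "p1", 90, 100)]
        out = enumerate_pairs(sites, ScoringConfig())
        assert out == [(PairKey("A", "B"), "p1", 5.0)]

    def test_matches_brute_force_on_random_site_sets(self):
        """Sweep enumeration equals the double loop, counts included."""
        rng = np.random.default_rng(99)
        tfs = ["T1", "T2", "T3", "T4"]
        for _ in range(100):
            sites = []
            for p in range(int(rng.integers(1, 6))):
                for _ in range(int(rng.integers(0, 12))):
                    start = int(rng.integers(0, 120))
                    L = int(rng.integers(6, 14))
                    sites.append(site(str(rng.choice(tfs)), f"p{p}", start, start + L))
            got = Counter(
                (frozenset((k.tf_a, k.tf_b)), prom, d)
                for k, prom, d in enumerate_pairs(sites, ScoringConfig())
            )
            expected = Counter(
                brute_force_pairs(
                    [(s.tf_name, s.promoter_id, s.start, s.end) for s in sites], 5, 20
                )
            )
            assert got == expected


class TestPmi:
    def test_toy_corpus_value(self):
        # two TFs, two sites each, the only two co-occurring pairs
        occurrences = [
            (PairKey("A", "B"), "p1", 10.0),
            (PairKey("A", "B"), "p2", 12.0),
        ]
        counts = {"A": 2, "B": 2}
        out = pmi(occurrences, counts)
        assert out[PairKey("A", "B")] == pytest.approx(2.0)

    def test_symmetry_identical_counts(self):
        occ = [
            (PairKey("A", "B"), "p1", 8.0),
            (PairKey("C", "D"), "p1", 8.0),
        ]
        counts = {"A": 3, "B": 3, "C": 3, "D": 3}
        out = pmi(occ, counts)
        assert out[PairKey("A", "B")] == pytest.approx(out[PairKey("C", "D")])

    def test_scale_invariance(self):
        occ = {PairKey("A", "B"): 3, PairKey("A", "C"): 2}
        counts = {"A": 5, "B": 4, "C": 3}
        doubled = {k: 2 * v for k, v in occ.items()}
        counts2 = {k: 2 * v for k, v in counts.items()}
        a = pmi(occ, counts)
        b = pmi(doubled, counts2)
        for k in a:
            assert a[k] == pytest.approx(b[k])

    def test_no_cooccurrence_is_error(self):
        with pytest.raises(ValueError, match="no co-occurrences"):
            pmi([], {"A": 1})

    def test_zero_count_pairs_absent_not_minus_inf(self):
        occ = {PairKey("A", "B"): 2}
        out = pmi(occ, {"A": 2, "B": 2, "C": 5})
        assert PairKey("A", "C") not in out

    def test_log_base_configurable(self):
        occ = {PairKey("A", "B"): 2}
        counts = {"A": 2, "B": 2}
        assert pmi(occ, counts, log_base=4.0)[PairKey("A", "B")] == pytest.approx(1.0)


class TestPmiCor:
    def test_printed_equation_example(self):
        assert pmi_cor(1.0, 0.5, 0.2) == pytest.approx(0.4)

    def test_alpha_minus_one_disables_background(self):
        assert pmi_cor(1.234, 99.0, -1.0) == pytest.approx(1.234)

    def test_zero_background_identity(self):
        for alpha in (-1.0, -0.5, 0.0, 0.2, 1.0):
            assert pmi_cor(0.77, 0.0, alpha) == pytest.approx(0.77)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pmi_cor(1.0, 0.5, 1.5)

    @settings(deadline=None, max_examples=100)
    @given(
        st.floats(-10, 10, allow_nan=False),
        st.floats(-10, 10, allow_nan=False),
        st.floats(-1, 1, allow_nan=False),
    )
    def test_equation_property(self, p, avg, alpha):
        assert pmi_cor(p, avg, alpha) == pytest.approx(p - (1 + alpha) * avg, abs=1e-12)


class TestZscore:
    def test_zero_variance_all_zero(self):
        vals = {PairKey("A", "B"): 0.4, PairKey("A", "C"): 0.4, PairKey("B", "C"): 0.4}
        assert set(zscore_transform(vals).values()) == {0.0}

    def test_population_sd_example(self):
        vals = {PairKey("A", "B"): 1.0, PairKey("A", "C"): 2.0, PairKey("B", "C"): 3.0}
        z = zscore_transform(vals)
        assert z[PairKey("A", "B")] == pytest.approx(-1.2247448, abs=1e-6)
        assert z[PairKey("A", "C")] == pytest.approx(0.0, abs=1e-12)
        assert z[PairKey("B", "C")] == pytest.approx(1.2247448, abs=1e-6)

    def test_location_invariance(self):
        keys = [PairKey("A", "B"), PairKey("A", "C"), PairKey("B", "C")]
        vals = dict(zip(keys, [0.1, 0.9, 0.5]))
        shifted = {k: v + 10.0 for k, v in vals.items()}
        z1, z2 = zscore_transform(vals), zscore_transform(shifted)
        for k in keys:
            assert z1[k] == pytest.approx(z2[k], abs=1e-9)

    def test_single_pair_is_error(self):
        with pytest.raises(ValueError):
            zscore_transform({PairKey("A", "B"): 1.0})


class TestSignificance:
    def mk(self, a, b, z):
        return PairStatistics(PairKey(a, b), 1, 1, 1, 0.0, 0.0, 0.0, z)

    def test_threshold_inclusive(self):
        stats = [self.mk("A", "B", 3.0), self.mk("A", "C", 2.999)]
        sig = significant_pairs(stats, ScoringConfig())
        assert [s.key for s in sig] == [PairKey("A", "B")]

    def test_sorted_descending_with_key_tiebreak(self):
        stats = [self.mk("C", "D", 3.5), self.mk("A", "B", 3.5), self.mk("E", "F", 4.0)]
        sig = significant_pairs(stats, ScoringConfig())
        assert [str(s.key) for s in sig] == ["E-F", "A-B", "C-D"]

    def test_empty_input(self):
        assert significant_pairs([], ScoringConfig()) == []


class TestBackgroundAvg:
    def _corpus(self, seed=0, n=30):
        from tfcoop.synthetic_data import Decoy, SyntheticSpec, generate_corpus

        lib = fixture_library(4)
        spec = SyntheticSpec(
            n_promoters=n, length=300,
            decoys=tuple(Decoy(p, 1.0) for p in lib),
            seed=seed,
        )
        proms, _ = generate_corpus(spec)
        return proms, lib

    def test_single_shuffle_equals_that_replicate(self):
        proms, lib = self._corpus()
        cfg1 = ScoringConfig(n_shuffles=1, seed=5)
        avg = background_avg_pmi(proms, lib, ScanProfile(0.6, 0.6), cfg1,
                                 rng=np.random.default_rng(5))
        # recompute the one replicate by hand with the same RNG stream
        from tfcoop.site_scanner import scan_corpus
        from tfcoop.synthetic_data import dinucleotide_shuffle

        rng = np.random.default_rng(5)
        shuffled = [
            PromoterSequence(p.gene_id, p.chrom, p.start, p.end, p.strand,
                             dinucleotide_shuffle(p.sequence, rng))
            for p in proms
        ]
        sites = scan_corpus(shuffled, lib, ScanProfile(0.6, 0.6))
        expected = pmi(enumerate_pairs(sites, cfg1), count_sites_per_tf(sites))
        assert avg.keys() == expected.keys()
        for k in avg:
            assert avg[k] == pytest.approx(expected[k])

    def test_absent_pair_gets_zero(self):
        proms, lib = self._corpus()
        cfg = ScoringConfig(n_shuffles=2, seed=1)
        avg = background_avg_pmi(proms, lib, ScanProfile(0.6, 0.6), cfg)
        missing = PairKey("NOPE1", "NOPE2")
        assert avg.get(missing, 0.0) == 0.0


class TestScoreCorpusDeterminism:
    def test_fixed_seed_bit_identical(self):
        from tfcoop.synthetic_data import Decoy, PlantedPair, SyntheticSpec, generate_corpus

        lib = fixture_library(4)
        spec = SyntheticSpec(
            n_promoters=40, length=300,
            planted_pairs=(PlantedPair(lib[0], lib[1], 0.5),),
            decoys=tuple(Decoy(p, 1.0) for p in lib[2:]),
            seed=3,
        )
        proms, _ = generate_corpus(spec)
        cfg = ScoringConfig(n_shuffles=3, seed=11)
        runs = [score_corpus(proms, lib, ScanProfile(), cfg) for _ in range(2)]
        assert runs[0] == runs[1]


def test_pairs_tsv_round_trip(tmp_path):
    stats = [
        PairStatistics(PairKey("A", "B"), 5, 9, 7, 1.2345678901234, 0.111, 1.1,
                       3.3333333333333335),
        PairStatistics(PairKey("A", "C"), 2, 9, 4, -0.5, 0.0, -0.5, -1.0),
    ]
    f = tmp_path / "pairs.tsv"
    write_pairs_tsv(stats, f)
    back = read_pairs_tsv(f)
    assert back == stats
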