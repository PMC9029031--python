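"""Best Match / Best Close Match / best-hit identification logic."""

import math

import numpy as np
import pytest

from barcodeval.identify import (
    AMBIGUOUS,
    BCM,
    BLAST1,
    BM,
    CORRECT,
    INCORRECT,
    NO_MATCH,
    bcm_threshold,
    best_close_match,
    best_match,
    blast1_classify,
    blast1_from_hits,
    identification_report,
    read_hit_table,
    similarity_matrix,
)
from barcodeval.k2p import distance_matrix
from barcodeval.simulate import SynthConfig, simulate_dataset

from conftest import make_dataset, make_dm


def diagnostic_dataset(n_species=4, n_seqs=3, length=60):
    """Every species has a private haplotype, identical within species:
    positive barcode gap, BM must be 100% correct."""
    entries = []
    for s in range(n_species):
        hap = list("A" * length)
        hap[5 * s : 5 * s + 5] = "GGGGG"  # species-diagnostic block
        for k in range(n_seqs):
            entries.append((f"s{s}_{k}", f"sp{s}", "".join(hap)))
    return make_dataset(entries)


class TestBestMatch:
    def test_private_haplotypes_all_correct(self):
        ds = diagnostic_dataset()
        dm = distance_matrix(ds)
        for i in range(ds.n):
            assert best_match(dm, i).verdict == CORRECT

    def test_identical_sequences_across_species_all_ambiguous(self):
        ds = make_dataset([(f"s{i}", f"sp{i % 2}", "ACGTACGT") for i in range(6)])
        dm = distance_matrix(ds)
        for i in range(ds.n):
            v = best_match(dm, i)
            assert v.verdict == AMBIGUOUS
            assert len(v.best_ids) == 5  # every other sequence ties at 0

    def test_nearest_heterospecific_beats_farther_conspecific(self):
        d = np.array(
            [
                [0.0, 0.01, 0.02],
                [0.01, 0.0, 0.05],
                [0.02, 0.05, 0.0],
            ]
        )
        dm = make_dm(["spA", "spB", "spA"], d)
        v = best_match(dm, 0)
        assert v.verdict == INCORRECT
        assert v.best_ids == ["q1"] and v.best_score == 0.01

    def test_all_references_undefined_is_no_match(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        dm = make_dm(["spA", "spA"], d)
        assert best_match(dm, 0).verdict == NO_MATCH


class TestBCMThreshold:
    def test_all_zero_intraspecific_gives_zero_threshold(self):
        ds = make_dataset([(f"s{i}", "spA", "ACGT") for i in range(4)])
        assert bcm_threshold(distance_matrix(ds)) == 0.0

    def test_percentile_matches_sorting_oracle(self):
        rng = np.random.default_rng(42)
        vals = np.round(rng.uniform(0, 0.1, size=20), 5)
        n = len(vals)
        d = np.full((2 * n, 2 * n), np.nan)
        np.fill_diagonal(d, 0.0)
        species = []
        for k, val in enumerate(vals):
            d[2 * k, 2 * k + 1] = d[2 * k + 1, 2 * k] = val
            species += [f"sp{k}", f"sp{k}"]
        dm = make_dm(species, d)
        # order-statistics oracle: sort, linear interpolation at rank 0.95(n−1)
        srt = np.sort(vals)
        rank = 0.95 * (n - 1)
        lo, frac = int(math.floor(rank)), rank - math.floor(rank)
        expected = srt[lo] + frac * (srt[lo + 1] - srt[lo])
        assert bcm_threshold(dm) == pytest.approx(expected, abs=1e-12)

    def test_single_intraspecific_pair_threshold_is_that_distance(self):
        d = np.array([[0.0, 0.034], [0.034, 0.0]])
        dm = make_dm(["spA", "spA"], d)
        assert bcm_threshold(dm) == pytest.approx(0.034)

    def test_no_intraspecific_pairs_is_an_error(self):
        dm = make_dm(["spA", "spB"], np.array([[0.0, 0.1], [0.1, 0.0]]))
        with pytest.raises(ValueError):
            bcm_threshold(dm)


class TestBestCloseMatch:
    def test_nearest_reference_beyond_threshold_is_no_match(self):
        d = np.array([[0.0, 0.2], [0.2, 0.0]])
        dm = make_dm(["spA", "spA"], d)
        v = best_close_match(dm, 0, threshold=0.05)
        assert v.verdict == NO_MATCH

    def test_zero_threshold_keeps_zero_distance_ties(self):
        # identical-sequence complex: ties at d=0 survive a 0 threshold
        ds = make_dataset([(f"s{i}", f"sp{i % 2}", "ACGTACGT") for i in range(6)])
        dm = distance_matrix(ds)
        v = best_close_match(dm, 0, threshold=0.0)
        assert v.verdict == AMBIGUOUS

    def test_threshold_between_first_and_second_neighbor(self):
        d = np.array(
            [
                [0.0, 0.01, 0.08],
                [0.01, 0.0, 0.07],
                [0.08, 0.07, 0.0],
            ]
        )
        dm = make_dm(["spA", "spB", "spA"], d)
        # conspecific q2 is cut away by the threshold; verdict by q1 only
        v = best_close_match(dm, 0, threshold=0.05)
        assert v.verdict == INCORRECT and v.best_ids == ["q1"]

    def test_bcm_only_converts_verdicts_to_no_match(self):
        ds, _ = simulate_dataset(SynthConfig(seed=13, length=150))
        dm = distance_matrix(ds)
        thr = bcm_threshold(dm)
        for i in range(0, ds.n, 7):
            bm_v = best_match(dm, i).verdict
            bcm_v = best_close_match(dm, i, thr).verdict
            if bm_v != bcm_v:
                assert bcm_v == NO_MATCH
            if bcm_v == CORRECT:
                assert bm_v == CORRECT


class TestBlast1:
    def test_private_haplotypes_all_correct(self):
        ds = diagnostic_dataset()
        sim = similarity_matrix(ds)
        for i in range(ds.n):
            v = blast1_classify(i, ds.ids, ds.species, sim)
            assert v.verdict == CORRECT

    def test_equal_top_hits_of_mixed_species_is_ambiguous(self):
        sim = np.array(
            [
                [1.0, 0.9, 0.9],
                [0.9, 1.0, 0.8],
                [0.9, 0.8, 1.0],
            ]
        )
        v = blast1_classify(0, ["q0", "q1", "q2"], ["spA", "spA", "spB"], sim)
        assert v.verdict == AMBIGUOUS

    def test_top_hit_heterospecific_is_incorrect(self):
        sim = np.array(
            [
                [1.0, 0.95, 0.80],
                [0.95, 1.0, 0.70],
                [0.80, 0.70, 1.0],
            ]
        )
        v = blast1_classify(0, ["q0", "q1", "q2"], ["spA", "spB", "spA"], sim)
        assert v.verdict == INCORRECT and v.best_score == 0.95

    def test_agrees_with_best_match_on_gap_free_alignments(self):
        # similarity = 1 − p-distance is rank-equivalent to K2P ordering
        ds, _ = simulate_dataset(SynthConfig(seed=21, length=200))
        dm = distance_matrix(ds)
        sim = similarity_matrix(ds)
        for i in range(0, ds.n, 5):
            assert (
                blast1_classify(i, ds.ids, ds.species, sim).verdict
                == best_match(dm, i).verdict
            )

    def test_external_hit_table(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\tq1\t100.0\t200\n"
            "q1\tr2\t90.5\t180\n"
            "q1\tr3\t90.5\t180\n"
            "q1\tr4\t50.0\t90\n"
        )
        hits = read_hit_table(path)
        species_of = {"r2": "spA", "r3": "spB", "r4": "spC"}
        v = blast1_from_hits("q1", "spA", species_of, hits)
        assert v.verdict == AMBIGUOUS
        assert set(v.best_ids) == {"r2", "r3"}  # self-hit dropped


class TestIdentificationReport:
    def test_single_species_identical_sequences_fully_correct(self):
        ds = make_dataset([(f"s{i}", "spA", "ACGTACGT") for i in range(5)])
        report = identification_report(ds, BM)
        assert report.rate(CORRECT) == 100.00
        assert report.rate(AMBIGUOUS) == report.rate(INCORRECT) == 0.0

    def test_identical_multi_species_dataset_fully_ambiguous(self):
        ds = make_dataset([(f"s{i}", f"sp{i % 3}", "ACGTACGT") for i in range(9)])
        for method in (BM, BCM):
            report = identification_report(ds, method)
            assert report.rate(AMBIGUOUS) == 100.00

    def test_rates_by_enumeration_on_three_species_toy(self):
        # sp1 identical pair (correct); sp2 pair split by a nearer sp3;
        # verdicts enumerated by hand from the distance structure
        base = "A" * 40
        entries = [
            ("a1", "sp1", base),
            ("a2", "sp1", base),
            ("b1", "sp2", "GGGGGGGG" + "A" * 32),
            ("b2", "sp2", "GGGGGGGGGG" + "A" * 30),
            ("c1", "sp3", "GGGGGGGGG" + "A" * 31),
            ("c2", "sp3", "CCCC" + "GGGGGGGGG" + "A" * 27),
        ]
        ds = make_dataset(entries)
        report = identification_report(ds, BM)
        verdicts = {v.query_id: v.verdict for v in report.verdicts}
        assert verdicts["a1"] == verdicts["a2"] == CORRECT
        # b1's nearest is b2 (2 diffs) vs c1 (1 diff) → c1 wins → incorrect
        assert verdicts["b1"] == INCORRECT
        assert report.n_queries == 6

    def test_queries_from_sub_two_sequence_species_excluded(self):
        ds = make_dataset(
            [
                ("a1", "spA", "ACGTACGT"),
                ("a2", "spA", "ACGTACGT"),
                ("b1", "spB", "AGGTACGT"),
            ]
        )
        report = identification_report(ds, BM)
        assert report.n_queries == 2
        assert {v.query_id for v in report.verdicts} == {"a1", "a2"}

    def test_rates_invariant_under_relabeling_within_species(self):
        ds, _ = simulate_dataset(SynthConfig(seed=31, length=150))
        report1 = identification_report(ds, BM)
        # permute ids within each species
        from barcodeval.io import AlignedDataset, SequenceRecord

        records = list(ds.records)
        by_species: dict[str, list[int]] = {}
        for i, r in enumerate(records):
            by_species.setdefault(r.species, []).append(i)
        rng = np.random.default_rng(0)
        relabeled = list(records)
        for idxs in by_species.values():
            perm = rng.permutation(idxs)
            for src, dst in zip(idxs, perm):
                relabeled[dst] = SequenceRecord(
                    records[dst].id, records[dst].species, records[src].sequence
                )
        ds2 = AlignedDataset(records=relabeled, taxonomy=ds.taxonomy)
        report2 = identification_report(ds2, BM)
        for verdict in (CORRECT, INCORRECT, AMBIGUOUS, NO_MATCH):
            assert report1.rate(verdict) == report2.rate(verdict)

    def test_no_eligible_queries_is_an_error(self):
        ds = make_dataset([("a1", "spA", "ACGT"), ("b1", "spB", "AGGT")])
        with pytest.raises(ValueError, match="eligible"):
            identification_report(ds, BM)

    def test_percentages_sum_to_100(self):
        ds, _ = simulate_dataset(SynthConfig(seed=17, length=150))
        for method in (BM, BCM, BLAST1):
            report = identification_report(ds, method)
            total = sum(
                report.rate(v) for v in (CORRECT, INCORRECT, AMBIGUOUS, NO_MATCH)
            )
            assert total == pytest.approx(100.0, abs=0.05)
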