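"""Synthetic-data generator: determinism, regime switches, and the
consistency of the K2P simulator with its own distance estimator."""

import json
import math

import numpy as np
import pytest

from barcodeval.divergence import divergence_summary
from barcodeval.identify import AMBIGUOUS, BM, best_match, identification_report
from barcodeval.io import subset_by_level
from barcodeval.k2p import distance_matrix, k2p_pair
from barcodeval.simulate import (
    GenusSpec,
    SynthConfig,
    evolve,
    expected_k2p,
    expected_pq,
    simulate_dataset,
    transition_matrix,
    write_dataset,
)


class TestConfig:
    def test_impossible_divergence_ordering_rejected(self):
        with pytest.raises(ValueError, match="δ_w ≤ δ_b ≤ δ_g"):
            SynthConfig(delta_w=0.2, delta_b=0.1)

    def test_nonpositive_kappa_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(kappa=0.0)


class TestDeterminism:
    def test_fixed_seed_gives_byte_identical_fasta(self, tmp_path):
        for run in ("a", "b"):
            ds, truth = simulate_dataset(SynthConfig(seed=123))
            write_dataset(
                ds, truth,
                tmp_path / f"{run}.fasta", tmp_path / f"{run}.tsv",
                tmp_path / f"{run}.json",
            )
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_different_seeds_differ(self):
        ds1, _ = simulate_dataset(SynthConfig(seed=1))
        ds2, _ = simulate_dataset(SynthConfig(seed=2))
        assert [r.sequence for r in ds1.records] != [r.sequence for r in ds2.records]


class TestDegenerateRegimes:
    def test_zero_divergence_everywhere_gives_identical_sequences(self):
        ds, _ = simulate_dataset(
            SynthConfig(seed=5, delta_w=0.0, delta_b=0.0, delta_g=0.0)
        )
        assert len({r.sequence for r in ds.records}) == 1
        dm = distance_matrix(ds)
        assert np.all(dm.d == 0.0)

    def test_zero_variation_complex_is_fully_ambiguous(self):
        ds, truth = simulate_dataset(
            SynthConfig(seed=8, zero_variation_complex=True)
        )
        assert truth["zero_variation_complex"] == ["CPX"]
        view = subset_by_level(ds, "complex", "CPX")
        assert len({r.sequence for r in view.records}) == 1
        report = identification_report(view, BM)
        assert report.rate(AMBIGUOUS) == 100.00

    def test_haplotype_sharing_forces_zero_minimum_interspecific(self):
        ds, truth = simulate_dataset(SynthConfig(seed=9, share_haplotypes=True))
        assert truth["shared_haplotype_pairs"]
        seqs = {r.id: r.sequence for r in ds.records}
        for src, dst in truth["shared_haplotype_pairs"]:
            assert seqs[src] == seqs[dst]
        # check one sharing genus end-to-end
        src_id = truth["shared_haplotype_pairs"][0][0]
        genus = ds.taxonomy.genus[next(r.species for r in ds.records if r.id == src_id)]
        view = subset_by_level(ds, "genus", genus)
        summary = divergence_summary(distance_matrix(view))
        assert summary.min_interspecific.mean < summary.all_interspecific.mean
        assert min(
            0.0 if s1 == s2 else d
            for (s1, s2, d) in _hetero_pairs(view)
        ) == 0.0

    def test_gap_injection_produces_gap_columns(self):
        ds, _ = simulate_dataset(SynthConfig(seed=4, n_gap_columns=20, gap_prob=0.5))
        assert any("-" in r.sequence for r in ds.records)
        distance_matrix(ds)  # pairwise deletion still yields a matrix


def _hetero_pairs(view):
    dm = distance_matrix(view)
    iu, ju = dm.pair_indices()
    for i, j in zip(iu, ju):
        if dm.defined[i, j]:
            yield dm.species[i], dm.species[j], dm.d[i, j]


class TestProcessConsistency:
    def test_transition_matrix_rows_are_distributions(self):
        P = transition_matrix(0.37, kappa=3.0)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.all(P >= 0.0)

    def test_expected_k2p_is_the_branch_length(self):
        assert expected_k2p(0.0, 2.0) == 0.0
        assert expected_k2p(0.1, 0.5) == 0.1
        assert expected_k2p(0.1, 10.0) == 0.1

    def test_estimator_inverts_expected_proportions_exactly(self):
        # plugging the analytic E[P], E[Q] into the distance formula must
        # return the branch length: the estimator is consistent
        for t in (0.01, 0.1, 0.3):
            for kappa in (0.5, 1.0, 2.0, 8.0):
                P, Q = expected_pq(t, kappa)
                d = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
                assert d == pytest.approx(t, abs=1e-12)

    @pytest.mark.parametrize("kappa", [1.0, 4.0])
    def test_mean_estimated_distance_matches_divergence(self, kappa):
        # Monte-Carlo: many simulated pairs at total branch length 0.1;
        # kappa=1 is the equal-rates (Jukes–Cantor-like) limit
        rng = np.random.default_rng(100)
        t = 0.1
        dists = []
        for _ in range(300):
            root = rng.integers(0, 4, size=300)
            leaf = evolve(root, t, kappa, rng)
            a = "".join("ACGT"[x] for x in root)
            b = "".join("ACGT"[x] for x in leaf)
            d, *_ , ok = k2p_pair(a, b)
            assert ok
            dists.append(d)
        dists = np.asarray(dists)
        se = dists.std(ddof=1) / math.sqrt(len(dists))
        assert abs(dists.mean() - t) < 3 * se + 1e-4


class TestStructure:
    def test_roster_respects_genus_and_subfamily_assignment(self):
        ds, truth = simulate_dataset(SynthConfig(seed=2))
        tax = ds.taxonomy
        assert truth["n_species"] == len(tax.genus)
        # complex species sit inside their genus
        for sp, cpx in tax.complex.items():
            assert cpx == "CPX" and tax.genus[sp] == "GenusG"

    def test_custom_roster_and_fixed_sampling_depth(self):
        genera = [GenusSpec("G1", "S1", n_species=3, seqs_per_species=4)]
        ds, _ = simulate_dataset(SynthConfig(seed=3, genera=genera, length=100))
        assert ds.n == 12 and ds.aligned_length == 100
        counts = ds.species_counts()
        assert set(counts.values()) == {4}
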