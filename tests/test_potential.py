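"""Training averages, preference coefficients, energies and scoring."""

import math

import numpy as np
import pytest

from contactpot.constants import AA_INDEX, AA_ORDER, N_AA
from contactpot.contact_area import ContactRecord, ContactTable, structure_contact_table
from contactpot.fixtures import PlantedCorpusSpec, make_planted_corpus
from contactpot.potential import (
    PotentialTable,
    TrainingAverages,
    accumulate_averages,
    compute_E,
    compute_K,
    load_potential,
    save_potential,
    score_structure,
    train_potential,
)


def _table(structure_id, pairs, probe=0.25):
    """ContactTable from [(aa_i, aa_j, d, area), ...]."""
    return ContactTable(
        structure_id=structure_id,
        probe_radius=probe,
        n_points=0,
        records=[
            ContactRecord(aa_i=a, aa_j=b, d_bin=d, area=area, probe_radius=probe)
            for a, b, d, area in pairs
        ],
    )


class TestAccumulateAverages:
    def test_single_observation_mean(self):
        """One structure, one ALA-GLY d=1 contact of 5 A^2: the pair mean is
        5; the off-diagonal pair enters both marginals, so A_all counts it
        from both sides (the convention under which a preference-free corpus
        gives K identically 1)."""
        avgs = accumulate_averages([_table("s1", [("A", "G", 1, 5.0)])], d_bins=(1,))
        i, j = AA_INDEX["A"], AA_INDEX["G"]
        assert avgs.A_ab[1][i, j] == 5.0
        assert avgs.A_ab[1][j, i] == 5.0
        assert avgs.A_a[1][i] == 5.0
        assert avgs.A_all[1] == 10.0

    def test_mean_over_structures(self):
        tables = [
            _table("s1", [("A", "G", 1, 4.0)]),
            _table("s2", [("A", "G", 1, 6.0)]),
        ]
        avgs = accumulate_averages(tables, d_bins=(1,))
        assert avgs.A_ab[1][AA_INDEX["A"], AA_INDEX["G"]] == 5.0
        assert avgs.n_structures == 2

    def test_unordered_pair_pooling(self):
        """(G, A) and (A, G) records accumulate into the same cell."""
        avgs = accumulate_averages(
            [_table("s1", [("G", "A", 1, 2.0), ("A", "G", 1, 3.0)])], d_bins=(1,)
        )
        assert avgs.A_ab[1][AA_INDEX["A"], AA_INDEX["G"]] == 5.0

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            accumulate_averages([], d_bins=(1,))

    def test_mixed_probe_rejected(self):
        tables = [
            _table("s1", [("A", "G", 1, 4.0)], probe=0.25),
            _table("s2", [("A", "G", 1, 6.0)], probe=0.5),
        ]
        with pytest.raises(ValueError):
            accumulate_averages(tables, d_bins=(1,))


def _uniform_averages(value=5.0):
    M = np.full((N_AA, N_AA), value)
    return TrainingAverages(
        probe_radius=0.25,
        d_bins=(1,),
        A_ab={1: M},
        A_a={1: M.sum(axis=1)},
        A_all={1: float(M.sum())},
        counts={1: np.full((N_AA, N_AA), 100, dtype=int)},
        n_structures=100,
    )


class TestComputeK:
    def test_uniform_corpus_gives_unit_preference(self):
        K = compute_K(_uniform_averages())
        assert np.allclose(K[1], 1.0, atol=1e-12)

    def test_linear_in_pair_area_at_fixed_marginals(self):
        avgs = _uniform_averages()
        K1 = compute_K(avgs)[1].copy()
        i, j = AA_INDEX["A"], AA_INDEX["L"]
        avgs.A_ab[1][i, j] *= 2.0
        avgs.A_ab[1][j, i] = avgs.A_ab[1][i, j]
        K2 = compute_K(avgs)[1]
        assert K2[i, j] == pytest.approx(2.0 * K1[i, j], rel=1e-12)

    def test_recomputable_from_serialized_tables(self, tmp_path):
        """K from the training pipeline equals a one-pass recomputation from
        the contact tables written to disk."""
        spec = PlantedCorpusSpec(
            n_structures=25, pair_enrichment=np.ones((N_AA, N_AA)) + 0.5,
            area_noise_cv=0.3, rng_seed=11,
        )
        tables = make_planted_corpus(spec)
        K = compute_K(accumulate_averages(tables, d_bins=(1,)))[1]

        paths = []
        for t in tables:
            p = tmp_path / f"{t.structure_id}.tsv"
            t.write_tsv(p)
            paths.append(p)
        # independent one-pass recomputation from the TSVs
        M = np.zeros((N_AA, N_AA))
        for p in paths:
            for line in p.read_text().splitlines()[1:]:
                _, a, b, d, _, area = line.split("\t")
                i, j = AA_INDEX[a], AA_INDEX[b]
                M[i, j] += float(area)
                if i != j:
                    M[j, i] += float(area)
        M /= len(paths)
        expected = M * M.sum() / np.outer(M.sum(axis=1), M.sum(axis=1))
        assert np.allclose(K, expected, rtol=1e-10)


class TestComputeE:
    def test_log_identities_unsmoothed(self):
        K = {1: np.full((N_AA, N_AA), 1.0)}
        assert np.allclose(compute_E(K, None)[1], 0.0)
        K = {1: np.full((N_AA, N_AA), math.e)}
        assert np.allclose(compute_E(K, None)[1], -1.0)
        assert np.allclose(compute_E(K, None, temperature_factor=2.0)[1], -2.0)

    def test_smoothing_neutralises_unobserved_pairs(self):
        K = {1: np.zeros((N_AA, N_AA))}
        counts = {1: np.zeros((N_AA, N_AA), dtype=int)}
        E = compute_E(K, counts)
        assert np.allclose(E[1], 0.0)

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(0.5, 2.0, (N_AA, N_AA))
        K = {1: (raw + raw.T) / 2}
        counts = {1: np.full((N_AA, N_AA), 10, dtype=int)}
        E = compute_E(K, counts)[1]
        assert np.allclose(E, E.T)


class TestInvariants:
    def test_scale_invariance_of_K(self):
        spec = PlantedCorpusSpec(
            n_structures=10, pair_enrichment=np.ones((N_AA, N_AA)) * 1.3,
            area_noise_cv=0.2, rng_seed=3,
        )
        tables = make_planted_corpus(spec)
        K1 = compute_K(accumulate_averages(tables, d_bins=(1,)))[1]
        scaled = [
            ContactTable(
                structure_id=t.structure_id, probe_radius=t.probe_radius,
                n_points=t.n_points,
                records=[
                    ContactRecord(aa_i=r.aa_i, aa_j=r.aa_j, d_bin=r.d_bin,
                                  area=7.0 * r.area, probe_radius=r.probe_radius)
                    for r in t.records
                ],
            )
            for t in tables
        ]
        K2 = compute_K(accumulate_averages(scaled, d_bins=(1,)))[1]
        assert np.allclose(K1, K2, rtol=1e-10)


def _flat_potential(e_value, d_bins=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10), probe=0.25):
    K = {d: np.full((N_AA, N_AA), math.exp(-e_value)) for d in d_bins}
    E = {d: np.full((N_AA, N_AA), float(e_value)) for d in d_bins}
    counts = {d: np.full((N_AA, N_AA), 1, dtype=int) for d in d_bins}
    return PotentialTable(probe_radius=probe, d_bins=d_bins, K=K, E=E,
                          counts=counts, metadata={"n_points": 256})


class TestScoring:
    def test_total_is_area_times_energy(self, extended10):
        """With E = -0.5 everywhere the total equals -0.5 times the summed
        d=1 contact area."""
        pot = _flat_potential(-0.5)
        result = score_structure(extended10, pot, d_filter={1})
        table = structure_contact_table(extended10, 0.25, n_points=256)
        area_d1 = sum(r.area for r in table.records if r.d_bin == 1)
        assert result.total_energy == pytest.approx(-0.5 * area_d1, rel=1e-9)
        assert result.total_energy == pytest.approx(
            sum(c[-1] for c in result.contributions), rel=1e-9
        )

    def test_score_equals_dot_product_of_serialized_table(self, tmp_path, helix10):
        """Oracle equivalence: total equals the dot product of the written
        contact-table areas with the matching E entries."""
        rng = np.random.default_rng(5)
        raw = rng.uniform(-1, 1, (N_AA, N_AA))
        E1 = (raw + raw.T) / 2
        pot = _flat_potential(0.0)
        pot.E[1] = E1
        result = score_structure(helix10, pot, d_filter={1})
        table = structure_contact_table(helix10, 0.25, n_points=256)
        path = tmp_path / "t.tsv"
        table.write_tsv(path)
        expected = 0.0
        for line in path.read_text().splitlines()[1:]:
            _, a, b, d, _, area = line.split("\t")
            if int(d) == 1:
                expected += float(area) * E1[AA_INDEX[a], AA_INDEX[b]]
        assert result.total_energy == pytest.approx(expected, rel=1e-9)

    def test_scoring_linearity_over_bin_partition(self, helix10):
        pot = _flat_potential(-0.3)
        parts = [
            score_structure(helix10, pot, d_filter={d}).total_energy
            for d in pot.d_bins
        ]
        full = score_structure(helix10, pot, d_filter=set(pot.d_bins)).total_energy
        assert full == pytest.approx(sum(parts), rel=1e-9)

    def test_no_contacts_in_filter_scores_zero(self, extended10):
        pot = _flat_potential(-0.5)
        assert score_structure(extended10, pot, d_filter={9}).total_energy == 0.0

    def test_too_small_structure_rejected(self, extended10):
        from dataclasses import replace

        single = replace(extended10, residues=extended10.residues[:1])
        with pytest.raises(ValueError):
            score_structure(single, _flat_potential(-0.5))

    def test_use_preference_multiplies_K(self, extended10):
        pot = _flat_potential(-0.5)
        by_e = score_structure(extended10, pot, d_filter={1})
        by_k = score_structure(extended10, pot, d_filter={1}, use_preference=True)
        area = by_e.total_energy / -0.5
        assert by_k.total_energy == pytest.approx(math.exp(0.5) * area, rel=1e-9)


class TestSerialization:
    def _trained(self):
        spec = PlantedCorpusSpec(
            n_structures=8, pair_enrichment=np.ones((N_AA, N_AA)),
            area_noise_cv=0.4, rng_seed=9,
        )
        return train_potential(make_planted_corpus(spec), d_bins=(1, 2))

    def test_round_trip_bit_identical(self, tmp_path):
        pot = self._trained()
        path = tmp_path / "pot.tsv"
        save_potential(pot, path)
        back = load_potential(path)
        for d in pot.d_bins:
            assert np.array_equal(pot.K[d], back.K[d])
            assert np.array_equal(pot.E[d], back.E[d])
            assert np.array_equal(pot.counts[d], back.counts[d])
        assert back.probe_radius == pot.probe_radius
        assert back.metadata["n_training_structures"] == 8

    def test_missing_bin_rows_named_in_error(self, tmp_path):
        pot = self._trained()
        path = tmp_path / "pot.tsv"
        save_potential(pot, path)
        lines = [
            l for l in path.read_text().splitlines()
            if not (l[0:2] == "2\t")
        ]
        clipped = tmp_path / "clipped.tsv"
        clipped.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="d bin 2"):
            load_potential(clipped)

    def test_pair_order_violation_rejected(self, tmp_path):
        pot = self._trained()
        path = tmp_path / "pot.tsv"
        save_potential(pot, path)
        text = path.read_text().replace("1\tA\tC\t", "1\tC\tA\t", 1)
        bad = tmp_path / "bad.tsv"
        bad.write_text(text)
        with pytest.raises(ValueError, match="aa_i <= aa_j"):
            load_potential(bad)

    def test_duplicate_row_rejected(self, tmp_path):
        pot = self._trained()
        path = tmp_path / "pot.tsv"
        save_potential(pot, path)
        lines = path.read_text().splitlines()
        body_at = next(i for i, l in enumerate(lines) if l.startswith("d_bin"))
        lines.append(lines[body_at + 1])
        dup = tmp_path / "dup.tsv"
        dup.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_potential(dup)

    def test_wrong_format_tag_rejected(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("not a potential\n")
        with pytest.raises(ValueError, match="format"):
            load_potential(path)
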