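"""Filtering, CSS normalization, ADG slopes and the dataset join."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutsem import (
    BodyWeightSeries,
    GenomicRelationshipMatrix,
    NormalizedOtuTable,
    OtuCountTable,
    PhenotypeTable,
    assemble_sem_dataset,
    compute_adg,
    css_normalize,
    filter_otus,
)


def _table(counts, taxonomy=None):
    counts = np.asarray(counts)
    return OtuCountTable(
        sample_ids=[f"s{i}" for i in range(counts.shape[0])],
        otu_ids=[f"otu{j}" for j in range(counts.shape[1])],
        counts=counts,
        taxonomy=taxonomy or {},
    )


class TestFilterOtus:
    def test_boundary_prevalence_exactly_at_threshold_is_retained(self):
        # detected in exactly 5% of samples: the removal rule is strictly
        # "less than", so the OTU survives
        counts = np.zeros((20, 2), dtype=int)
        counts[0, 0] = 1000
        counts[:, 1] = 5
        out = filter_otus(_table(counts), prevalence_min=0.05, abundance_min=0.0001)
        assert out.otu_ids == ["otu0", "otu1"]

    def test_all_zero_column_removed(self):
        counts = np.column_stack([np.ones(10, dtype=int), np.zeros(10, dtype=int)])
        out = filter_otus(_table(counts), prevalence_min=0.01, abundance_min=0.0001)
        assert out.otu_ids == ["otu0"]

    def test_toy_matrix_against_independent_column_scan(self):
        # OTU-A nonzero in 6 samples summing 600, OTU-B nonzero in 1 sample
        # summing 1, OTU-C all zero
        counts = np.zeros((10, 3), dtype=int)
        counts[:6, 0] = 100
        counts[0, 1] = 1
        table = _table(counts)
        prevalence_min, abundance_min = 0.5, 0.01

        # independent per-column scan
        survivors = []
        grand = counts.sum()
        for j, otu in enumerate(table.otu_ids):
            col = counts[:, j]
            if (col > 0).sum() / 10 >= prevalence_min and col.sum() / grand >= abundance_min:
                survivors.append(otu)
        assert survivors == ["otu0"]

        out = filter_otus(table, prevalence_min, abundance_min)
        assert out.otu_ids == survivors
        assert out.sample_ids == table.sample_ids

    def test_idempotent(self, rng):
        counts = rng.poisson(3, size=(15, 8))
        once = filter_otus(_table(counts), 0.3, 0.01)
        twice = filter_otus(once, 0.3, 0.01)
        assert once.otu_ids == twice.otu_ids
        np.testing.assert_array_equal(once.counts, twice.counts)

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            filter_otus(_table(np.empty((0, 0), dtype=int)))
        counts = np.zeros((10, 2), dtype=int)
        counts[0] = [1, 1]
        with pytest.raises(ValueError, match="all OTUs removed"):
            filter_otus(_table(counts), prevalence_min=0.9)

    def test_taxonomy_restricted_to_survivors(self):
        counts = np.column_stack([np.ones(10, dtype=int), np.zeros(10, dtype=int)])
        table = _table(counts, taxonomy={"otu0": "k__A", "otu1": "k__B"})
        out = filter_otus(table, 0.5, 0.001)
        assert out.taxonomy == {"otu0": "k__A"}


class TestCssNormalize:
    def test_hand_evaluated_two_by_two(self):
        # sample 1 counts (2,2): median positive count 2, factor 2+2=4
        # sample 2 counts (4,4): factor 8; reference = median(4,8) = 6
        out = css_normalize(_table([[2, 2], [4, 4]]), quantile=0.5)
        np.testing.assert_allclose(out.scaling_factors, [4.0, 8.0])
        np.testing.assert_allclose(out.values, [[3.0, 3.0], [3.0, 3.0]])

    def test_proportional_samples_normalize_identically(self, rng):
        base = rng.poisson(10, size=12) + 1
        out = css_normalize(_table(np.vstack([base, 3 * base, 7 * base])))
        np.testing.assert_allclose(out.values[0], out.values[1], rtol=1e-12)
        np.testing.assert_allclose(out.values[0], out.values[2], rtol=1e-12)

    def test_identical_samples_all_equal(self):
        counts = np.tile([5, 1, 9, 0], (4, 1))
        out = css_normalize(_table(counts))
        assert np.allclose(out.values, out.values[0])

    def test_single_otu_table(self):
        out = css_normalize(_table([[3], [30], [7]]))
        np.testing.assert_allclose(out.values, out.reference_scale)

    def test_log2_flag(self):
        plain = css_normalize(_table([[2, 2], [4, 4]]), log2_transform=False)
        logged = css_normalize(_table([[2, 2], [4, 4]]), log2_transform=True)
        np.testing.assert_allclose(logged.values, np.log2(plain.values + 1))
        assert logged.log2_transformed

    def test_zero_sample_named_in_error(self):
        with pytest.raises(ValueError, match="s1"):
            css_normalize(_table([[1, 2], [0, 0]]))


class TestComputeAdg:
    def test_exact_linear(self):
        series = BodyWeightSeries("a", [(d, 100 + 50 * d) for d in (32, 39, 46, 53)])
        assert compute_adg(series) == pytest.approx(50.0)

    def test_two_point_slope(self):
        assert compute_adg(
            BodyWeightSeries("a", [(32, 700), (66, 2400)])
        ) == pytest.approx((2400 - 700) / (66 - 32))

    def test_noisy_points_match_closed_form_ols(self, rng):
        ages = np.array([32.0, 39.0, 46.0, 53.0])
        weights = 650 + 48.0 * ages + rng.normal(0, 30, 4)
        slope = compute_adg(BodyWeightSeries("a", list(zip(ages, weights))))
        expected = ((ages - ages.mean()) * (weights - weights.mean())).sum() / (
            (ages - ages.mean()) ** 2
        ).sum()
        assert slope == pytest.approx(expected, rel=1e-12)

    @given(
        shift=st.floats(-30, 30),
        scale=st.floats(0.1, 10),
        slope=st.floats(-5, 80),
    )
    @settings(max_examples=50, deadline=None)
    def test_shift_invariant_and_scale_equivariant(self, shift, scale, slope):
        ages = np.array([35.0, 42.0, 49.0, 63.0])
        weights = 500 + slope * ages + np.array([3.0, -5.0, 1.0, 2.0])
        base = compute_adg(BodyWeightSeries("a", list(zip(ages, weights))))
        shifted = compute_adg(BodyWeightSeries("a", list(zip(ages + shift, weights))))
        scaled = compute_adg(BodyWeightSeries("a", list(zip(ages, weights * scale))))
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError, match="2 body-weight"):
            compute_adg(BodyWeightSeries("a", [(32, 700)]))
        with pytest.raises(ValueError, match="distinct ages"):
            compute_adg(BodyWeightSeries("a", [(32, 700), (32, 710)]))


def _toy_join_inputs():
    animals = [f"a{i}" for i in range(6)]
    frame = pd.DataFrame(
        {
            "animal_id": animals,
            "regime": ["AL", "R", "AL", "R", "AL", "R"],
            "adg": [55.0, 38.0, 52.0, 40.0, 57.0, 37.0],
            "batch_farm": ["b1", "b1", "b2", "b2", "b1", "b2"],
            "ww_class": ["large", "small", "large", "small", "large", "small"],
            "litter_id": ["L1", "L1", "L2", "L2", "L3", "L3"],
            "cage_id": ["C1", "C2", "C1", "C2", "C3", "C3"],
        }
    )
    phenos = PhenotypeTable(frame)
    norm = NormalizedOtuTable(
        sample_ids=animals[::-1],  # deliberately different ordering
        otu_ids=["otuX"],
        values=np.arange(6, dtype=float).reshape(-1, 1),
        scaling_factors=np.ones(6),
        reference_scale=1.0,
    )
    grm = GenomicRelationshipMatrix(animals, np.eye(6), 0.0)
    return phenos, norm, grm


class TestAssembleSemDataset:
    def test_hand_aligned_join(self):
        phenos, norm, grm = _toy_join_inputs()
        data = assemble_sem_dataset(phenos, norm, "otuX", grm)
        assert data.animal_ids == [f"a{i}" for i in range(6)]
        # sample ids were reversed, so animal a0 carries M value 5
        np.testing.assert_allclose(data.y_m, [5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        np.testing.assert_allclose(data.y_al[[0, 2, 4]], [55.0, 52.0, 57.0])
        assert np.isnan(data.y_al[[1, 3, 5]]).all()

    def test_regime_determines_missing_slot(self):
        phenos, norm, grm = _toy_join_inputs()
        data = assemble_sem_dataset(phenos, norm, "otuX", grm)
        on_al = phenos.frame.regime.to_numpy() == "AL"
        assert np.isnan(data.y_r[on_al]).all()
        assert not np.isnan(data.y_al[on_al]).any()

    def test_disjoint_ids_error(self):
        phenos, norm, grm = _toy_join_inputs()
        norm.sample_ids = [f"z{i}" for i in range(6)]
        with pytest.raises(ValueError, match="unmatched"):
            assemble_sem_dataset(phenos, norm, "otuX", grm)


def test_biom_hdf5_reader_round_trip(tmp_path, rng):
    """A minimal BIOM 2.x file (observations x samples, CSR) reads back
    into the same counts and taxonomy."""
    import h5py
    from scipy.sparse import csr_matrix

    from gutsem.preprocess import read_otu_table_biom

    counts = rng.poisson(4, size=(3, 5))  # otus x samples
    sparse = csr_matrix(counts)
    path = tmp_path / "table.biom"
    with h5py.File(path, "w") as f:
        f.create_dataset("observation/ids", data=[b"otuA", b"otuB", b"otuC"])
        f.create_dataset("sample/ids", data=[f"s{i}".encode() for i in range(5)])
        f.create_dataset("observation/matrix/data", data=sparse.data.astype(float))
        f.create_dataset("observation/matrix/indices", data=sparse.indices)
        f.create_dataset("observation/matrix/indptr", data=sparse.indptr)
        tax = np.array(
            [[b"k__Bacteria", b"f__S24-7"], [b"k__Bacteria", b"f__X"], [b"Unassigned", b""]]
        )
        f.create_dataset("observation/metadata/taxonomy", data=tax)
    table = read_otu_table_biom(path)
    assert table.otu_ids == ["otuA", "otuB", "otuC"]
    assert table.sample_ids == [f"s{i}" for i in range(5)]
    np.testing.assert_array_equal(table.counts, counts.T)
    assert table.taxonomy["otuA"] == "k__Bacteria;f__S24-7"


def test_phenotype_table_warns_on_crowded_litter_cage():
    frame = pd.DataFrame(
        {
            "animal_id": ["a", "b", "c"],
            "regime": ["AL", "R", "AL"],
            "adg": [50.0, 40.0, 52.0],
            "batch_farm": ["b1"] * 3,
            "ww_class": ["large"] * 3,
            "litter_id": ["L1"] * 3,
            "cage_id": ["C1"] * 3,
        }
    )
    with pytest.warns(UserWarning, match="more than 2"):
        PhenotypeTable(frame)
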