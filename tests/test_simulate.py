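import numpy as np
import pandas as pd
import pytest

import scsexbias as s
from scsexbias.simulate import ConfigurationError, SimConfig, _realize, write_simulation


class TestSimConfig:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_cell_types=2, type_proportions_female=[0.6, 0.5])

    def test_baseline_shape_checked(self):
        with pytest.raises(ConfigurationError, match="baseline_means shape"):
            SimConfig(n_genes=3, n_cell_types=2, baseline_means=np.ones((2, 2)))

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(nb_dispersion=-0.5)

    def test_dropout_range(self):
        with pytest.raises(ConfigurationError):
            SimConfig(dropout_rate=1.2)

    def test_bad_regulatory_assignment(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_genes=5, regulatory_assignments=[(9, 0, "female")])


class TestSimulateCounts:
    def test_dimensions(self):
        cfg = SimConfig(n_genes=50, n_cell_types=2, n_replicates_per_sex=3,
                        cells_per_sample=100, seed=0)
        counts, meta, truth = s.simulate_counts(cfg)
        assert counts.shape == (50, 600)
        assert len(meta) == 600
        assert truth.expected_bulk_lfc.shape == (50,)

    def test_determinism_bit_identical(self):
        cfg = SimConfig(n_genes=30, n_cell_types=2, cells_per_sample=50,
                        regulatory_fraction=0.3, dropout_rate=0.1, seed=42)
        a = s.simulate_counts(cfg)
        b = s.simulate_counts(SimConfig(**{**cfg.to_flat_dict()}))
        assert a[0] == b[0]
        assert a[1].frame.equals(b[1].frame)
        assert np.array_equal(a[2].expected_bulk_lfc, b[2].expected_bulk_lfc,
                              equal_nan=True)
        assert a[2].regulatory_genes == b[2].regulatory_genes

    def test_different_seed_differs(self):
        cfg1 = SimConfig(n_genes=30, cells_per_sample=50, seed=1)
        cfg2 = SimConfig(n_genes=30, cells_per_sample=50, seed=2)
        assert s.simulate_counts(cfg1)[0] != s.simulate_counts(cfg2)[0]

    def test_metadata_structure(self):
        cfg = SimConfig(n_genes=10, n_replicates_per_sex=2, cells_per_sample=20, seed=3)
        _, meta, _ = s.simulate_counts(cfg)
        frame = meta.frame
        assert set(frame["sex"]) == {"female", "male"}
        assert frame.groupby("sample_id").size().nunique() == 1
        assert len(set(frame["sample_id"])) == 4

    def test_mean_recovery(self):
        """Empirical per-(gene, type, sex) means over >= 5000 cells are within
        5% of the configured NB mean for means >= 1."""
        base = np.array([[2.0, 8.0], [1.0, 30.0], [12.0, 4.0]])
        cfg = SimConfig(
            n_genes=3, n_cell_types=2, n_replicates_per_sex=1,
            cells_per_sample=12000, baseline_means=base,
            libsize_logsd=0.0, nb_dispersion=0.2, seed=7,
        )
        counts, meta, _ = s.simulate_counts(cfg)
        dense = counts.to_dense()
        frame = meta.frame
        for sex in ("female", "male"):
            for t in range(2):
                mask = ((frame["sex"] == sex) & (frame["cell_type"] == f"type{t}")).to_numpy()
                assert mask.sum() >= 5000
                emp = dense[:, mask].mean(axis=1)
                assert np.allclose(emp, base[:, t], rtol=0.05)

    def test_abundance_truth_binomial_error(self):
        props_f = np.array([0.6, 0.3, 0.1])
        cfg = SimConfig(n_genes=5, n_cell_types=3, n_replicates_per_sex=1,
                        cells_per_sample=20000,
                        type_proportions_female=props_f, seed=11)
        _, meta, _ = s.simulate_counts(cfg)
        frame = meta.frame[meta.frame["sex"] == "female"]
        n = len(frame)
        for t, p in enumerate(props_f):
            emp = (frame["cell_type"] == f"type{t}").mean()
            se = np.sqrt(p * (1 - p) / n)
            assert abs(emp - p) <= 5 * se

    def test_dropout_thins_means(self):
        base = np.full((4, 1), 20.0)
        kw = dict(n_genes=4, n_cell_types=1, n_replicates_per_sex=1,
                  cells_per_sample=8000, baseline_means=base,
                  libsize_logsd=0.0, seed=5)
        full, _, _ = s.simulate_counts(SimConfig(**kw))
        dropped, _, _ = s.simulate_counts(SimConfig(dropout_rate=0.4, **kw))
        ratio = dropped.to_dense().mean() / full.to_dense().mean()
        assert ratio == pytest.approx(0.6, abs=0.03)


class TestExpectedBulkLfc:
    def test_all_zero_under_symmetry(self):
        cfg = SimConfig(n_genes=20, n_cell_types=3, regulatory_fraction=0.0, seed=0)
        assert np.allclose(s.expected_bulk_lfc(cfg), 0.0)

    def test_closed_form_mixture_example(self):
        # baseline (10, 0); pi_f = (.5, .5); pi_m = (.25, .75)
        # mixture means: f = .5*10 = 5; m = .25*10 = 2.5 -> lfc = 1
        cfg = SimConfig(
            n_genes=1, n_cell_types=2, baseline_means=np.array([[10.0, 0.0]]),
            type_proportions_female=[0.5, 0.5],
            type_proportions_male=[0.25, 0.75], seed=0,
        )
        assert s.expected_bulk_lfc(cfg)[0] == pytest.approx(1.0)

    def test_independent_mixture_oracle(self, rng):
        """Cross-check against a direct loop computation."""
        base = rng.gamma(2, 2, size=(15, 3))
        pf = np.array([0.2, 0.5, 0.3])
        pm = np.array([0.4, 0.4, 0.2])
        cfg = SimConfig(n_genes=15, n_cell_types=3, baseline_means=base,
                        type_proportions_female=pf, type_proportions_male=pm,
                        regulatory_assignments=[(0, 1, "female"), (3, 0, "male")],
                        regulatory_lfc=2.0, seed=0)
        got = s.expected_bulk_lfc(cfg)
        half = 2 ** 1.0  # lfc/2 in linear scale
        for g in range(15):
            mf = mm = 0.0
            for t in range(3):
                ff = fm = 1.0
                if (g, t) == (0, 1):
                    ff, fm = half, 1 / half
                if (g, t) == (3, 0):
                    ff, fm = 1 / half, half
                mf += pf[t] * base[g, t] * ff
                mm += pm[t] * base[g, t] * fm
            assert got[g] == pytest.approx(np.log2(mf / mm), abs=1e-12)

    def test_sex_limited_infinite(self):
        cfg = SimConfig(
            n_genes=1, n_cell_types=2, baseline_means=np.array([[0.0, 4.0]]),
            type_proportions_female=[0.5, 0.5],
            type_proportions_male=[1.0, 0.0], seed=0,
        )
        lfc, limited = s.expected_bulk_lfc(cfg, return_sex_limited=True)
        assert np.isposinf(lfc[0])
        assert limited[0]

    def test_within_type_regulatory_lfc_is_exact(self):
        cfg = SimConfig(
            n_genes=2, n_cell_types=1, baseline_means=np.array([[6.0], [6.0]]),
            regulatory_assignments=[(0, 0, "female")], regulatory_lfc=3.0, seed=0,
        )
        lfc = s.expected_bulk_lfc(cfg)
        assert lfc[0] == pytest.approx(3.0)
        assert lfc[1] == pytest.approx(0.0)


class TestTruthSets:
    def test_regulatory_and_abundance_sets_disjoint(self):
        cfg = SimConfig(n_genes=60, n_cell_types=2,
                        type_proportions_female=[0.7, 0.3],
                        type_proportions_male=[0.3, 0.7],
                        regulatory_fraction=0.4, seed=9)
        _, _, truth = s.simulate_counts(cfg)
        reg = {g for g, _, _ in truth.regulatory_genes}
        assert not (reg & truth.expected_abundance_driven)

    def test_mixture_consistency_large_sample(self):
        """Empirical bulk lfc from simulated counts approaches the analytic
        mixture value (<= 0.1 absolute at 50,000 cells per sex)."""
        base = np.array([[20.0, 2.0], [5.0, 15.0], [8.0, 8.0]])
        cfg = SimConfig(
            n_genes=3, n_cell_types=2, n_replicates_per_sex=1,
            cells_per_sample=50000, baseline_means=base,
            type_proportions_female=[0.7, 0.3], type_proportions_male=[0.3, 0.7],
            libsize_logsd=0.0, seed=13,
        )
        counts, meta, truth = s.simulate_counts(cfg)
        dense = counts.to_dense()
        f = (meta.frame["sex"] == "female").to_numpy()
        emp = np.log2(dense[:, f].mean(axis=1) / dense[:, ~f].mean(axis=1))
        assert np.all(np.abs(emp - truth.expected_bulk_lfc) <= 0.1)


class TestSimulateDivergence:
    def test_omega_zero_gives_no_nonsynonymous(self):
        cfg = SimConfig(n_genes=100, omega_by_group={"dead": 0.0}, seed=1)
        div = s.simulate_divergence(cfg)
        assert (div["DN"] == 0).all()

    def test_saturated_limit(self):
        cfg = SimConfig(n_genes=50, omega_by_group={"sat": 1.0}, seed=2)
        div = s.simulate_divergence(cfg, p_s=1.0)
        assert np.allclose(div["dN"], 1.0)
        assert np.allclose(div["dS"], 1.0)

    def test_invalid_rate_product(self):
        cfg = SimConfig(n_genes=10, omega_by_group={"hot": 20.0}, seed=0)
        with pytest.raises(ConfigurationError, match="> 1"):
            s.simulate_divergence(cfg, p_s=0.1)

    def test_group_aggregated_omega_recovered(self):
        cfg = SimConfig(n_genes=2000, omega_by_group={"sel": 0.5}, seed=3)
        div = s.simulate_divergence(cfg, n_by_gene=900, s_by_gene=300, p_s=0.1)
        gd = s.group_rates(div)
        assert 0.45 <= gd.omega <= 0.55

    def test_group_labels_round_robin(self):
        cfg = SimConfig(n_genes=10, omega_by_group={"a": 0.1, "b": 0.9}, seed=4)
        div = s.simulate_divergence(cfg)
        assert (div["group"].value_counts() == 5).all()

    def test_seed_reproducible(self):
        cfg = SimConfig(n_genes=40, omega_by_group={"a": 0.4}, seed=8)
        assert s.simulate_divergence(cfg).equals(s.simulate_divergence(cfg))


class TestWriteSimulation:
    def test_round_trip_files(self, tmp_path):
        cfg = SimConfig(n_genes=12, n_cell_types=2, cells_per_sample=30, seed=6)
        counts, meta, truth = s.simulate_counts(cfg)
        write_simulation(str(tmp_path), counts, meta, truth, cfg)
        back = s.read_counts(str(tmp_path / "counts"))
        assert back == counts
        meta_back = s.CellMetadata.read_tsv(str(tmp_path / "metadata.tsv"))
        assert len(meta_back) == len(meta)
        truth_back = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        assert len(truth_back) == 12
        assert (tmp_path / "sim_config.txt").exists()
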