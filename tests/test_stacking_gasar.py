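"""PF assembly, chromosome mechanics, GA-SAR and the meta-predictor."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stackpr.baseline_models import CVScheme
from stackpr.stacking_gasar import (
    CARDINALITY_MAX,
    CARDINALITY_MIN,
    Chromosome,
    ConfigurationError,
    GAConfig,
    GAResult,
    PFMatrix,
    assemble_pf_matrix,
    cardinality_bounds,
    control_result,
    decode_param,
    feature_importance,
    fitness,
    predict_meta,
    repair,
    run_gasar,
    train_meta,
)
from stackpr.synthetic import SyntheticPFConfig, make_synthetic_pf

FAST_CV = CVScheme(n_folds=3, seed=0)


def planted(n=120, p=12, informative=(0, 1, 2), effect=0.35, noise=0.1, seed=0):
    cfg = SyntheticPFConfig(
        n_compounds=n, n_columns=p, informative_columns=tuple(informative),
        effect=effect, noise_sd=noise, seed=seed,
    )
    return make_synthetic_pf(cfg)


class TestPFMatrix:
    def test_assembly_order_and_shape(self):
        vectors = {f"BM{i}": np.full(10, 0.5) for i in range(72)}
        pf = assemble_pf_matrix(vectors, ids=[str(i) for i in range(10)])
        assert pf.shape == (10, 72)
        assert pf.columns == list(vectors)

    def test_single_compound_row_is_concatenation(self):
        vectors = {"a": np.array([0.1]), "b": np.array([0.9])}
        pf = assemble_pf_matrix(vectors, ids=["c1"])
        assert pf.values.tolist() == [[0.1, 0.9]]

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            assemble_pf_matrix({"a": np.array([1.2])}, ids=["c1"])

    def test_length_mismatch_rejected(self):
        from stackpr.stacking_gasar import AlignmentError

        with pytest.raises(AlignmentError):
            assemble_pf_matrix(
                {"a": np.zeros(3), "b": np.zeros(4)}, ids=["1", "2", "3"]
            )

    def test_select_missing_column_names_it(self):
        pf, _ = planted()
        with pytest.raises(KeyError, match="PF99"):
            pf.select(["PF00", "PF99"])

    def test_csv_roundtrip(self, tmp_path):
        pf, _ = planted(n=5)
        path = tmp_path / "pf.csv"
        pf.to_csv(path)
        loaded = PFMatrix.from_csv(path)
        assert loaded.columns == pf.columns
        assert np.allclose(loaded.values, pf.values)


class TestDecode:
    @pytest.mark.parametrize(
        "bits,expected",
        [((0, 0, 0), 20), ((0, 0, 1), 50), ((0, 1, 0), 100), ((0, 1, 1), 200),
         ((1, 0, 0), 500), ((1, 0, 1), 20), ((1, 1, 0), 50), ((1, 1, 1), 100)],
    )
    def test_total_over_all_codes(self, bits, expected):
        assert decode_param(bits) == expected

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            decode_param((0, 1))


class TestRepair:
    def test_all_zero_promoted_to_lower_bound(self):
        chrom = Chromosome(bg=np.zeros(72, dtype=int), param_bits=(0, 0, 0))
        assert repair(chrom, np.random.default_rng(0)).n_selected == CARDINALITY_MIN

    def test_all_one_demoted_to_upper_bound(self):
        chrom = Chromosome(bg=np.ones(72, dtype=int), param_bits=(0, 0, 0))
        assert repair(chrom, np.random.default_rng(0)).n_selected == CARDINALITY_MAX

    def test_feasible_chromosome_untouched(self):
        bg = np.zeros(72, dtype=int)
        bg[:12] = 1
        chrom = Chromosome(bg=bg, param_bits=(1, 0, 1))
        out = repair(chrom, np.random.default_rng(0))
        assert (out.bg == bg).all()

    @given(st.integers(0, 72), st.integers(0, 2**16 - 1))
    @settings(max_examples=100, derandomize=True)
    def test_hamming_distance_equals_deficit_or_excess(self, n_ones, seed):
        rng = np.random.default_rng(seed)
        bg = np.zeros(72, dtype=int)
        bg[rng.choice(72, size=n_ones, replace=False)] = 1
        out = repair(Chromosome(bg=bg, param_bits=(0, 0, 0)), rng)
        lo, hi = cardinality_bounds(72)
        assert lo <= out.n_selected <= hi
        hamming = int((out.bg != bg).sum())
        assert hamming == max(0, lo - n_ones) + max(0, n_ones - hi)

    def test_bounds_clamp_for_narrow_matrices(self):
        assert cardinality_bounds(4) == (4, 4)
        assert cardinality_bounds(10) == (5, 10)
        assert cardinality_bounds(72) == (5, 20)


def _chrom(p, cols, bits=(0, 1, 0)):
    bg = np.zeros(p, dtype=int)
    bg[list(cols)] = 1
    return Chromosome(bg=bg, param_bits=bits)


class TestFitness:
    def test_informative_beats_noise(self):
        wins = 0
        for seed in range(5):
            pf, y = planted(n=120, p=12, informative=(0, 1, 2, 3, 4), seed=seed)
            cv = CVScheme(n_folds=3, seed=seed)
            f_info = fitness(_chrom(12, range(5)), pf, y, cv, seed=seed)
            f_noise = fitness(_chrom(12, range(5, 10)), pf, y, cv, seed=seed)
            wins += f_info > f_noise
        assert wins >= 4

    def test_permutation_null_fitness_near_zero(self):
        pf, y = planted(n=300, p=12, informative=(0, 1, 2))
        rng = np.random.default_rng(123)
        y_perm = rng.permutation(y)
        f = fitness(_chrom(12, range(5)), pf, y_perm, FAST_CV, seed=0)
        assert abs(f) < 0.15

    def test_deterministic(self):
        pf, y = planted()
        c = _chrom(12, range(5))
        assert fitness(c, pf, y, FAST_CV, seed=3) == fitness(c, pf, y, FAST_CV, seed=3)

    def test_unrepaired_chromosome_rejected(self):
        pf, y = planted()
        with pytest.raises(ValueError, match="repair"):
            fitness(_chrom(12, [0]), pf, y, FAST_CV)


SMALL_GA = dict(population_size=6, generations=3, n_runs=1, cv=FAST_CV)


class TestRunGasar:
    def test_selected_cardinality_within_bounds(self):
        pf, y = planted(n=100, p=12)
        result = run_gasar(pf, y, GAConfig(seed=1, **SMALL_GA))
        lo, hi = cardinality_bounds(12)
        assert lo <= len(result.selected_columns) <= hi
        assert result.n_estimators in (20, 50, 100, 200, 500)

    def test_single_run_frequencies_are_binary(self):
        pf, y = planted(n=100, p=12)
        result = run_gasar(pf, y, GAConfig(seed=1, **SMALL_GA))
        assert set(result.sar_frequencies.values()) <= {0.0, 1.0}

    def test_every_evaluated_chromosome_feasible(self):
        pf, y = planted(n=100, p=12)
        result = run_gasar(pf, y, GAConfig(seed=2, **SMALL_GA))
        lo, hi = cardinality_bounds(12)
        assert result.evaluated_cardinalities
        assert all(lo <= c <= hi for c in result.evaluated_cardinalities)

    def test_deterministic_given_seed(self):
        pf, y = planted(n=100, p=12)
        r1 = run_gasar(pf, y, GAConfig(seed=5, **SMALL_GA))
        r2 = run_gasar(pf, y, GAConfig(seed=5, **SMALL_GA))
        assert r1.to_json() == r2.to_json()

    def test_small_population_rejected(self):
        with pytest.raises(ConfigurationError):
            GAConfig(population_size=2)

    def test_odd_population_rejected(self):
        with pytest.raises(ConfigurationError):
            GAConfig(population_size=7)


class TestRecoveryWithGradient:
    def test_weak_complementary_signal_is_enriched_in_selection(self):
        # weak per-column effect: no single column is near-perfect, so CV
        # fitness genuinely rewards collecting informative columns and the
        # selected subset must be enriched well beyond the chance level
        # (17 of 36 columns would pick up ~2.8 informative at random)
        cfg = SyntheticPFConfig(
            n_compounds=250, n_columns=36, informative_columns=tuple(range(6)),
            effect=0.10, noise_sd=0.15, seed=0,
        )
        pf, y = make_synthetic_pf(cfg)
        ga = GAConfig(
            population_size=8, generations=4, n_runs=2, seed=0,
            cv=CVScheme(n_folds=2, seed=0),
        )
        result = run_gasar(pf, y, ga)
        recovered = len(set(result.selected_columns) & {f"PF{i:02d}" for i in range(6)})
        assert recovered >= 4


class TestMeta:
    def _fit(self, seed=0):
        pf, y = planted(n=100, p=12, seed=seed)
        result = run_gasar(pf, y, GAConfig(seed=seed, **SMALL_GA))
        model = train_meta(pf, y, result, seed=seed)
        return pf, y, model

    def test_training_rescore_is_deterministic(self):
        pf, y, model = self._fit()
        p1 = predict_meta(model, pf)["probability"].to_numpy()
        p2 = predict_meta(model, pf)["probability"].to_numpy()
        assert np.array_equal(p1, p2)

    def test_probability_half_is_called_active(self):
        pf, y, model = self._fit()
        # force a score of exactly 0.5 through the threshold rule
        proba = np.array([0.5])
        label = np.where(proba >= model.threshold, "active", "inactive")
        assert label[0] == "active"

    def test_control_mode_uses_all_columns(self):
        pf, y = planted(n=100, p=12)
        control = control_result(pf, y, FAST_CV, seed=0)
        assert control.selected_columns == pf.columns
        model = train_meta(pf, y, control, seed=0)
        out = predict_meta(model, pf)
        assert list(out.columns) == ["id", "probability", "label"]
        assert len(out) == 100

    def test_missing_selected_column_raises(self):
        pf, y, model = self._fit()
        reduced = PFMatrix(
            ids=pf.ids, columns=pf.columns[:-1], values=pf.values[:, :-1]
        )
        if model.columns[-1] == pf.columns[-1]:
            with pytest.raises(KeyError):
                predict_meta(model, reduced)
        else:
            dropped = model.columns[0]
            keep = [c for c in pf.columns if c != dropped]
            reduced = pf.select(keep)
            with pytest.raises(KeyError, match=dropped):
                predict_meta(model, reduced)


class TestFeatureImportance:
    def test_informative_columns_rank_above_noise(self):
        pf, y = planted(n=150, p=10, informative=(0, 1, 2))
        result = control_result(pf, y, FAST_CV, seed=0)
        model = train_meta(pf, y, result, seed=0)
        imp = feature_importance(model, pf, y, backend="permutation", n_repeats=5, seed=0)
        info = imp.iloc[[0, 1, 2]].mean()
        noise = imp.iloc[3:].mean()
        assert info > noise

    def test_constant_column_has_zero_importance(self):
        pf, y = planted(n=100, p=10, informative=(0,))
        values = pf.values.copy()
        values[:, 5] = 0.5
        pf2 = PFMatrix(ids=pf.ids, columns=pf.columns, values=values)
        result = control_result(pf2, y, FAST_CV, seed=0)
        model = train_meta(pf2, y, result, seed=0)
        imp = feature_importance(model, pf2, y, backend="permutation", n_repeats=3, seed=0)
        assert imp["PF05"] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_backend_rejected(self):
        pf, y = planted(n=60, p=10)
        result = control_result(pf, y, FAST_CV, seed=0)
        model = train_meta(pf, y, result, seed=0)
        with pytest.raises(ConfigurationError, match="backend"):
            feature_importance(model, pf, y, backend="astrology")
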