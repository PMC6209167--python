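import numpy as np
import pytest

from abxlattice import (
    CellState,
    Lattice,
    ModelParams,
    SweepRng,
    antibiotic_field,
    concentrations,
    initialize_lattice,
    mutate_offspring,
    read_snapshot,
    run,
    sweep,
    write_snapshot,
)
from abxlattice.lattice import (
    _KernelState,
    _neighbor_production_sum,
    code_label,
    lattice_to_rgb,
)


def brute_force_field(lattice: Lattice, b: float) -> np.ndarray:
    """Independent O(L^2 * 9) oracle for the antibiotic field."""
    L = lattice.side
    grid = lattice.grid
    arate = {0: 0.0, 100: 0.0, 101: 0.0}
    for k, a in enumerate(lattice.allowed_a):
        arate[1 + k] = a
    out = np.zeros((L, L))
    for x in range(L):
        for y in range(L):
            total = 0.0
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    total += arate[int(grid[(x + dx) % L, (y + dy) % L])]
            out[x, y] = total / (9 * b)
    return out


def random_lattice(params, rng, p_occupied=0.4):
    codes = [0, 100, 101] + list(range(1, len(params.allowed_a) + 1))
    n_types = len(codes) - 1
    probs = [1 - p_occupied] + [p_occupied / n_types] * n_types
    flat = rng.choice(np.array(codes, dtype=np.int8), size=params.L**2, p=probs)
    return Lattice(params.L, flat, params.allowed_a)


class TestInitializeLattice:
    def test_expected_fractions(self):
        p = ModelParams(L=128, allowed_a=(0.0, 150.0))
        comp = [
            (CellState.producer(150.0), 0.05),
            (CellState.nonproducer(), 0.05),
            (CellState.sensitive(), 0.05),
        ]
        lat = initialize_lattice(p, comp, rng=0)
        n = p.L**2
        counts = lat.counts()
        # binomial: sd of count ~ sqrt(n * .05 * .95) ~ 28; allow 5 sigma
        for code in (1, 2, 100):
            assert abs(counts[code] - 0.05 * n) < 5 * np.sqrt(n * 0.05 * 0.95)
        assert counts[0] == n - counts[1] - counts[2] - counts[100]

    def test_empty_composition_gives_vacant_lattice(self):
        lat = initialize_lattice(ModelParams(L=16), [], rng=0)
        assert (lat.codes == 0).all()

    def test_full_sensitive_lattice(self):
        lat = initialize_lattice(
            ModelParams(L=16), [(CellState.sensitive(), 1.0)], rng=0
        )
        assert (lat.codes == 100).all()

    def test_overfull_rejected(self):
        with pytest.raises(ValueError):
            initialize_lattice(
                ModelParams(L=16),
                [(CellState.sensitive(), 0.7), (CellState.nonproducer(), 0.5)],
            )

    def test_unknown_strain_rejected(self):
        with pytest.raises(ValueError):
            initialize_lattice(
                ModelParams(L=16, allowed_a=(0.0,)),
                [(CellState.producer(42.0), 0.1)],
            )


class TestAntibioticField:
    def test_single_producer(self):
        p = ModelParams(L=8, allowed_a=(0.0, 110.0))
        lat = initialize_lattice(p, [], rng=0)
        lat.grid[3, 4] = 2  # one P110
        field = antibiotic_field(lat, b=10.0)
        expected = np.zeros((8, 8))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                expected[(3 + dx) % 8, (4 + dy) % 8] = 110.0 / 90.0
        assert np.allclose(field, expected)

    def test_all_sensitive_zero_field(self):
        p = ModelParams(L=8)
        lat = initialize_lattice(p, [(CellState.sensitive(), 1.0)], rng=0)
        assert np.allclose(antibiotic_field(lat, 10.0), 0.0)

    def test_uniform_producers_match_well_mixed(self):
        p = ModelParams(L=8, allowed_a=(0.0, 90.0))
        lat = initialize_lattice(p, [(CellState.producer(90.0), 1.0)], rng=0)
        assert np.allclose(antibiotic_field(lat, 10.0), 9.0)  # a/b

    def test_matches_brute_force_on_random_lattices(self, rng):
        p = ModelParams(L=12, allowed_a=(0.0, 50.0, 110.0))
        for _ in range(3):
            lat = random_lattice(p, rng)
            assert np.allclose(
                antibiotic_field(lat, 10.0), brute_force_field(lat, 10.0)
            )

    def test_torus_wrap_at_corners(self):
        p = ModelParams(L=6, allowed_a=(0.0, 60.0))
        lat = initialize_lattice(p, [], rng=0)
        lat.grid[0, 0] = 2
        field = antibiotic_field(lat, 10.0)
        assert field[5, 5] == pytest.approx(60.0 / 90.0)  # diagonal wrap
        assert field[3, 3] == 0.0


class TestKernelFieldConsistency:
    def test_incremental_field_matches_recomputation(self):
        # the kernel maintains the neighbourhood production sum
        # incrementally; after many births/deaths it must still equal the
        # from-scratch vectorized computation (exact for integer rates)
        p = ModelParams(L=48, allowed_a=(0.0, 150.0), seed=3)
        comp = [
            (CellState.producer(150.0), 0.05),
            (CellState.nonproducer(), 0.05),
            (CellState.sensitive(), 0.05),
        ]
        lat = initialize_lattice(p, comp, rng=3)
        ks = _KernelState(lat, p, SweepRng(3))
        ks.advance(2000, sr_mutation=False, global_dispersal=False)
        assert np.array_equal(ks.afield, _neighbor_production_sum(lat, p))


class TestMutateOffspring:
    def test_u_zero_is_identity(self):
        p = ModelParams(allowed_a=(0.0, 110.0), u=0.0)
        rng = SweepRng(1)
        parent = CellState.producer(110.0)
        assert mutate_offspring(parent, p, rng) == parent

    def test_vacant_parent_rejected(self):
        with pytest.raises(ValueError):
            mutate_offspring(CellState.vacant(), ModelParams(), SweepRng(1))

    def test_two_strain_flip(self):
        p = ModelParams(allowed_a=(0.0, 110.0), u=1.0)
        rng = SweepRng(1)
        offspring = mutate_offspring(CellState.producer(110.0), p, rng)
        assert offspring == CellState.producer(0.0)
        assert mutate_offspring(CellState.nonproducer(), p, rng) == CellState.producer(110.0)

    def test_multi_strain_uniform_over_complement(self):
        allowed = tuple(float(x) for x in range(0, 210, 10))
        p = ModelParams(allowed_a=allowed, u=1.0)
        rng = SweepRng(9)
        parent = CellState.producer(110.0)
        draws = [mutate_offspring(parent, p, rng).a for _ in range(4000)]
        values, counts = np.unique(draws, return_counts=True)
        assert 110.0 not in values
        assert len(values) == 20
        # each of the 20 other strains ~200 hits; allow 5 sigma ~ 70
        assert (np.abs(counts - 200) < 70).all()

    def test_sr_toggle_only_when_enabled(self):
        p = ModelParams(u=1.0)
        rng = SweepRng(1)
        s = CellState.sensitive()
        assert mutate_offspring(s, p, rng, sr_mutation=False) == s
        assert mutate_offspring(s, p, rng, sr_mutation=True) == CellState.resistant_cell()
        assert (
            mutate_offspring(CellState.resistant_cell(), p, rng, sr_mutation=True)
            == CellState.sensitive()
        )


class TestSweepAndRun:
    def test_empty_lattice_unchanged(self):
        p = ModelParams(L=16)
        lat = initialize_lattice(p, [], rng=0)
        sweep(lat, p, SweepRng(0), n_sweeps=50)
        assert (lat.codes == 0).all()

    def test_determinism(self, pns_composition):
        p = ModelParams(L=48, allowed_a=(0.0, 150.0), seed=11)
        r1 = run(p, pns_composition(150.0), 30.0)
        r2 = run(p, pns_composition(150.0), 30.0)
        assert np.array_equal(r1.lattice.codes, r2.lattice.codes)
        assert np.array_equal(r1.series.counts, r2.series.counts)

    def test_seed_changes_trajectory(self, pns_composition):
        p = ModelParams(L=48, allowed_a=(0.0, 150.0))
        r1 = run(p, pns_composition(150.0), 30.0, seed=1)
        r2 = run(p, pns_composition(150.0), 30.0, seed=2)
        assert not np.array_equal(r1.lattice.codes, r2.lattice.codes)

    def test_single_type_absorbing_with_no_mutation(self):
        p = ModelParams(L=32, u=0.0, seed=5)
        result = run(p, [(CellState.sensitive(), 0.5)], 100.0)
        codes = set(np.unique(result.lattice.codes).tolist())
        assert codes <= {0, 100}
        # and the run flags early termination at the first record
        assert result.stopped_early

    def test_no_new_types_without_mutation(self, pns_composition):
        # conservation: with u = 0 the set of present a-values never grows
        p = ModelParams(L=48, allowed_a=(0.0, 50.0, 150.0), u=0.0, seed=13)
        comp = [
            (CellState.producer(150.0), 0.05),
            (CellState.sensitive(), 0.05),
        ]  # note: no N, no P50
        result = run(p, comp, 80.0, early_stop=False)
        assert (result.series.counts[:, 1] == 0).all()  # N never appears
        assert (result.series.counts[:, 2] == 0).all()  # P50 never appears
        assert (result.series.counts[:, 101] == 0).all()  # R never appears

    def test_all_vacant_is_absorbing_even_with_mutation(self):
        p = ModelParams(L=16, u=0.5)
        result = run(p, [], 50.0)
        assert result.stopped_early
        assert (result.lattice.codes == 0).all()

    def test_null_model_pure_death_decay(self):
        # negligible birth rates: occupancy decays ~ exp(-v t)
        p = ModelParams(L=96, r1=1e-9, r2=1e-9, v=1.0, seed=2)
        result = run(
            p, [(CellState.sensitive(), 0.9)], 3.0, record_every=1.0,
            early_stop=False,
        )
        occ = 1.0 - result.series.fractions()[:, 0]
        expected = occ[0] * np.exp(-result.series.times)
        assert np.allclose(occ, expected, rtol=0.05)

    def test_quasi_stationary_sensitive_density(self):
        # spatial correlations keep the density strictly between 0 and
        # the mean-field value 1 - 1/r2 = 0.6
        p = ModelParams(L=128, seed=8)
        result = run(p, [(CellState.sensitive(), 1.0)], 150.0, early_stop=False)
        final_frac = result.series.fractions()[-1, 100]
        assert 0.3 < final_frac < 0.6

    def test_birth_and_death_probabilities(self):
        # single S cell: per sweep P(birth attempt) = r2 dt, P(death) = v dt
        p = ModelParams(L=24, r2=2.5, v=1.0, dt=0.01)
        n_death = 0
        n_trials = 300
        for s in range(n_trials):
            lat = initialize_lattice(p, [], rng=0)
            lat.grid[5, 5] = 100
            sweep(lat, p, SweepRng(s), n_sweeps=1)
            n = int((lat.codes == 100).sum())
            if lat.grid[5, 5] == 0:
                n_death += 1
        # death prob 0.01: expect ~3 of 300; allow wide slack
        assert n_death <= 12

    def test_surrounded_sensitive_cannot_give_birth(self):
        # 9 producers at a=150, b=10 -> A_loc = 15 > r2: birth clamped to 0
        p = ModelParams(L=16, allowed_a=(0.0, 150.0), dt=0.04, seed=0)
        lat = initialize_lattice(p, [], rng=0)
        lat.grid[4:7, 4:7] = 2
        lat.grid[5, 5] = 100
        for s in range(60):
            trial = lat.copy()
            sweep(trial, p, SweepRng(s), n_sweeps=1)
            n_s = int((trial.codes == 100).sum())
            assert n_s <= 1  # never two S cells: the S cell cannot reproduce

    def test_hooks_switch_mutation_on(self):
        # strain 2 can only appear after the hook enables mutation
        p = ModelParams(L=32, allowed_a=(0.0, 110.0), u=0.0, seed=4)
        result = run(
            p,
            [(CellState.producer(110.0), 0.4)],
            60.0,
            record_every=5.0,
            hooks=[(30.0, {"u": 0.2})],
            early_stop=False,
        )
        n_counts = result.series.counts[:, 1]  # non-producer N
        times = result.series.times
        assert (n_counts[times <= 30.0] == 0).all()
        assert n_counts[-1] > 0

    def test_hook_beyond_t_end_rejected(self):
        p = ModelParams(L=16)
        with pytest.raises(ValueError):
            run(p, [], 10.0, hooks=[(20.0, {"u": 0.1})])

    def test_resume_from_lattice(self):
        p = ModelParams(L=32, seed=6)
        first = run(p, [(CellState.sensitive(), 0.3)], 20.0, early_stop=False)
        resumed = run(
            p, None, 20.0, lattice=first.lattice.copy(), early_stop=False
        )
        assert resumed.series.counts[0, 100] == first.series.counts[-1, 100]

    def test_species_label_symmetry(self):
        # with a = 0 everywhere, c_R = 0 and r1 = r2, species labels are
        # exchangeable: ensemble-mean occupancies must agree
        p = ModelParams(L=48, r1=2.0, r2=2.0)
        f1, f2 = [], []
        for s in range(12):
            result = run(
                p,
                [(CellState.nonproducer(), 0.25), (CellState.sensitive(), 0.25)],
                40.0,
                seed=s,
                early_stop=False,
            )
            frac = result.series.fractions()[-1]
            f1.append(frac[1])
            f2.append(frac[100])
        m1, m2 = np.mean(f1), np.mean(f2)
        pooled_sd = np.sqrt((np.var(f1) + np.var(f2)) / 12)
        assert abs(m1 - m2) < 5 * pooled_sd + 0.02


class TestConcentrations:
    def test_all_vacant(self):
        lat = initialize_lattice(ModelParams(L=16), [], rng=0)
        assert concentrations(lat) == {"vacant": 1.0}

    def test_half_and_half_exact(self):
        p = ModelParams(L=16)
        lat = initialize_lattice(p, [], rng=0)
        lat.codes[: 128] = 100
        conc = concentrations(lat)
        assert conc == {"vacant": 0.5, "S": 0.5}

    def test_sums_to_one_exactly(self, rng):
        p = ModelParams(L=32, allowed_a=(0.0, 50.0, 110.0))
        lat = random_lattice(p, rng)
        assert sum(concentrations(lat).values()) == 1.0

    def test_initialization_fractions(self):
        p = ModelParams(L=128, allowed_a=(0.0, 150.0))
        comp = [
            (CellState.producer(150.0), 0.05),
            (CellState.nonproducer(), 0.05),
            (CellState.sensitive(), 0.05),
        ]
        conc = concentrations(initialize_lattice(p, comp, rng=1))
        for key in ("P150", "N", "S"):
            assert conc[key] == pytest.approx(0.05, abs=0.01)


class TestSnapshotIO:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        p = ModelParams(
            L=24, allowed_a=(0.0, 50.0, 110.0), c=0.0012, u=1e-4, c_R=0.3, seed=77
        )
        lat = random_lattice(p, rng)
        path = tmp_path / "state.snap"
        write_snapshot(path, lat, p, time=123.5)
        lat2, p2, t2 = read_snapshot(path)
        assert np.array_equal(lat.codes, lat2.codes)
        assert p2 == p
        assert t2 == 123.5

    def test_code_labels(self):
        allowed = (0.0, 50.0, 110.0)
        assert code_label(0, allowed) == "vacant"
        assert code_label(1, allowed) == "N"
        assert code_label(3, allowed) == "P110"
        assert code_label(100, allowed) == "S"
        assert code_label(101, allowed) == "R"

    def test_series_csv(self, tmp_path, pns_composition):
        p = ModelParams(L=32, allowed_a=(0.0, 150.0), seed=1)
        result = run(p, pns_composition(150.0), 20.0, early_stop=False)
        path = tmp_path / "series.csv"
        result.series.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["t", "N", "P150", "S", "R", "vacant"]
        assert len(df) == len(result.series.times)
        assert (df[["N", "P150", "S", "R", "vacant"]].sum(axis=1) == 32 * 32).all()


class TestRender:
    def test_rgb_shape_and_palette(self, rng):
        p = ModelParams(L=16, allowed_a=(0.0, 110.0))
        lat = random_lattice(p, rng)
        img = lattice_to_rgb(lat)
        assert img.shape == (16, 16, 3)
        assert img.dtype == np.uint8
        vac = np.where(lat.grid == 0)
        assert (img[vac[0][0], vac[1][0]] == [255, 255, 255]).all()
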