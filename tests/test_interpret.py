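import numpy as np
import pytest

from succinet.interpret import (
    AttributionProfile,
    aggregate_by_distance,
    aggregate_by_position,
    exact_shapley,
    kernel_shapley,
    read_structure_ca,
    window_distances,
)
from succinet.seqdata import ALPHABET, HALF_WIDTH, WINDOW_LENGTH


def random_windows(rng, n):
    aa = list(ALPHABET)
    return ["".join(rng.choice(aa, size=WINDOW_LENGTH)) for _ in range(n)]


def k_centered(rng, n):
    out = []
    for w in random_windows(rng, n):
        chars = list(w)
        chars[HALF_WIDTH] = "K"
        out.append("".join(chars))
    return out


def additive_fn(coefs, letter="E"):
    def predict(windows):
        return np.array(
            [sum(c for i, c in enumerate(coefs) if w[i] == letter) for w in windows]
        )
    return predict


# --- exact enumeration -------------------------------------------------------

def test_constant_position_gets_zero_attribution(rng):
    """A position holding the same residue in the instance and every
    background (here the centre lysine) contributes exactly zero."""
    instance = k_centered(rng, 1)[0]
    backgrounds = k_centered(rng, 10)
    coefs = rng.normal(size=WINDOW_LENGTH)
    positions = [13, 14, 15, HALF_WIDTH, 17, 18]
    prof = exact_shapley(additive_fn(coefs, "K"), instance, backgrounds, positions)
    assert prof.values[HALF_WIDTH] == 0.0


def test_additive_model_closed_form(rng):
    """For f(w) = sum_i c_i [w_i == 'E'] the Shapley value at i is
    c_i * ([x_i == 'E'] - mean_bg [w_i == 'E'])."""
    coefs = rng.normal(size=WINDOW_LENGTH)
    instance = random_windows(rng, 1)[0]
    backgrounds = random_windows(rng, 12)
    positions = list(range(10, 18))
    prof = exact_shapley(additive_fn(coefs), instance, backgrounds, positions)
    for i in positions:
        mean_bg = np.mean([w[i] == "E" for w in backgrounds])
        expected = coefs[i] * ((instance[i] == "E") - mean_bg)
        assert prof.values[i] == pytest.approx(expected, abs=1e-10)
    untouched = [i for i in range(WINDOW_LENGTH) if i not in positions]
    assert np.all(prof.values[untouched] == 0.0)


def test_symmetry_axiom(rng):
    """Positions the model and data treat identically get equal values."""
    def predict(windows):  # symmetric in positions 5 and 6
        return np.array([(w[5] == "E") + (w[6] == "E") for w in windows], dtype=float)

    instance = "E" * WINDOW_LENGTH
    backgrounds = ["A" * WINDOW_LENGTH] * 3
    prof = exact_shapley(predict, instance, backgrounds, positions=[5, 6, 7, 8])
    assert prof.values[5] == pytest.approx(prof.values[6], abs=1e-12)


def test_efficiency_exact(rng):
    instance = random_windows(rng, 1)[0]
    backgrounds = random_windows(rng, 8)
    coefs = rng.normal(size=WINDOW_LENGTH)

    def predict(windows):  # nonlinear in the window content
        base = additive_fn(coefs)(windows)
        return 1.0 / (1.0 + np.exp(-(base + 0.5 * base**2)))

    positions = list(range(8))
    prof = exact_shapley(predict, instance, backgrounds, positions)
    fx = float(predict([instance])[0])
    assert prof.values.sum() + prof.base_value == pytest.approx(fx, abs=1e-10)


def test_dummy_axiom(rng):
    """Positions the model provably ignores get |phi| below 1e-9."""
    active = {3, 4}

    def predict(windows):
        return np.array([sum(w[i] == "E" for i in active) for w in windows], dtype=float)

    instance = random_windows(rng, 1)[0]
    backgrounds = random_windows(rng, 6)
    prof = exact_shapley(predict, instance, backgrounds, positions=[2, 3, 4, 5, 6])
    assert abs(prof.values[2]) < 1e-9
    assert abs(prof.values[5]) < 1e-9
    assert abs(prof.values[6]) < 1e-9


def test_exact_position_limit():
    with pytest.raises(ValueError, match="kernel_shapley"):
        exact_shapley(lambda ws: np.zeros(len(ws)), "K" * 33, ["A" * 33])


# --- kernel estimator ---------------------------------------------------------

def nonlinear_fn(rng):
    coefs = rng.normal(size=WINDOW_LENGTH)
    pair = rng.normal()

    def predict(windows):
        base = additive_fn(coefs)(windows)
        inter = np.array([pair * (w[12] == "E") * (w[20] == "E") for w in windows])
        return 1.0 / (1.0 + np.exp(-(base + inter)))

    return predict


def test_kernel_matches_exact_enumerated(rng):
    """With every coalition inside the budget the kernel solve is exact."""
    for _ in range(10):
        predict = nonlinear_fn(rng)
        instance = random_windows(rng, 1)[0]
        backgrounds = random_windows(rng, 6)
        positions = sorted(rng.choice(WINDOW_LENGTH, size=8, replace=False).tolist())
        ex = exact_shapley(predict, instance, backgrounds, positions)
        ke = kernel_shapley(predict, instance, backgrounds, n_samples=4096,
                            seed=1, positions=positions)
        assert np.abs(ex.values - ke.values).max() < 1e-8
        assert ke.base_value == pytest.approx(ex.base_value, abs=1e-12)


def test_kernel_sampling_branch(rng):
    """Sampled coalitions: efficiency still exact, values close to truth."""
    predict = nonlinear_fn(rng)
    instance = random_windows(rng, 1)[0]
    backgrounds = random_windows(rng, 5)
    positions = list(range(12))  # 4094 proper coalitions > budget
    ke = kernel_shapley(predict, instance, backgrounds, n_samples=2000,
                        seed=3, positions=positions)
    fx = float(predict([instance])[0])
    assert ke.values.sum() + ke.base_value == pytest.approx(fx, abs=1e-6)
    ex = exact_shapley(predict, instance, backgrounds, positions)
    assert np.abs(ex.values - ke.values).max() < 0.05
    # determinism
    ke2 = kernel_shapley(predict, instance, backgrounds, n_samples=2000,
                         seed=3, positions=positions)
    np.testing.assert_array_equal(ke.values, ke2.values)


def test_kernel_constant_position_zero(rng):
    instance = k_centered(rng, 1)[0]
    backgrounds = k_centered(rng, 8)
    predict = nonlinear_fn(rng)
    positions = [14, 15, HALF_WIDTH, 17, 18]
    ke = kernel_shapley(predict, instance, backgrounds, n_samples=4096,
                        seed=0, positions=positions)
    assert abs(ke.values[HALF_WIDTH]) < 1e-9


def test_kernel_sample_budget_error():
    with pytest.raises(ValueError, match="M\\+2"):
        kernel_shapley(lambda ws: np.zeros(len(ws)), "K" * 33, ["A" * 33], n_samples=10)


# --- structures ----------------------------------------------------------------

def _pdb_atom(serial, name, altloc, resname, chain, resseq, x, y, z, record="ATOM"):
    return (
        f"{record:<6s}{serial:5d} {name:^4s}{altloc:1s}{resname:3s} {chain:1s}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {name.strip()[0]:>2s}"
    )


def test_read_structure_ca_minimal(tmp_path):
    lines = [
        _pdb_atom(1, "CA", " ", "ALA", "A", 1, 0.0, 0.0, 0.0),
        _pdb_atom(2, "CA", " ", "LYS", "A", 2, 3.8, 0.0, 0.0),
        _pdb_atom(3, "CA", " ", "GLY", "A", 3, 7.6, 0.0, 0.0),
        "END",
    ]
    p = tmp_path / "mini.pdb"
    p.write_text("\n".join(lines) + "\n")
    coords = read_structure_ca(p, "A")
    assert sorted(coords) == [1, 2, 3]
    np.testing.assert_allclose(coords[2], [3.8, 0.0, 0.0])
    with pytest.raises(KeyError):
        read_structure_ca(p, "B")


def test_read_structure_altloc_first_kept(tmp_path):
    lines = [
        _pdb_atom(1, "CA", "A", "SER", "A", 1, 1.0, 0.0, 0.0),
        _pdb_atom(2, "CA", "B", "SER", "A", 1, 9.0, 0.0, 0.0),
        "END",
    ]
    p = tmp_path / "alt.pdb"
    p.write_text("\n".join(lines) + "\n")
    coords = read_structure_ca(p, "A")
    assert coords[1][0] == pytest.approx(1.0)


def test_read_structure_hetatm_only_error(tmp_path):
    lines = [_pdb_atom(1, "CA", " ", "CA ", "A", 1, 0.0, 0.0, 0.0, record="HETATM"), "END"]
    p = tmp_path / "het.pdb"
    p.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValueError, match="Cα|CA|no"):
        read_structure_ca(p, "A")


def test_window_distances_collinear():
    coords = {i: np.array([float(i), 0.0, 0.0]) for i in range(1, 101)}
    prof = window_distances(coords, 100, 50)
    assert prof.distances[HALF_WIDTH] == 0.0
    for k in range(1, 17):
        assert prof.distances[HALF_WIDTH + k] == pytest.approx(k)
        assert prof.distances[HALF_WIDTH - k] == pytest.approx(k)


def test_window_distances_boundary_and_missing():
    coords = {i: np.array([float(i), 0.0, 0.0]) for i in range(1, 21)}
    del coords[5]
    prof = window_distances(coords, 20, 10)
    assert np.isnan(prof.distances[0])  # offset 0 -> residue -6, out of range
    assert np.isnan(prof.distances[HALF_WIDTH - 5])  # residue 5 has no CA
    assert prof.distances[HALF_WIDTH + 1] == pytest.approx(1.0)


# --- aggregation ----------------------------------------------------------------

def _profile(values):
    return AttributionProfile(values=np.asarray(values, dtype=float), base_value=0.0)


def test_aggregate_by_position():
    zeros = [_profile(np.zeros(WINDOW_LENGTH))] * 3
    np.testing.assert_array_equal(aggregate_by_position(zeros), np.zeros(WINDOW_LENGTH))
    vals = np.linspace(-1, 1, WINDOW_LENGTH)
    single = [_profile(vals)]
    np.testing.assert_allclose(aggregate_by_position(single), np.abs(vals))


def test_aggregate_by_distance_bins():
    values = np.zeros(WINDOW_LENGTH)
    values[15] = 0.5
    values[17] = 0.3
    values[20] = 0.2
    values[HALF_WIDTH] = 9.9  # excluded target
    dist = np.full(WINDOW_LENGTH, np.nan)
    dist[15], dist[17], dist[20], dist[HALF_WIDTH] = 2.0, 3.0, 6.5, 0.0
    prof = _profile(values)
    from succinet.interpret import DistanceProfile

    bins = aggregate_by_distance([prof], [DistanceProfile(distances=dist)])
    assert set(bins) == {0, 1}  # [0,4) and [4,8); empty bins absent
    mean0, n0 = bins[0]
    assert n0 == 2 and mean0 == pytest.approx(0.4)
    mean1, n1 = bins[1]
    assert n1 == 1 and mean1 == pytest.approx(0.2)


def test_aggregate_single_bin_equals_grand_mean():
    values = np.abs(np.linspace(-1, 1, WINDOW_LENGTH))
    dist = np.full(WINDOW_LENGTH, 1.5)
    dist[HALF_WIDTH] = 0.0
    from succinet.interpret import DistanceProfile

    bins = aggregate_by_distance([_profile(values)], [DistanceProfile(distances=dist)])
    others = [values[i] for i in range(WINDOW_LENGTH) if i != HALF_WIDTH]
    assert set(bins) == {0}
    assert bins[0][0] == pytest.approx(np.mean(others))
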