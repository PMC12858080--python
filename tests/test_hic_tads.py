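"""Hi-C map handling, power-law fitting, Bernoulli networks, scaling fits,
and the synthetic-map generator that supplies known ground truth."""

import numpy as np
import pytest

from tadwalk import (
    ContactModel,
    HiCContactMap,
    SyntheticMapSpec,
    TADRecord,
    WalkerParams,
    build_hic_network,
    ensemble_search_time,
    fit_power_law,
    fit_scaling_exponent,
    generate_map,
    intra_tad_contact_curve,
    mean_quenched,
    probability_scale,
    read_tads_bed,
)


def toy_map(values, scaled=False):
    return HiCContactMap(
        values=np.asarray(values, dtype=float),
        normalisation="probability" if scaled else "raw",
    )


# ---------------------------------------------------------------------------
# probability scaling
# ---------------------------------------------------------------------------


def test_probability_scale_max_offdiagonal_becomes_one():
    vals = np.array([[9.0, 2.0, 4.0], [2.0, 9.0, 1.0], [4.0, 1.0, 9.0]])
    scaled = probability_scale(toy_map(vals))
    off = scaled.values.copy()
    np.fill_diagonal(off, 0.0)
    assert off.max() == 1.0
    assert scaled.values[0, 2] == 1.0  # the former maximum
    assert scaled.scaled


def test_probability_scale_idempotent():
    vals = np.abs(np.random.default_rng(0).random((6, 6)))
    vals = vals + vals.T
    once = probability_scale(toy_map(vals))
    twice = probability_scale(once)
    assert np.allclose(once.values, twice.values)


def test_probability_scale_all_zero_errors():
    with pytest.raises(ValueError):
        probability_scale(toy_map(np.zeros((4, 4))))


# ---------------------------------------------------------------------------
# intra-TAD contact curves
# ---------------------------------------------------------------------------


def test_constant_map_gives_flat_curve():
    hic = toy_map(np.full((10, 10), 0.3), scaled=True)
    s, pc = intra_tad_contact_curve(hic, TADRecord("chr1", 0, 10_000))
    assert np.allclose(pc, 0.3)


def test_four_bin_tad_hand_enumeration():
    vals = np.zeros((8, 8))
    block = np.array(
        [
            [1.0, 0.5, 0.2, 0.1],
            [0.5, 1.0, 0.4, 0.3],
            [0.2, 0.4, 1.0, 0.6],
            [0.1, 0.3, 0.6, 1.0],
        ]
    )
    vals[2:6, 2:6] = block
    hic = toy_map(vals, scaled=True)
    tad = TADRecord("chr1", 2000, 6000)
    s, pc = intra_tad_contact_curve(hic, tad)
    # independent enumeration over pairs inside the block
    for sep in (1, 2, 3):
        pairs = [block[i, i + sep] for i in range(4 - sep)]
        assert pc[sep - 1] == pytest.approx(np.mean(pairs))


def test_tad_outside_map_errors():
    hic = toy_map(np.ones((10, 10)), scaled=True)
    with pytest.raises(ValueError):
        intra_tad_contact_curve(hic, TADRecord("chr1", 5000, 20_000))


# ---------------------------------------------------------------------------
# power-law fits
# ---------------------------------------------------------------------------


def test_fit_exact_power_law():
    s = np.arange(1, 300)
    pc = 0.02 * s**-0.8
    fit = fit_power_law(s, pc)
    assert fit.c == pytest.approx(0.02, rel=1e-10)
    assert fit.gamma == pytest.approx(0.8, rel=1e-10)
    assert fit.r_squared == pytest.approx(1.0)


def test_fit_flat_curve_zero_gamma():
    s = np.arange(1, 300)
    fit = fit_power_law(s, np.full(299, 0.05))
    assert fit.gamma == pytest.approx(0.0, abs=1e-12)


def test_fit_excludes_nonpositive_and_errors_when_starved():
    s = np.arange(1, 300)
    pc = 0.02 * s**-0.8
    pc[50:60] = 0.0
    with pytest.warns(UserWarning):
        fit = fit_power_law(s, pc)
    assert fit.gamma == pytest.approx(0.8, rel=1e-6)
    with pytest.raises(ValueError):
        fit_power_law(s[:5], pc[:5], s_min=1, s_max=3)


def test_fit_range_empty_for_short_domains():
    # the default range [10, L-100] is empty for domains up to 110 kb
    s = np.arange(1, 100)
    with pytest.raises(ValueError):
        fit_power_law(s, 0.02 * s**-0.7)


def test_fit_bias_under_lognormal_noise():
    rng = np.random.default_rng(0)
    s = np.arange(1, 300)
    gammas = [
        fit_power_law(s, 0.0214 * s**-0.71 * np.exp(0.2 * rng.standard_normal(299))).gamma
        for _ in range(30)
    ]
    assert abs(np.mean(gammas) - 0.71) < 0.05


# ---------------------------------------------------------------------------
# Bernoulli Hi-C networks
# ---------------------------------------------------------------------------


def test_build_network_extremes():
    ones = toy_map(np.ones((12, 12)), scaled=True)
    tad = TADRecord("chr1", 0, 12_000)
    full = build_hic_network(ones, tad, 0, insulate_boundaries=False)
    n = 12
    assert full.adj.sum() == n * (n - 1)  # complete graph
    insulated = build_hic_network(ones, tad, 0)
    assert insulated.adj[0, 2:].sum() == 0

    zeros = toy_map(np.zeros((12, 12)), scaled=True)
    chain = build_hic_network(zeros, tad, 0)
    assert chain.adj.sum() == 2 * (n - 1)


def test_build_network_requires_scaled_map():
    with pytest.raises(ValueError):
        build_hic_network(toy_map(np.ones((6, 6))), TADRecord("c", 0, 6000), 0)


def test_build_network_edge_frequency():
    rng = np.random.default_rng(1)
    vals = rng.random((10, 10)) * 0.5
    vals = np.triu(vals, 1) + np.triu(vals, 1).T
    hic = toy_map(vals, scaled=True)
    tad = TADRecord("chr1", 0, 10_000)
    acc = np.zeros((10, 10))
    n_draws = 10_000
    for seed in range(n_draws):
        acc += build_hic_network(hic, tad, seed, insulate_boundaries=False).adj
    for i in range(10):
        for j in range(i + 2, 10):
            p = vals[i, j]
            se = np.sqrt(p * (1 - p) / n_draws)
            assert abs(acc[i, j] / n_draws - p) < 3 * se + 1e-3


# ---------------------------------------------------------------------------
# scaling fits
# ---------------------------------------------------------------------------


def test_scaling_exponent_exact_laws():
    L = np.array([100, 200, 400, 800])
    assert fit_scaling_exponent(L, 0.25 * L**2.0).nu == pytest.approx(2.0, abs=1e-12)
    assert fit_scaling_exponent(L, 3.0 * L**1.0).nu == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        fit_scaling_exponent(L[:3], L[:3] ** 2.0)
    with pytest.raises(ValueError):
        fit_scaling_exponent(L, np.array([1.0, -1.0, 1.0, 1.0]))


# ---------------------------------------------------------------------------
# synthetic maps
# ---------------------------------------------------------------------------


def test_synthetic_spec_validation():
    with pytest.raises(ValueError):
        SyntheticMapSpec(n_bins=100, tads=((0, 50_000), (40_000, 90_000)))
    with pytest.raises(ValueError):
        SyntheticMapSpec(n_bins=10, tads=((0, 50_000),))


def test_synthetic_noiseless_curve_is_exact():
    spec = SyntheticMapSpec(n_bins=400, tads=((50_000, 350_000),), sigma_log=0.0)
    hic, tads = generate_map(spec, 0)
    s, pc = intra_tad_contact_curve(hic, tads[0])
    expected = np.minimum(1.0, 0.0214 * s.astype(float) ** -0.71)
    assert np.allclose(pc, expected, rtol=1e-12)
    fit = fit_power_law(s, pc)
    assert fit.c == pytest.approx(0.0214, rel=1e-9)
    assert fit.gamma == pytest.approx(0.71, rel=1e-9)


def test_synthetic_map_is_valid_probability_map():
    spec = SyntheticMapSpec(n_bins=200, tads=((0, 200_000),), sigma_log=0.5)
    hic, _ = generate_map(spec, 3)
    assert np.array_equal(hic.values, hic.values.T)
    assert hic.values.max() <= 1.0
    assert hic.values.min() >= 0.0
    scaled = probability_scale(hic)
    off = scaled.values.copy()
    np.fill_diagonal(off, 0.0)
    assert off.max() == pytest.approx(1.0)


def test_synthetic_two_tads_ordered_gammas():
    spec = SyntheticMapSpec(
        n_bins=500,
        tads=((0, 200_000), (250_000, 450_000)),
        tad_params=((0.0214, 0.4), (0.0214, 1.0)),
        sigma_log=0.1,
    )
    hic, tads = generate_map(spec, 5)
    fits = [fit_power_law(*intra_tad_contact_curve(hic, t)) for t in tads]
    assert fits[0].gamma < fits[1].gamma


@pytest.mark.parametrize("gamma_true", [0.3, 0.71, 1.5])
def test_round_trip_gamma_recovery(gamma_true):
    """Generator -> curve -> fit recovers gamma within 0.05 under noise."""
    gammas = []
    for rep in range(30):
        spec = SyntheticMapSpec(
            n_bins=320,
            tads=((10_000, 310_000),),
            tad_params=((0.0214, gamma_true),),
            sigma_log=0.2,
        )
        hic, tads = generate_map(spec, 1000 + rep)
        s, pc = intra_tad_contact_curve(hic, tads[0])
        gammas.append(fit_power_law(s, pc).gamma)
    assert abs(np.mean(gammas) - gamma_true) < 0.05


def test_method1_and_method2_search_times_agree():
    """Solver on fitted (c, gamma) vs walks on Bernoulli map networks.

    With matched parameters the two routes estimate the same ensemble mean;
    agreement asserted within 10% using 100 configurations each.
    """
    spec = SyntheticMapSpec(n_bins=300, tads=((0, 300_000),), sigma_log=0.0)
    hic, tads = generate_map(spec, 1)
    s, pc = intra_tad_contact_curve(hic, tads[0])
    fit = fit_power_law(s, pc)
    model = ContactModel.powerlaw(fit.c, fit.gamma)
    m1 = mean_quenched(model, 299, WalkerParams(), 100, 5)

    rng = np.random.default_rng(9)
    times = []
    for _ in range(100):
        C = build_hic_network(hic, tads[0], int(rng.integers(0, 2**31 - 1)))
        est = ensemble_search_time(
            ContactModel.uniform(0.0),
            C.L,
            WalkerParams(),
            1,
            300,
            int(rng.integers(0, 2**31 - 1)),
            C=C,
        )
        times.append(est.mean)
    m2 = np.mean(times)
    assert m2 == pytest.approx(m1.mean, rel=0.10)


def test_read_tads_bed(tmp_path):
    bed = tmp_path / "tads.bed"
    bed.write_text("chr1\t0\t100000\nchr2\t5000\t65000\n")
    tads = read_tads_bed(bed)
    assert len(tads) == 2
    assert tads[0].L_kb == 100
    assert tads[1].chrom == "chr2"
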