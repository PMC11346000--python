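"""DNA gate, QC rates, percentile cutoffs, HDR, AreaX and positivity."""

import numpy as np
import pytest
from scipy.stats import chi2

from ki67flow.gating import (
    DnaGate,
    EllipseGate,
    GateInfeasibleError,
    apply_gate,
    ck_gate,
    dna_partition,
    find_2n_peak,
    fit_areax,
    ki67_positivity,
    main_population,
    percentile_cutoff,
    positivity,
    qc_rates,
)
from ki67flow.simulate import (
    default_tumor_populations,
    simulate_pair,
    uniform_background_pair_spec,
)

# ---------------------------------------------------------------------------
# 2n peak and DNA partition


def test_find_2n_peak_in_mixture(make_event_table):
    """2n Gaussian at 100 (70%), 4n at 200 (10%), sub-2n debris (20%)."""
    rng = np.random.default_rng(1)
    dna = np.concatenate([
        rng.normal(100, 5, 7000),
        rng.normal(200, 20, 1000),
        rng.uniform(5, 80, 2000),
    ])
    table = make_event_table({"DNA": dna})
    assert 95 <= find_2n_peak(table) <= 105


def test_find_2n_peak_unimodal(make_event_table):
    rng = np.random.default_rng(2)
    table = make_event_table({"DNA": rng.normal(50, 2, 5000)})
    assert abs(find_2n_peak(table) - 50) < 2


def test_find_2n_peak_degenerate_warns(make_event_table):
    table = make_event_table({"DNA": [42.0] * 200})
    with pytest.warns(UserWarning, match="degenerate"):
        assert find_2n_peak(table) == 42.0


def test_dna_partition_window_bounds(make_event_table):
    table = make_event_table({"DNA": [50.0, 90.0, 100.0, 130.0, 250.0]})
    part = dna_partition(table, DnaGate(peak_2n=100, window_fraction=0.2))
    assert list(table.channel("DNA")[part.below_2n]) == [50.0]
    assert list(table.channel("DNA")[part.at_2n]) == [90.0, 100.0]
    assert list(table.channel("DNA")[part.above_2n]) == [130.0, 250.0]
    # exhaustive + disjoint
    total = part.below_2n.astype(int) + part.at_2n.astype(int) \
        + part.above_2n.astype(int)
    assert (total == 1).all()


def test_dna_partition_uniform_closed_form(make_event_table):
    """Uniform DNA on [0, 200]: partition fractions match the analytic split."""
    rng = np.random.default_rng(3)
    n = 100_000
    table = make_event_table({"DNA": rng.uniform(0, 200, n)})
    part = dna_partition(table, DnaGate(100, 0.2))
    np.testing.assert_allclose(part.below_2n.mean(), 0.40, atol=0.01)
    np.testing.assert_allclose(part.at_2n.mean(), 0.20, atol=0.01)
    np.testing.assert_allclose(part.above_2n.mean(), 0.40, atol=0.01)


def test_qc_rates_printed_formulas(make_event_table):
    dna = [50.0] * 200 + [100.0] * 600 + [250.0] * 200
    part = dna_partition(make_event_table({"DNA": dna}), DnaGate(100, 0.2))
    rates = qc_rates(part)
    assert rates.cell_recovery_rate == 60.0
    np.testing.assert_allclose(rates.debris_rate, 200 / 600)
    assert rates.single_cell_rate == 75.0


def test_qc_rates_integer_identities(make_event_table):
    rng = np.random.default_rng(4)
    dna = rng.uniform(10, 400, 5000)
    part = dna_partition(make_event_table({"DNA": dna}), DnaGate(100, 0.2))
    rates = qc_rates(part)
    n_b, n_a, n_o = (int(m.sum()) for m in
                     (part.below_2n, part.at_2n, part.above_2n))
    np.testing.assert_allclose(rates.cell_recovery_rate * (n_b + n_a + n_o),
                               100 * n_a)
    np.testing.assert_allclose(rates.debris_rate * n_a, n_b)
    np.testing.assert_allclose(rates.single_cell_rate * (n_a + n_o), 100 * n_a)


def test_qc_rates_zero_denominators(make_event_table):
    part = dna_partition(make_event_table({"DNA": [10.0, 20.0]}), DnaGate(100, 0.2))
    with pytest.raises(ValueError, match="debris_rate undefined"):
        qc_rates(part)


def test_qc_no_debris_gives_zero_rate(make_event_table):
    part = dna_partition(make_event_table({"DNA": [100.0] * 10}), DnaGate(100, 0.2))
    assert qc_rates(part).debris_rate == 0.0


# ---------------------------------------------------------------------------
# Percentile cutoffs and positivity


def test_percentile_linear_interpolation(make_event_table):
    control = make_event_table({"KI67": np.arange(1.0, 101.0)},
                               stain="isotype_control")
    cut = percentile_cutoff(control, "KI67", q=95)
    np.testing.assert_allclose(cut.threshold, 95.05)
    control3 = make_event_table({"KI67": [1.0, 2.0, 3.0]},
                                stain="isotype_control")
    assert percentile_cutoff(control3, "KI67", q=50).threshold == 2.0


def test_cutoff_requires_isotype_control(make_event_table):
    stained = make_event_table({"KI67": [1.0, 2.0]}, stain="antibody")
    with pytest.raises(ValueError, match="isotype control"):
        percentile_cutoff(stained, "KI67")


def test_positivity_direct_ratio(make_event_table):
    values = np.concatenate([np.full(700, 1.0), np.full(300, 10.0)])
    table = make_event_table({"KI67": values})
    control = make_event_table({"KI67": [5.0] * 10}, stain="isotype_control")
    cut = percentile_cutoff(control, "KI67", q=95)
    assert positivity(table, cut) == 30.0


def test_positivity_strict_inequality(make_event_table):
    table = make_event_table({"KI67": [5.0, 5.0, 6.0, 4.0]})
    control = make_event_table({"KI67": [5.0] * 10}, stain="isotype_control")
    cut = percentile_cutoff(control, "KI67", q=95)
    assert positivity(table, cut) == 25.0  # boundary events are negative


def test_positivity_empty_gate_raises(make_event_table):
    table = make_event_table({"KI67": [1.0, 2.0]})
    control = make_event_table({"KI67": [1.0, 2.0]}, stain="isotype_control")
    cut = percentile_cutoff(control, "KI67")
    with pytest.raises(ValueError, match="empty"):
        positivity(table, cut, mask=np.zeros(2, dtype=bool))


def test_percentile_self_consistency_property():
    """Control self-positivity never exceeds (100-q)% + 1/n."""
    rng = np.random.default_rng(5)
    for n in (37, 500, 10_000):
        values = rng.lognormal(2.0, 0.6, n)
        thr = np.percentile(values, 95)
        assert np.mean(values > thr) <= 0.05 + 1.0 / n


def test_ck_gate_separates_populations(tumor_pair):
    pair, truth = tumor_pair
    gate = DnaGate(find_2n_peak(pair.stained))
    mask = ck_gate(pair, gate)
    part = dna_partition(pair.stained, gate)
    cancer = (truth.population == "cancer").to_numpy() & part.analysis
    lymph = (truth.population == "lymphocyte").to_numpy() & part.analysis
    assert mask[cancer].mean() >= 0.99
    # lymphocyte CK is background, so ~5% sit above the 95th-percentile
    # cutoff by construction; allow 3 binomial SDs on top
    n_lymph = lymph.sum()
    assert mask[lymph].mean() <= 0.05 + 3 * np.sqrt(2 * 0.05 * 0.95 / n_lymph)


def test_ck_gate_on_control_pair_retains_about_5pct():
    """A 'stained' sample that is itself background retains ~5% after CK gating."""
    pair, _ = simulate_pair(uniform_background_pair_spec(0.0), 50_000, seed=6)
    # replace stained CK by background: use the control twin as both members
    from ki67flow.io import EventTable, SamplePair
    fake = EventTable(pair.control.data.copy(), dict(pair.control.channel_map),
                      sample_id="fake", stain="antibody")
    pair2 = SamplePair(fake, pair.control, pair_id="ctrl-twin")
    gate = DnaGate(find_2n_peak(pair2.stained))
    mask = ck_gate(pair2, gate)
    analysis = dna_partition(pair2.stained, gate).analysis
    assert abs(mask.sum() / analysis.sum() - 0.05) < 0.01


# ---------------------------------------------------------------------------
# Highest-density region


def test_hdr_gaussian_matches_chi2_contour():
    rng = np.random.default_rng(7)
    pts = rng.standard_normal((100_000, 2))
    hdr = main_population(pts, mass=0.40)
    expected_area = np.pi * chi2.ppf(0.40, df=2)  # |Sigma| = 1
    assert abs(hdr.area / expected_area - 1) < 0.10
    assert abs(hdr.covered_fraction - 0.40) < 0.01


def test_hdr_nesting():
    rng = np.random.default_rng(8)
    pts = rng.standard_normal((20_000, 2)) * [3, 1] + [5, 5]
    prev = None
    for mass in (0.2, 0.4, 0.6, 0.8):
        hdr = main_population(pts, mass=mass)
        if prev is not None:
            assert not (prev.cells & ~hdr.cells).any()
        prev = hdr


def test_hdr_mass_limit_covers_almost_everything():
    rng = np.random.default_rng(9)
    pts = rng.standard_normal((5_000, 2))
    hdr = main_population(pts, mass=0.999)
    assert hdr.covered_fraction >= 0.999


def test_hdr_splits_across_two_equal_modes():
    rng = np.random.default_rng(10)
    pts = np.vstack([rng.standard_normal((10_000, 2)),
                     rng.standard_normal((10_000, 2)) + [10, 10]])
    hdr = main_population(pts, mass=0.40)
    centers = hdr.cell_centers()
    assert (centers[:, 0] < 5).any() and (centers[:, 0] > 5).any()


def test_hdr_matches_bruteforce_density_ranking():
    """Greedy accumulation equals a naive reimplementation on a tiny grid."""
    rng = np.random.default_rng(12)
    pts = rng.normal(5, 1, (600, 2))
    hdr = main_population(pts, mass=0.4, grid_size=16, min_events=1)

    # naive: same histogram, same smoothing, explicit sort + accumulate loop
    counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1],
                                  bins=[hdr.x_edges, hdr.y_edges])
    from scipy import ndimage
    sig = [pts[:, k].std(ddof=1) * len(pts) ** (-1 / 6)
           / np.diff(e)[0] for k, e in ((0, hdr.x_edges), (1, hdr.y_edges))]
    dens = ndimage.gaussian_filter(counts, sigma=sig, mode="constant")
    flat = sorted(range(dens.size), key=lambda i: (-dens.ravel()[i], i))
    acc, chosen = 0.0, np.zeros(dens.size, dtype=bool)
    for i in flat:
        chosen[i] = True
        acc += counts.ravel()[i]
        if acc >= 0.4 * len(pts):
            break
    np.testing.assert_array_equal(hdr.cells, chosen.reshape(dens.shape))


def test_hdr_rejects_bad_mass():
    with pytest.raises(ValueError, match="mass"):
        main_population(np.zeros((10, 2)), mass=1.5)


# ---------------------------------------------------------------------------
# Ellipse gate


def test_ellipse_membership_against_geometric_oracle():
    gate = EllipseGate(center=(3.0, -1.0), semi_axes=(2.0, 0.5), angle=0.7)
    rng = np.random.default_rng(13)
    pts = rng.uniform(-5, 10, (2_000, 2))
    got = gate.contains(pts)
    c, s = np.cos(0.7), np.sin(0.7)
    expected = []
    for x, y in pts:
        dx, dy = x - 3.0, y + 1.0
        u = dx * c + dy * s
        v = -dx * s + dy * c
        expected.append((u / 2.0) ** 2 + (v / 0.5) ** 2 <= 1 + 1e-12)
    np.testing.assert_array_equal(got, np.array(expected))


def test_ellipse_center_and_boundary_are_members():
    gate = EllipseGate(center=(0.0, 0.0), semi_axes=(2.0, 1.0), angle=0.0)
    assert gate.contains([[0.0, 0.0]])[0]
    assert gate.contains([[2.0, 0.0]])[0]  # closed gate: boundary included


def test_ellipse_yaml_round_trip(tmp_path):
    gate = EllipseGate(center=(1.0, 2.0), semi_axes=(3.0, 4.0), angle=0.5,
                       provenance={"mass": 0.4})
    gate.save(tmp_path / "g.yaml")
    back = EllipseGate.load(tmp_path / "g.yaml")
    assert back == gate


def test_fit_areax_separated_blobs():
    rng = np.random.default_rng(14)
    pos = rng.multivariate_normal([600, 500], [[6400, 2800], [2800, 4900]], 20_000)
    neg = rng.multivariate_normal([200, 150], [[1600, 400], [400, 1225]], 20_000)
    gate = fit_areax(pos, neg)
    assert gate.contains(pos).mean() >= 0.95
    assert gate.contains(neg).mean() <= 0.01


def test_fit_areax_excludes_negative_hdr_by_construction():
    rng = np.random.default_rng(15)
    pos = rng.normal(600, 60, (20_000, 2))
    neg = rng.normal(350, 50, (20_000, 2))  # close: forces a shrink
    gate = fit_areax(pos, neg)
    neg_hdr = main_population(neg, mass=0.40)
    assert not gate.contains(neg_hdr.cell_centers()).any()


def test_fit_areax_infeasible_for_identical_distributions():
    rng = np.random.default_rng(16)
    pos = rng.normal(400, 50, (10_000, 2))
    neg = rng.normal(400, 50, (10_000, 2))
    with pytest.raises(GateInfeasibleError, match="inseparable"):
        fit_areax(pos, neg)


def test_fit_areax_without_negatives_keeps_base_level():
    rng = np.random.default_rng(17)
    pos = rng.normal(500, 40, (10_000, 2))
    gate_alone = fit_areax(pos, None)
    far_neg = np.full((100, 2), 5_000.0) + rng.normal(0, 10, (100, 2))
    gate_vacuous = fit_areax(pos, far_neg)
    np.testing.assert_allclose(gate_alone.semi_axes, gate_vacuous.semi_axes,
                               rtol=1e-9)


def test_apply_gate_matches_contains(tumor_pair):
    pair, _ = tumor_pair
    gate = EllipseGate(center=(600, 500), semi_axes=(300, 250), angle=0.2)
    np.testing.assert_array_equal(apply_gate(pair.stained, gate),
                                  gate.contains(pair.stained.scatter()))


# ---------------------------------------------------------------------------
# End-to-end positivity


def test_pure_control_pair_positivity_near_5pct():
    pair, _ = simulate_pair(uniform_background_pair_spec(0.0), 100_000, seed=18)
    res = ki67_positivity(pair, scheme="dapi_only")
    assert abs(res.positivity - 5.0) < 0.5


def test_mixture_positivity_follows_cutoff_algebra():
    """True fraction p with control-matched negatives: 100(p + .05(1-p))."""
    p = 0.30
    pair, _ = simulate_pair(uniform_background_pair_spec(p), 100_000, seed=19)
    res = ki67_positivity(pair, scheme="dapi_only")
    expected = 100 * (p + 0.05 * (1 - p))
    q = expected / 100
    tol = 3 * 100 * np.sqrt(2 * q * (1 - q) / 100_000)
    assert abs(res.positivity - expected) < tol


def test_scheme_gate_chains_log_counts(tumor_pair):
    pair, _ = tumor_pair
    res = ki67_positivity(pair, scheme="areax")
    counts = res.stage_counts
    assert counts["total"] >= counts["dna_gate"] >= counts["areax_gate"]
    assert counts["ki67_positive"] <= counts["areax_gate"]
    assert res.gates.ki67_cutoff is not None


def test_missing_scheme_rejected(tumor_pair):
    pair, _ = tumor_pair
    with pytest.raises(ValueError, match="unknown scheme"):
        ki67_positivity(pair, scheme="magic")
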