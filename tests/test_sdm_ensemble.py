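"""Occurrence thinning, member models, evaluation metrics, ensembling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gapscape import sdm_ensemble as se
from gapscape.core_io import Grid


# ---------------------------------------------------------------------------
# thinning
# ---------------------------------------------------------------------------

def test_coincident_points_collapse_to_one():
    occ = se.OccurrenceSet("sp", [[0, 0], [0, 0]])
    assert len(se.thin_occurrences(occ, 1.0, seed=0).points) == 1


def test_distant_points_both_kept():
    occ = se.OccurrenceSet("sp", [[0, 0], [5000, 0]])
    assert len(se.thin_occurrences(occ, 1.0, seed=0).points) == 2


def test_thinning_pairwise_separation_oracle():
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 3000, size=(100, 2))
    out = se.thin_occurrences(se.OccurrenceSet("sp", pts), 1.0, seed=4).points
    for i in range(len(out)):
        for j in range(i + 1, len(out)):
            assert np.hypot(*(out[i] - out[j])) >= 1000.0
    # seed-reproducible
    again = se.thin_occurrences(se.OccurrenceSet("sp", pts), 1.0, seed=4).points
    np.testing.assert_array_equal(out, again)


def test_empty_input_warns():
    with pytest.warns(UserWarning, match="empty"):
        out = se.thin_occurrences(se.OccurrenceSet("sp", np.empty((0, 2))))
    assert len(out.points) == 0


# ---------------------------------------------------------------------------
# predictor filtering
# ---------------------------------------------------------------------------

def layers_from(arrays):
    return [Grid(values=np.asarray(a, dtype=float)) for a in arrays]


def test_identical_layers_one_dropped():
    rng = np.random.default_rng(1)
    a = rng.standard_normal((10, 10))
    kept, idx = se.filter_predictors(layers_from([a, a.copy()]),
                                     np.empty((0, 2)))
    assert len(kept) == 1


def test_sign_flipped_duplicate_dropped():
    rng = np.random.default_rng(2)
    a = rng.standard_normal((10, 10))
    kept, idx = se.filter_predictors(layers_from([a, -a]), np.empty((0, 2)))
    assert len(kept) == 1


def test_independent_layers_all_kept():
    rng = np.random.default_rng(3)
    arrays = [rng.standard_normal((30, 30)) for _ in range(4)]
    kept, idx = se.filter_predictors(layers_from(arrays), np.empty((0, 2)))
    data = np.column_stack([a.ravel() for a in arrays])
    R = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(R, 0)
    assert np.abs(R).max() < 0.8   # oracle: genuinely uncorrelated
    assert len(kept) == 4


def test_single_layer_returned_unchanged():
    g = Grid(values=np.zeros((5, 5)))
    kept, idx = se.filter_predictors([g], np.empty((0, 2)))
    assert kept == [g]


# ---------------------------------------------------------------------------
# background sampling
# ---------------------------------------------------------------------------

def test_background_seed_reproducible(small_geom):
    a = se.sample_background(small_geom, 50, seed=9)
    b = se.sample_background(small_geom, 50, seed=9)
    np.testing.assert_array_equal(a, b)


def test_background_respects_exclusion(small_geom):
    cells = np.array([[r, c] for r in range(20) for c in range(20)])
    keep = cells[:5]
    excl = cells[5:]
    out = se.sample_background(small_geom, 5, seed=0, exclude_cells=excl)
    assert {tuple(x) for x in out} == {tuple(x) for x in keep}


def test_background_overdraw_errors(small_geom):
    with pytest.raises(ValueError, match="available"):
        se.sample_background(small_geom, 10**6, seed=0)


def test_background_uniformity_chisquare(small_geom):
    from scipy import stats
    counts = np.zeros(400)
    for s in range(100):
        cells = se.sample_background(small_geom, 100, seed=s)
        np.add.at(counts, cells[:, 0] * 20 + cells[:, 1], 1)
    _, p = stats.chisquare(counts)
    assert p > 0.01


# ---------------------------------------------------------------------------
# member models
# ---------------------------------------------------------------------------

def test_envelope_scores_by_layer_membership():
    rng = np.random.default_rng(5)
    layers = layers_from([rng.uniform(0, 1, (20, 20)) for _ in range(3)])
    pres = np.column_stack([rng.integers(5, 15, 30), rng.integers(5, 15, 30)])
    pred = se.fit_envelope(pres, layers).values
    assert pred.min() >= 0 and pred.max() <= 1
    # score granularity is multiples of 1/3
    assert set(np.round(np.unique(pred) * 3, 9) % 1) == {0.0}


def test_envelope_centroid_scores_one():
    vals = np.linspace(0, 1, 400).reshape(20, 20)
    layers = layers_from([vals, vals.T])
    pres = np.array([[9, 9], [10, 10], [9, 10], [10, 9], [11, 11]])
    pred = se.fit_envelope(pres, layers).values
    assert pred[10, 10] == pytest.approx(1.0)
    assert pred[0, 19] == pytest.approx(0.0)   # outside both envelopes


def test_envelope_needs_five_points():
    layers = layers_from([np.zeros((10, 10))])
    with pytest.raises(ValueError, match="5"):
        se.fit_envelope(np.array([[1, 1]]), layers)


def test_logistic_separates_informative_layer():
    rng = np.random.default_rng(6)
    grad = np.tile(np.linspace(-2, 2, 40), (40, 1))
    layers = layers_from([grad])
    pres = np.column_stack([rng.integers(0, 40, 40), rng.integers(30, 40, 40)])
    bg = np.column_stack([rng.integers(0, 40, 200), rng.integers(0, 25, 200)])
    pred = se.fit_logistic(pres, bg, layers)
    ev = se.evaluate(pred, pres, bg)
    assert ev.auc > 0.95


def test_logistic_shuffled_labels_auc_near_half():
    rng = np.random.default_rng(7)
    grad = np.tile(np.linspace(-2, 2, 40), (40, 1))
    layers = layers_from([grad, grad.T])
    aucs = []
    for s in range(20):
        r = np.random.default_rng(s)
        allc = np.column_stack([r.integers(0, 40, 360), r.integers(0, 40, 360)])
        pres, bg, te_p, te_b = allc[:40], allc[40:240], allc[240:280], allc[280:]
        pred = se.fit_logistic(pres, bg, layers)
        aucs.append(se.evaluate(pred, te_p, te_b).auc)  # held-out labels
    assert abs(np.mean(aucs) - 0.5) < 0.07


def test_logistic_heavy_penalty_flattens_predictions():
    rng = np.random.default_rng(8)
    grad = np.tile(np.linspace(-2, 2, 30), (30, 1))
    layers = layers_from([grad])
    pres = np.column_stack([rng.integers(0, 30, 30), rng.integers(20, 30, 30)])
    bg = np.column_stack([rng.integers(0, 30, 90), rng.integers(0, 15, 90)])
    pred = se.fit_logistic(pres, bg, layers, l2=1e6).values
    prevalence = 30 / 120
    assert np.all(np.abs(pred - prevalence) < 0.05)


def test_logistic_complete_separation_errors_without_penalty():
    grad = np.tile(np.linspace(-2, 2, 30), (30, 1))
    layers = layers_from([grad])
    pres = np.column_stack([np.arange(10), np.full(10, 29)])
    bg = np.column_stack([np.arange(10), np.full(10, 0)])
    with pytest.raises(ValueError, match="l2 > 0"):
        se.fit_logistic(pres, bg, layers, l2=0.0)


def test_external_prediction_validation(small_geom):
    ok = small_geom.like(np.full((20, 20), 0.5))
    m = se.load_external_prediction(ok, "RF", small_geom, tss_claim=0.9)
    assert m.tss == 0.9
    with pytest.raises(ValueError, match="outside"):
        se.load_external_prediction(small_geom.like(np.full((20, 20), 1.2)),
                                    "RF", small_geom)
    with pytest.raises(ValueError, match="misaligned"):
        se.load_external_prediction(Grid(values=np.zeros((5, 5))),
                                    "RF", small_geom)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

def test_perfect_separation_metrics():
    ev = se.evaluate_scores([0.9, 0.8], [0.1, 0.2])
    assert (ev.auc, ev.tss, ev.kappa) == (1.0, 1.0, 1.0)


def test_constant_scores_are_uninformative():
    ev = se.evaluate_scores([0.5, 0.5], [0.5, 0.5])
    assert ev.auc == 0.5
    assert ev.tss == pytest.approx(0.0)


def test_six_point_toy_set_matches_enumeration():
    """AUC = 8/9 (8 of 9 rank pairs won) and max TSS = 2/3."""
    pres = [0.9, 0.8, 0.6]
    bg = [0.7, 0.3, 0.2]
    ev = se.evaluate_scores(pres, bg)
    assert ev.auc == pytest.approx(8 / 9)
    assert ev.tss == pytest.approx(2 / 3)
    # exhaustive check over every candidate threshold
    best = max(np.mean(np.asarray(pres) >= t) + np.mean(np.asarray(bg) < t) - 1
               for t in np.r_[pres, bg])
    assert best == pytest.approx(ev.tss)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=20),
       st.lists(st.floats(0.01, 0.99), min_size=2, max_size=20))
def test_auc_invariant_under_monotone_transform(pres, bg):
    a1 = se.evaluate_scores(pres, bg).auc
    f = lambda x: np.exp(3 * np.asarray(x))  # strictly increasing
    a2 = se.evaluate_scores(f(pres), f(bg)).auc
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_empty_test_set_errors():
    with pytest.raises(ValueError, match="non-empty"):
        se.evaluate_scores([], [0.5])


# ---------------------------------------------------------------------------
# ensemble weighting and stacking
# ---------------------------------------------------------------------------

def test_tss_proportional_weights():
    tss = np.array([0.9, 0.85])
    w = tss / tss.sum()
    np.testing.assert_allclose(w, [18 / 35, 17 / 35])
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


def make_surface(geom, high):
    z = np.zeros(geom.shape)
    return se.SuitabilitySurface(
        species="s", p_ens=geom.like(z), binary=geom.like(z > 0),
        classes=geom.like(z.astype(np.int32)), high_mask=geom.like(high),
        threshold=0.5, evaluation=se.ModelEvaluation(1, 1, 1, 0.5))


def test_stack_richness_counts_and_classes(small_geom):
    rng = np.random.default_rng(11)
    masks = [rng.random((20, 20)) < 0.5 for _ in range(10)]
    surfaces = [make_surface(small_geom, m) for m in masks]
    out = se.stack_richness(surfaces)
    brute = sum(m.astype(int) for m in masks)
    np.testing.assert_array_equal(out["richness"].values, brute)
    cls = out["classes"].values
    assert (cls[brute == 0] == 0).all()
    assert (cls[(brute >= 1) & (brute <= 2)] == 1).all()
    assert (cls[(brute >= 7)] == 4).all()


def test_stack_richness_all_high_everywhere(small_geom):
    surfaces = [make_surface(small_geom, np.ones((20, 20), bool))
                for _ in range(10)]
    out = se.stack_richness(surfaces)
    assert (out["richness"].values == 10).all()
    assert (out["classes"].values == 4).all()


def test_ensemble_contract_on_default_scenario(default_scenario_data):
    """Single qualifying member -> weight 1; convexity of the mean."""
    data = default_scenario_data
    env = data["environment"]
    geom = env[0]
    occ = se.thin_table(data["occurrences"], 1.0, seed=11)
    sp = sorted(occ.species.unique())[0]
    pts = occ.loc[occ.species == sp, ["x", "y"]].to_numpy()
    cells = np.unique(se.points_to_cells(pts, geom), axis=0)
    model, surf = se.ensemble(sp, cells, env, runs=4, seed=1)
    assert model.weights.sum() == pytest.approx(1.0, abs=1e-12)
    lo = np.min([m.prediction.values for m in model.members], axis=0)
    hi = np.max([m.prediction.values for m in model.members], axis=0)
    assert np.all(surf.p_ens.values >= lo - 1e-12)
    assert np.all(surf.p_ens.values <= hi + 1e-12)
    if len(model.members) == 1:
        np.testing.assert_allclose(surf.p_ens.values,
                                   model.members[0].prediction.values)
    # binarization reproducibility: re-evaluating the stored test points
    ev = se.evaluate_scores(surf.test_presence_scores,
                            surf.test_background_scores)
    assert ev.threshold_at_max_tss == pytest.approx(surf.threshold)
    # classes: unsuitable exactly where binary is false
    assert ((surf.classes.values == 0) == ~surf.binary.values).all()


def test_ensemble_errors_when_no_member_qualifies(default_scenario_data):
    data = default_scenario_data
    env = data["environment"]
    geom = env[0]
    occ = se.thin_table(data["occurrences"], 1.0, seed=11)
    sp = sorted(occ.species.unique())[0]
    cells = np.unique(se.points_to_cells(
        occ.loc[occ.species == sp, ["x", "y"]].to_numpy(), geom), axis=0)
    with pytest.raises(RuntimeError, match="member TSS"):
        se.ensemble(sp, cells, env, runs=2, seed=1, inclusion_threshold=0.999)
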