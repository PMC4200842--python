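"""Matrix assembly, NIPALS PLS, LOO validation, statistics and model search."""

import math

import numpy as np
import pytest

from fieldqsar.chem_io import Atom, Molecule
from fieldqsar.field_engine import FieldBlock, Lattice
from fieldqsar.qsar_stats import (
    assemble_matrix,
    final_stats,
    loo_q2,
    model_search,
    pls_fit,
    select_opn,
    split_dataset,
)

LAT = Lattice(origin=(0, 0, 0), spacing=1.0, dims=(2, 2, 2))


def _block(values, kind="CoMSIA_H", flags=None):
    values = np.asarray(values, dtype=float)
    ids = [f"m{i}" for i in range(values.shape[0])]
    lat = Lattice(origin=(0, 0, 0), spacing=1.0, dims=(values.shape[1], 1, 1))
    return FieldBlock(kind, values, lat, ids, flags=flags)


def _random_matrix(n=25, p=12, seed=0, noise=0.0, coefs=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, p))
    if coefs is None:
        coefs = rng.normal(0, 1, p)
    y = X @ coefs + 1.7 + noise * rng.normal(0, 1, n)
    return assemble_matrix([_block(X)], y, scaling="none"), X, y


# ---------------------------------------------------------------- assembly

def test_constant_column_dropped_with_reason():
    X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [4.0, 5.0]])
    M = assemble_matrix([_block(X)], np.arange(4.0))
    assert M.n_columns == 1
    assert ("CoMSIA_H", 1) in M.dropped["zero variance"]


def test_scaling_none_is_identity():
    X = np.random.default_rng(3).normal(0, 1, (6, 4))
    M = assemble_matrix([_block(X)], np.arange(6.0), scaling="none")
    np.testing.assert_array_equal(M.X_raw, X)
    np.testing.assert_array_equal(M.scale_factors(), np.ones(4))


def test_block_standard_equalizes_block_variance():
    rng = np.random.default_rng(5)
    a = _block(rng.normal(0, 1, (10, 6)), kind="CoMSIA_H")
    b = _block(rng.normal(0, 40, (10, 6)), kind="CoMSIA_D")
    M = assemble_matrix([a, b], np.arange(10.0), scaling="block_standard")
    Xs = M.X_raw * M.scale_factors()
    var_a = Xs[:, M.block_of_col == 0].var(axis=0, ddof=1).sum()
    var_b = Xs[:, M.block_of_col == 1].var(axis=0, ddof=1).sum()
    assert var_a == pytest.approx(var_b, abs=1e-9)
    assert var_a == pytest.approx(1.0, abs=1e-9)


def test_comfa_min_sigma_default_filter():
    rng = np.random.default_rng(8)
    X = np.column_stack([rng.normal(0, 0.5, 10), rng.normal(0, 8, 10)])
    M = assemble_matrix([_block(X, kind="CoMFA_steric")], np.arange(10.0))
    # sd ~0.5 < 2.0 kcal/mol threshold -> dropped; sd ~8 kept
    assert M.n_columns == 1
    assert M.column_labels[0] == ("CoMFA_steric", 1)


def test_flagged_electrostatic_entries_mean_substituted():
    X = np.array([[30.0, 1.0], [2.0, 2.0], [4.0, 3.0], [6.0, 4.0]])
    flags = np.zeros_like(X, dtype=bool)
    flags[0, 0] = True  # inside the steric cap
    M = assemble_matrix(
        [_block(X, kind="CoMFA_electrostatic", flags=flags)],
        np.arange(4.0), min_sigma=0.0,
    )
    assert M.X_raw[0, 0] == pytest.approx(4.0)  # mean of unflagged 2, 4, 6
    assert ("CoMFA_electrostatic", 0) in M.substituted


def test_assembly_errors():
    with pytest.raises(ValueError, match="length"):
        assemble_matrix([_block(np.eye(3))], np.arange(4.0))
    const = np.ones((4, 2))
    with pytest.raises(ValueError, match="filter"):
        assemble_matrix([_block(const)], np.arange(4.0))


# -------------------------------------------------------------------- PLS

def test_univariate_pls_is_simple_regression():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 2, 15)
    y = 3.0 * x + rng.normal(0, 0.1, 15)
    M = assemble_matrix([_block(x[:, None])], y, scaling="none")
    model = pls_fit(M, 1)
    slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    assert model.coef[0] == pytest.approx(slope, abs=1e-10)


def test_full_rank_pls_equals_least_squares():
    M, X, y = _random_matrix(n=30, p=6, seed=2, noise=0.5)
    model = pls_fit(M, 6)
    Xc = X - X.mean(axis=0)
    beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
    np.testing.assert_allclose(model.coef, beta, atol=1e-8)


def test_pls_matches_sklearn_nipals():
    from sklearn.cross_decomposition import PLSRegression

    M, X, y = _random_matrix(n=40, p=20, seed=4, noise=1.0)
    for c in (1, 3, 5):
        ours = pls_fit(M, c)
        ref = PLSRegression(n_components=c, scale=False).fit(X, y)
        np.testing.assert_allclose(ours.coef, ref.coef_.ravel(), atol=1e-8)


def test_scores_are_orthogonal():
    M, _, _ = _random_matrix(n=30, p=10, seed=7, noise=0.3)
    model = pls_fit(M, 5)
    gram = model.scores.T @ model.scores
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8


def test_components_beyond_rank_rejected():
    M, _, _ = _random_matrix(n=5, p=10, seed=9)
    with pytest.raises(ValueError, match="rank"):
        pls_fit(M, 5)  # rank bound is n-1 = 4
    rng = np.random.default_rng(0)
    base = rng.normal(0, 1, (12, 2))
    X = np.hstack([base, base @ np.array([[1.0, 2.0], [0.5, -1.0]])])
    y = X[:, 0] + 0.1 * rng.normal(0, 1, 12)
    M2 = assemble_matrix([_block(X)], y, scaling="none")
    with pytest.raises(ValueError, match="rank"):
        pls_fit(M2, 3)  # true rank is 2


# -------------------------------------------------------------------- LOO

def _naive_loo(M, c):
    """Literal one-at-a-time refit loop over the training rows."""
    rows = M.train_rows
    y = M.y[rows]
    press = 0.0
    for pos in range(rows.size):
        sub = np.delete(rows, pos)
        model = pls_fit(M, c, rows=sub)
        pred = model.predict(M.X_raw[rows[pos]][None, :])[0]
        press += (y[pos] - pred) ** 2
    return 1.0 - press / float(((y - y.mean()) ** 2).sum())


def test_loo_matches_naive_refit_loop(small_matrix):
    for c in (1, 3):
        q2, _, _ = loo_q2(small_matrix, c)
        assert q2 == pytest.approx(_naive_loo(small_matrix, c), abs=1e-10)


def test_perfect_model_limit():
    M, _, _ = _random_matrix(n=20, p=3, seed=11, noise=0.0)
    q2, _, _ = loo_q2(M, 3)
    assert q2 >= 0.999


def test_constant_y_rejected():
    X = np.random.default_rng(1).normal(0, 1, (8, 3))
    M = assemble_matrix([_block(X)], np.full(8, 5.0))
    with pytest.raises(ValueError, match="sum of squares"):
        loo_q2(M, 1)


def test_sep_denominator():
    M, _, _ = _random_matrix(n=20, p=4, seed=13, noise=1.0)
    q2, sep, press = loo_q2(M, 2)
    assert sep == pytest.approx(math.sqrt(press / (20 - 2 - 1)), abs=1e-12)


# ------------------------------------------------------------------- OPN

def test_opn_at_q2_peak_with_tie_break(small_matrix):
    opn, table = select_opn(small_matrix, 6)
    q2s = table["q2"].to_numpy()
    assert q2s[opn - 1] >= q2s.max() - 1e-6
    # no smaller count reaches within tolerance of the chosen Q2
    assert all(q2s[c] < q2s[opn - 1] - 1e-6 for c in range(opn - 1))


def test_opn_recovers_planted_latent_factors():
    rng = np.random.default_rng(21)
    T = rng.normal(0, 1, (40, 3))          # 3 latent factors
    P = rng.normal(0, 1, (3, 30))
    X = T @ P + 0.01 * rng.normal(0, 1, (40, 30))
    y = T @ np.array([2.0, -1.0, 0.5]) + 0.01 * rng.normal(0, 1, 40)
    M = assemble_matrix([_block(X)], y, scaling="none")
    opn, _ = select_opn(M, 8)
    assert opn in (3, 4)


def test_min_see_criterion_available(small_matrix):
    opn_q2, table = select_opn(small_matrix, 5, criterion="q2")
    opn_see, _ = select_opn(small_matrix, 5, criterion="min_see")
    assert opn_see == int(table.loc[table["see"].idxmin(), "components"])


# ----------------------------------------------------------- final stats

def test_stats_match_hand_arithmetic_on_four_points():
    # 4 training + 2 test molecules, single descriptor column
    x = np.array([0.0, 1.0, 2.0, 3.0, 1.0, 2.0])
    y = np.array([1.0, 3.0, 4.0, 8.0, 3.5, 5.0])
    split = np.array(["train"] * 4 + ["test"] * 2)
    M = assemble_matrix([_block(x[:, None])], y, scaling="none", split_labels=split)
    model = pls_fit(M, 1)
    stats = final_stats(model, M)

    # hand arithmetic: simple regression of y on x over the 4 training points
    xt, yt = x[:4], y[:4]
    slope = np.cov(xt, yt, ddof=1)[0, 1] / np.var(xt, ddof=1)  # = 2.2
    intercept = yt.mean() - slope * xt.mean()                   # = 0.7
    pred = slope * xt + intercept
    rss = float(((yt - pred) ** 2).sum())
    ss = float(((yt - yt.mean()) ** 2).sum())
    r2 = 1 - rss / ss
    see = math.sqrt(rss / (4 - 1 - 1))
    f = (r2 / (1 - r2)) * ((4 - 1 - 1) / 1)
    pred_test = slope * x[4:] + intercept
    r2_pred = 1 - float(((y[4:] - pred_test) ** 2).sum()) / float(
        ((y[4:] - yt.mean()) ** 2).sum()
    )
    assert stats.r2_ncv == pytest.approx(r2, abs=1e-10)
    assert stats.see == pytest.approx(see, abs=1e-10)
    assert stats.f == pytest.approx(f, abs=1e-10)
    assert stats.r2_pred == pytest.approx(r2_pred, abs=1e-10)
    # Q2 by explicit leave-one-out simple regressions
    press = 0.0
    for i in range(4):
        keep = [j for j in range(4) if j != i]
        xs, ys = xt[keep], yt[keep]
        m = np.cov(xs, ys, ddof=1)[0, 1] / np.var(xs, ddof=1)
        b = ys.mean() - m * xs.mean()
        press += (yt[i] - (m * xt[i] + b)) ** 2
    assert stats.q2 == pytest.approx(1 - press / ss, abs=1e-10)


def test_perfect_fit_reports_zero_see_inf_f():
    x = np.arange(8.0)
    y = 2.0 * x + 1.0
    M = assemble_matrix([_block(x[:, None])], y, scaling="none")
    stats = final_stats(pls_fit(M, 1), M)
    assert stats.see == pytest.approx(0.0, abs=1e-10)
    assert math.isinf(stats.f)
    assert stats.as_dict()["F"] == "inf"


def test_r2_pred_zero_when_predicting_train_mean():
    rng = np.random.default_rng(31)
    Xtr = rng.normal(0, 1, (10, 3))
    ytr = Xtr @ np.array([1.0, -2.0, 0.5]) + 4.0
    # test rows placed at the training column means -> prediction = train mean
    Xte = np.tile(Xtr.mean(axis=0), (3, 1))
    yte = np.array([3.0, 5.0, 6.0])
    X = np.vstack([Xtr, Xte])
    y = np.concatenate([ytr, yte])
    split = np.array(["train"] * 10 + ["test"] * 3)
    M = assemble_matrix([_block(X)], y, scaling="none", split_labels=split)
    stats = final_stats(pls_fit(M, 3), M)
    assert stats.r2_pred == pytest.approx(0.0, abs=1e-9)


def test_r2_pred_omitted_without_test_rows():
    M, _, _ = _random_matrix(n=15, p=4, seed=17, noise=0.5)
    stats = final_stats(pls_fit(M, 2), M)
    assert stats.r2_pred is None


def test_contributions_nonnegative_and_sum_to_one(default_search):
    _table, fitted = default_search
    for _label, (_model, _M, stats) in fitted.items():
        vals = np.array(list(stats.contributions.values()))
        assert (vals >= 0).all()
        assert vals.sum() == pytest.approx(1.0, abs=1e-9)


# ------------------------------------------------------------ model search

def test_search_enumerates_31_subsets(default_search):
    table, fitted = default_search
    assert len(table) == 31
    assert len(fitted) == 31
    for single in ("S", "E", "H", "D", "A"):
        assert single in set(table["fields"])


def test_search_is_ranked_and_finds_planted_field(default_search, default_scenario):
    table, _ = default_search
    q2 = table["Q2"].to_numpy()
    assert (np.diff(q2) <= 1e-12).all()
    planted = default_scenario["truth"]["planted_field"]  # CoMSIA_H
    assert planted == "CoMSIA_H"
    top5 = table.head(5)["fields"]
    assert all("H" in label.split("+") for label in top5)


def test_search_requires_five_comsia_blocks():
    with pytest.raises(ValueError, match="five CoMSIA"):
        model_search([_block(np.eye(4))], np.arange(4.0))


# ------------------------------------------------------------------ split

def _mols(n, with_activity=True, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        m = Molecule(f"m{i}", [Atom("C", rng.normal(0, 1, 3))])
        if with_activity:
            m.activity_pIC50 = float(rng.uniform(5, 8.5))
        out.append(m)
    return out


def test_split_181_gives_121_60():
    labeled = split_dataset(_mols(181), ratio=(2, 1), seed=42)
    train = sum(m.split_label == "train" for m in labeled)
    test = sum(m.split_label == "test" for m in labeled)
    assert (train, test) == (121, 60)


def test_split_minimum_and_determinism():
    labeled = split_dataset(_mols(3), seed=5)
    counts = sorted(m.split_label for m in labeled)
    assert counts.count("train") == 2 and counts.count("test") == 1
    a = [m.split_label for m in split_dataset(_mols(50), seed=9)]
    b = [m.split_label for m in split_dataset(_mols(50), seed=9)]
    assert a == b
    c = [m.split_label for m in split_dataset(_mols(50), seed=10)]
    assert a != c


def test_stratified_split_mirrors_activity_distribution():
    mols = _mols(90, seed=3)
    labeled = split_dataset(mols, seed=1, stratify=True)
    acts = np.array([m.activity_pIC50 for m in labeled])
    test_mask = np.array([m.split_label == "test" for m in labeled])
    edges = np.quantile(acts, [1 / 3, 2 / 3])
    strata = np.digitize(acts, edges)
    for s in range(3):
        n_test = int((test_mask & (strata == s)).sum())
        assert n_test == pytest.approx(10, abs=1)  # 30 per tertile, 1/3 held out
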