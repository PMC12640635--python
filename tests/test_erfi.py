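import itertools

import numpy as np
import pandas as pd
import pytest

from reefshift import erfi
from reefshift.erfi import (
    DEFAULT_DIRECTION_WEIGHTS,
    ERFI_VARIABLES,
    build_site_matrix,
    combine_weights,
    erfi_scores,
    pca_loadings,
    run_erfi,
    standardize,
)
from reefshift.errors import DecompositionError, ValidationError


def site_matrix(seed=0, n_sites=6):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.random((n_sites, len(ERFI_VARIABLES))),
        index=[f"site{i}" for i in range(n_sites)],
        columns=list(ERFI_VARIABLES),
    )


class TestStandardize:
    def test_columns_are_zscores(self):
        z = standardize(site_matrix())
        assert np.allclose(z.mean(), 0, atol=1e-10)
        assert np.allclose(z.std(ddof=1), 1, atol=1e-10)

    def test_row_at_mean_is_zero(self):
        m = site_matrix(n_sites=5)
        m.loc["site_at_mean"] = m.mean()
        z = standardize(m)
        assert np.allclose(z.loc["site_at_mean"], 0, atol=1e-10)

    def test_two_site_closed_form(self):
        m = pd.DataFrame({"coral": [0.1, 0.5]}, index=["a", "b"])
        z = standardize(m, ddof=1)
        assert np.allclose(z["coral"], [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_ddof_zero_convention(self):
        m = pd.DataFrame({"coral": [0.1, 0.5]}, index=["a", "b"])
        z = standardize(m, ddof=0)
        assert np.allclose(z["coral"], [-1.0, 1.0])

    def test_constant_column_dropped_with_notice(self, caplog):
        m = site_matrix()
        m["cca"] = 0.25
        with caplog.at_level("WARNING"):
            z = standardize(m)
        assert "cca" not in z.columns
        assert any("cca" in rec.message for rec in caplog.records)

    def test_all_constant_raises(self):
        m = pd.DataFrame({"coral": [0.3, 0.3], "turf": [0.1, 0.1]})
        with pytest.raises(DecompositionError):
            standardize(m)


class TestPcaLoadings:
    def test_perfectly_correlated_columns_share_magnitude(self):
        rng = np.random.default_rng(3)
        x = rng.random(8)
        m = pd.DataFrame({"coral": x, "cca": 2 * x + 1})
        z = standardize(m)
        loadings, _ = pca_loadings(z, n_components=1)
        assert abs(loadings.loc["coral", "l1"]) == pytest.approx(
            abs(loadings.loc["cca", "l1"]), abs=1e-10
        )

    def test_uncorrelated_columns_load_on_own_component(self):
        # orthogonal centered columns with distinct variances -> axis-aligned PCs
        m = pd.DataFrame(
            {
                "coral": [3.0, -3.0, 0.0, 0.0],
                "turf": [0.0, 0.0, 2.0, -2.0],
            }
        )
        loadings, evr = pca_loadings(m, n_components=2)
        mags = loadings.abs().to_numpy()
        assert np.allclose(np.sort(mags, axis=1)[:, -1], 1.0, atol=1e-10)
        assert np.allclose(mags.sum(axis=0), 1.0, atol=1e-10)
        assert abs(loadings.loc["coral", "l1"]) == pytest.approx(1.0)  # larger variance first

    def test_l_invariant_under_sign_flips(self):
        z = standardize(site_matrix(seed=5))
        loadings, evr = pca_loadings(z)
        w = combine_weights(loadings, explained_variance_ratio=evr)
        flipped = loadings * np.array([1, -1, 1])
        w2 = combine_weights(flipped, explained_variance_ratio=evr)
        pd.testing.assert_series_equal(w.L, w2.L)

    def test_component_deficit_flagged(self, caplog):
        z = standardize(site_matrix(n_sites=3))
        with caplog.at_level("WARNING"):
            loadings, _ = pca_loadings(z, n_components=3)
        assert loadings.shape[1] == 2
        assert any("retrievable" in rec.message for rec in caplog.records)

    def test_orthonormal_loadings(self):
        z = standardize(site_matrix(seed=9, n_sites=8))
        loadings, _ = pca_loadings(z, n_components=3)
        gram = loadings.to_numpy().T @ loadings.to_numpy()
        assert np.allclose(gram, np.eye(3), atol=1e-10)


def spreadsheet_erfi(matrix: pd.DataFrame, directions: dict):
    """Independent oracle: step-by-step evaluation of the five index
    equations with plain loops and an eigendecomposition route."""
    sites = list(matrix.index)
    cols = list(matrix.columns)
    means = {j: sum(matrix[j]) / len(sites) for j in cols}
    sds = {
        j: (sum((x - means[j]) ** 2 for x in matrix[j]) / (len(sites) - 1)) ** 0.5
        for j in cols
    }
    z = {(i, j): (matrix.loc[i, j] - means[j]) / sds[j] for i in sites for j in cols}

    Z = np.array([[z[(i, j)] for j in cols] for i in sites])
    cov = np.cov(Z, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    L = {j: sum(abs(evecs[k, c]) for c in range(3)) for k, j in enumerate(cols)}
    C = {j: L[j] * directions[j] for j in cols}
    raw = {i: sum(C[j] * z[(i, j)] for j in cols) for i in sites}
    lo, hi = min(raw.values()), max(raw.values())
    norm = {i: (raw[i] - lo) / (hi - lo) for i in sites}
    return raw, norm


class TestErfiScores:
    def test_degenerate_all_equal(self, caplog):
        z = pd.DataFrame(0.0, index=["a", "b", "c"], columns=["coral", "turf"])
        loadings = pd.DataFrame(
            {"l1": [0.7, 0.7]}, index=["coral", "turf"]
        )
        w = combine_weights(loadings)
        with caplog.at_level("WARNING"):
            scores = erfi_scores(z, w)
        assert scores.degenerate
        assert (scores.raw == 0).all()
        assert (scores.normalized == 0.5).all()

    def test_matches_spreadsheet_oracle(self):
        m = site_matrix(seed=21, n_sites=6)
        raw_exp, norm_exp = spreadsheet_erfi(m, DEFAULT_DIRECTION_WEIGHTS)
        z = standardize(m)
        loadings, evr = pca_loadings(z, n_components=3)
        w = combine_weights(loadings, explained_variance_ratio=evr)
        scores = erfi_scores(z, w)
        for site in m.index:
            assert scores.raw[site] == pytest.approx(raw_exp[site], abs=1e-9)
            assert scores.normalized[site] == pytest.approx(norm_exp[site], abs=1e-9)

    def test_raw_scores_sum_to_zero(self):
        z = standardize(site_matrix(seed=4))
        loadings, evr = pca_loadings(z)
        scores = erfi_scores(z, combine_weights(loadings, explained_variance_ratio=evr))
        assert scores.raw.sum() == pytest.approx(0.0, abs=1e-9)

    def test_normalized_endpoints_attained(self):
        z = standardize(site_matrix(seed=8))
        loadings, evr = pca_loadings(z)
        scores = erfi_scores(z, combine_weights(loadings, explained_variance_ratio=evr))
        assert scores.normalized.min() == 0.0
        assert scores.normalized.max() == 1.0
        assert scores.normalized.between(0, 1).all()

    def test_sign_flip_invariance_of_scores(self):
        z = standardize(site_matrix(seed=12))
        loadings, evr = pca_loadings(z)
        base = erfi_scores(z, combine_weights(loadings, explained_variance_ratio=evr))
        for signs in itertools.product([1, -1], repeat=loadings.shape[1]):
            flipped = loadings * np.array(signs)
            scores = erfi_scores(z, combine_weights(flipped, explained_variance_ratio=evr))
            pd.testing.assert_series_equal(base.raw, scores.raw)

    def test_missing_weight_raises(self):
        z = standardize(site_matrix())
        loadings, _ = pca_loadings(z)
        with pytest.raises(ValidationError):
            combine_weights(loadings, direction_weights={"coral": 4})


class TestAffineInvariance:
    def test_column_shift_and_scale_leave_index_unchanged(self):
        m = site_matrix(seed=33)
        z0 = standardize(m)
        loadings, evr = pca_loadings(z0)
        base = erfi_scores(z0, combine_weights(loadings, explained_variance_ratio=evr))

        m2 = m.copy()
        m2["turf"] = 3.5 * m2["turf"] + 10.0  # positive affine map
        z2 = standardize(m2)
        loadings2, evr2 = pca_loadings(z2)
        scores = erfi_scores(z2, combine_weights(loadings2, explained_variance_ratio=evr2))
        pd.testing.assert_frame_equal(z0, z2, atol=1e-10, rtol=0)
        for site in m.index:
            assert scores.raw[site] == pytest.approx(base.raw[site], abs=1e-8)


class TestRunErfi:
    def test_dominant_site_ranks_first(self):
        rng = np.random.default_rng(7)
        dates = ["2025-01-15", "2025-02-10"]
        sites = ["best", "mid1", "mid2", "worst"]
        # 'best' maximizes every favourable variable, minimizes every unfavourable one
        cover = {
            "best": {"coral": 0.6, "cca": 0.2, "turf": 0.05, "cyanobacteria": 0.0},
            "mid1": {"coral": 0.3, "cca": 0.1, "turf": 0.3, "cyanobacteria": 0.05},
            "mid2": {"coral": 0.2, "cca": 0.08, "turf": 0.4, "cyanobacteria": 0.1},
            "worst": {"coral": 0.05, "cca": 0.02, "turf": 0.7, "cyanobacteria": 0.15},
        }
        bleach = {"best": 0.0, "mid1": 0.3, "mid2": 0.4, "worst": 0.9}
        ntaxa = {"best": 8, "mid1": 4, "mid2": 3, "worst": 1}
        brows, trows = [], []
        for site in sites:
            for date in dates:
                for transect in (1, 2, 3):
                    props = dict(cover[site])
                    props["other"] = 1 - sum(props.values())
                    jitter = rng.normal(0, 0.005, len(props))
                    vals = np.clip(np.array(list(props.values())) + jitter, 0, 1)
                    vals = vals / vals.sum()
                    for cat, p in zip(props, vals):
                        brows.append(
                            dict(site=site, date=date, transect=transect, category=cat, proportion=p)
                        )
                    for t in range(ntaxa[site]):
                        n_b = round(10 * bleach[site])
                        trows.append(
                            dict(site=site, date=date, transect=transect,
                                 taxon=f"tax{t}", health_state="healthy", count=10 - n_b)
                        )
                        if n_b:
                            trows.append(
                                dict(site=site, date=date, transect=transect,
                                     taxon=f"tax{t}", health_state="bleached", count=n_b)
                            )
        benthic = pd.DataFrame(brows)
        belt = pd.DataFrame(trows)
        report = run_erfi(benthic, belt, ("2025-01-01", "2025-02-28"))
        assert report.scores.ranking[0] == "best"
        assert report.scores.ranking[-1] == "worst"

    def test_direction_weight_scaling(self, benthic_table, belt_table):
        window = ("2025-01-01", "2025-02-28")
        base = run_erfi(benthic_table, belt_table, window)
        doubled = {k: 2 * v for k, v in DEFAULT_DIRECTION_WEIGHTS.items()}
        scaled = run_erfi(benthic_table, belt_table, window, direction_weights=doubled)
        assert scaled.scores.ranking == base.scores.ranking
        pd.testing.assert_series_equal(scaled.scores.normalized, base.scores.normalized)
        assert np.allclose(scaled.scores.raw, 2 * base.scores.raw)

    def test_row_permutation_invariance(self, benthic_table, belt_table):
        window = ("2025-01-01", "2025-02-28")
        base = run_erfi(benthic_table, belt_table, window)
        shuffled = run_erfi(
            benthic_table.sample(frac=1.0, random_state=3).reset_index(drop=True),
            belt_table.sample(frac=1.0, random_state=4).reset_index(drop=True),
            window,
        )
        pd.testing.assert_series_equal(
            base.scores.raw.sort_index(), shuffled.scores.raw.sort_index()
        )

    def test_window_with_no_surveys_raises(self, benthic_table, belt_table):
        with pytest.raises(ValidationError):
            build_site_matrix(benthic_table, belt_table, ("1990-01-01", "1990-02-01"))

    def test_provenance_recorded(self, benthic_table, belt_table):
        report = run_erfi(benthic_table, belt_table, ("2025-01-01", "2025-02-28"))
        assert report.provenance["direction_weights"]["coral"] == 4
        assert report.provenance["deterministic"] is True
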