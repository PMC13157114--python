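"""Inference layer: t-tests, split-plot ANOVA vs a projection oracle,
Greenhouse-Geisser behavior, Bonferroni."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stressphys.stats import (AnovaResult, bonferroni, mixed_rmanova,
                              posthoc_pairwise, ttest_ind)

# ---------------------------------------------------------------------
# independent oracle: sequential OLS projections on dummy designs
# ---------------------------------------------------------------------


def _dummies(labels):
    labels = pd.Series(labels).astype(str).to_numpy()
    return np.column_stack([(labels == c).astype(float)
                            for c in sorted(set(labels))])


def _inter(df, *cols):
    lab = df[cols[0]].astype(str)
    for c in cols[1:]:
        lab = lab + "|" + df[c].astype(str)
    return _dummies(lab)


def oracle_split_plot(df, dv, subject, between, within):
    """Brute-force split-plot F values via sequential least-squares
    projections; independent of the implementation under test."""
    y = df[dv].to_numpy(float)
    w = list(within)
    terms = [("mu", np.ones((len(df), 1))),
             (between, _inter(df, between)),
             ("S", _inter(df, subject)),
             (w[0], _inter(df, w[0])),
             (f"{between}*{w[0]}", _inter(df, between, w[0])),
             (f"S*{w[0]}", _inter(df, subject, w[0]))]
    if len(w) == 2:
        terms += [(w[1], _inter(df, w[1])),
                  (f"{between}*{w[1]}", _inter(df, between, w[1])),
                  (f"S*{w[1]}", _inter(df, subject, w[1])),
                  (f"{w[0]}*{w[1]}", _inter(df, w[0], w[1])),
                  (f"{between}*{w[0]}*{w[1]}",
                   _inter(df, between, w[0], w[1]))]
    ss, dfs = {}, {}
    X = np.empty((len(df), 0))
    rss_prev = float(y @ y)
    rank_prev = 0
    for name, block in terms:
        X = np.hstack([X, block])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        rank = np.linalg.matrix_rank(X)
        ss[name] = rss_prev - rss
        dfs[name] = rank - rank_prev
        rss_prev, rank_prev = rss, rank
    ss["resid"] = rss_prev
    dfs["resid"] = len(df) - rank_prev

    def F(eff, err):
        return (ss[eff] / dfs[eff]) / (ss[err] / dfs[err])

    out = {between: F(between, "S")}
    out[w[0]] = F(w[0], f"S*{w[0]}")
    out[f"{between}*{w[0]}"] = F(f"{between}*{w[0]}", f"S*{w[0]}")
    if len(w) == 2:
        out[w[1]] = F(w[1], f"S*{w[1]}")
        out[f"{between}*{w[1]}"] = F(f"{between}*{w[1]}", f"S*{w[1]}")
        out[f"{w[0]}*{w[1]}"] = F(f"{w[0]}*{w[1]}", "resid")
        out[f"{between}*{w[0]}*{w[1]}"] = F(f"{between}*{w[0]}*{w[1]}",
                                            "resid")
    return out


def _long(n_per_group, within_shape, rng, group_effect=0.0,
          interaction=0.3):
    rows = []
    wnames = ["b", "c"][: len(within_shape)]
    for g in ("g1", "g2"):
        for s in range(n_per_group):
            base = rng.normal(0, 1) + (group_effect if g == "g1" else 0.0)
            for cell in itertools.product(
                    *[range(k) for k in within_shape]):
                row = {"subj": f"{g}_{s}", "grp": g,
                       "y": base + rng.normal(0, 1)
                       + interaction * cell[0] * (g == "g1")}
                for name, lev in zip(wnames, cell):
                    row[name] = f"{name}{lev}"
                rows.append(row)
    return pd.DataFrame(rows)


class TestTTest:
    def test_printed_group_comparisons_reproduced(self):
        """Questionnaire group contrasts from summary statistics land on
        the published t and CI values."""
        r = ttest_ind(39.03, 12.14, 40, 39.83, 11.79, 40)
        assert round(r.t, 2) == -0.30
        assert round(r.ci95[0], 2) == -6.13
        assert round(r.ci95[1], 2) == 4.53
        r2 = ttest_ind(58.30, 5.75, 40, 58.10, 5.278, 40)
        assert round(r2.t, 2) == 0.16

    def test_identical_summaries(self):
        r = ttest_ind(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert r.t == 0.0 and r.mean_diff == 0.0
        assert r.ci95[0] == pytest.approx(-r.ci95[1])

    def test_raw_samples_match_scipy(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 1.2, 12)
        mine = ttest_ind(x, mean2=y)
        ref = sps.ttest_ind(x, y)
        assert mine.t == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ttest_ind(1.0, 1.0, 1, 2.0, 1.0, 10)
        with pytest.raises(ValueError):
            ttest_ind(1.0, 0.0, 10, 2.0, 1.0, 10)


class TestBonferroni:
    def test_worked_examples(self):
        assert bonferroni([0.01], 3)[0] == pytest.approx(0.03)
        assert bonferroni([0.5], 3)[0] == 1.0

    def test_monotone_and_dominates_raw(self, rng):
        p = np.sort(rng.uniform(0, 1, 20))
        adj = bonferroni(p)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(adj >= p)


class TestAnovaOracle:
    def test_one_within_matches_projection_oracle(self, rng):
        df = _long(4, (3,), rng)
        res = mixed_rmanova(df, "y", "subj", "grp", ["b"])
        ref = oracle_split_plot(df, "y", "subj", "grp", ["b"])
        for name, f_ref in ref.items():
            assert res[name].F == pytest.approx(f_ref, abs=1e-9), name

    def test_two_within_matches_projection_oracle(self, rng):
        df = _long(3, (3, 2), rng, group_effect=0.5)
        res = mixed_rmanova(df, "y", "subj", "grp", ["b", "c"])
        ref = oracle_split_plot(df, "y", "subj", "grp", ["b", "c"])
        assert len(ref) == 7
        for name, f_ref in ref.items():
            assert res[name].F == pytest.approx(f_ref, abs=1e-9), name

    def test_enumerated_fixture(self):
        """Hand-enumerated 2 groups x 3 levels x 4 subjects fixture."""
        vals = [3, 5, 4, 2, 4, 4, 4, 6, 5, 3, 5, 6,
                6, 7, 9, 5, 6, 8, 7, 8, 8, 6, 7, 9]
        rows = []
        i = 0
        for g in ("a", "b"):
            for s in range(4):
                for b in ("t1", "t2", "t3"):
                    rows.append({"subj": f"{g}{s}", "grp": g, "b": b,
                                 "y": float(vals[i])})
                    i += 1
        df = pd.DataFrame(rows)
        res = mixed_rmanova(df, "y", "subj", "grp", ["b"])
        ref = oracle_split_plot(df, "y", "subj", "grp", ["b"])
        for name, f_ref in ref.items():
            assert res[name].F == pytest.approx(f_ref, abs=1e-9)

    def test_cross_check_against_pingouin(self, rng):
        import pingouin as pg

        # interaction-free data: the pooled-within-group and total
        # covariance estimators of epsilon then agree up to noise
        df = _long(8, (4,), rng, interaction=0.0)
        res = mixed_rmanova(df, "y", "subj", "grp", ["b"])
        ref = pg.mixed_anova(df, dv="y", within="b", subject="subj",
                             between="grp", correction=True)
        ref = ref.set_index("Source")
        assert res["grp"].F == pytest.approx(ref.loc["grp", "F"], abs=1e-6)
        assert res["b"].F == pytest.approx(ref.loc["b", "F"], abs=1e-6)
        assert res["grp*b"].F == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-6)
        assert res["b"].partial_eta_sq == pytest.approx(
            ref.loc["b", "np2"], abs=1e-6)
        # epsilon conventions differ (pooled within-group vs total
        # covariance), so only proximity is checked here
        assert res["b"].epsilon == pytest.approx(ref.loc["b", "eps"],
                                                 abs=0.05)


class TestAnovaContracts:
    def test_two_level_epsilon_exactly_one(self, rng):
        df = _long(5, (2,), rng)
        res = mixed_rmanova(df, "y", "subj", "grp", ["b"])
        assert res["b"].epsilon == 1.0
        assert res["b"].df_num_gg == res["b"].df_num

    def test_epsilon_bounds(self, rng):
        df = _long(6, (4,), rng)
        res = mixed_rmanova(df, "y", "subj", "grp", ["b"])
        assert 1.0 / 3.0 <= res["b"].epsilon <= 1.0

    def test_partial_eta_sq_affine_invariant(self, rng):
        df = _long(4, (3,), rng)
        r1 = mixed_rmanova(df, "y", "subj", "grp", ["b"])
        df2 = df.assign(y=3.0 * df["y"] + 7.0)
        r2 = mixed_rmanova(df2, "y", "subj", "grp", ["b"])
        for e1, e2 in zip(r1.effects, r2.effects):
            assert e1.partial_eta_sq == pytest.approx(e2.partial_eta_sq,
                                                      abs=1e-9)
            assert e1.F == pytest.approx(e2.F, abs=1e-9)

    def test_unbalanced_rejected(self, rng):
        df = _long(4, (3,), rng).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_rmanova(df, "y", "subj", "grp", ["b"])

    def test_missing_values_rejected(self, rng):
        df = _long(4, (3,), rng)
        df.loc[2, "y"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            mixed_rmanova(df, "y", "subj", "grp", ["b"])


class TestNullCalibration:
    def test_permuted_group_labels_nominal_alpha(self, rng):
        """Between-group test under label permutation rejects at the
        nominal 5% rate (2000 permutations)."""
        df = _long(8, (3,), rng, group_effect=0.0)
        subjects = df["subj"].unique()
        base = df.drop(columns="grp")
        rej = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = dict(zip(subjects,
                            rng.permutation([g.split("_")[0]
                                             for g in subjects])))
            d = base.assign(grp=base["subj"].map(perm))
            res = mixed_rmanova(d, "y", "subj", "grp", ["b"])
            rej += res["grp"].p < 0.05
        assert rej / n_perm == pytest.approx(0.05, abs=0.02)

    def test_gg_type_one_error_under_nonsphericity(self, rng):
        """GG-corrected within-effect test holds its size under a null
        with strongly nonspherical covariance."""
        k, n = 4, 10
        A = rng.normal(size=(k, k))
        cov = A @ A.T + np.diag([4.0, 1.0, 0.2, 0.1])
        chol = np.linalg.cholesky(cov)
        rej_gg = 0
        n_sim = 600
        for _ in range(n_sim):
            rows = []
            for g in ("g1", "g2"):
                Y = rng.standard_normal((n, k)) @ chol.T
                for s in range(n):
                    for j in range(k):
                        rows.append({"subj": f"{g}{s}", "grp": g,
                                     "b": f"b{j}", "y": Y[s, j]})
            res = mixed_rmanova(pd.DataFrame(rows), "y", "subj", "grp",
                                ["b"])
            rej_gg += res["b"].p < 0.05
        assert rej_gg / n_sim == pytest.approx(0.05, abs=0.02)


class TestPosthoc:
    def test_paired_contrasts_bonferroni(self, rng):
        df = _long(6, (3,), rng)
        out = posthoc_pairwise(df, "y", "subj", "b", paired=True)
        assert len(out) == 3
        assert (out.p_bonf >= out.p).all()
        assert (out.p_bonf <= 1.0).all()

    def test_independent_group_contrast(self, rng):
        df = _long(6, (3,), rng, group_effect=2.0)
        out = posthoc_pairwise(df, "y", "subj", "grp", paired=False)
        assert len(out) == 1
        assert out.p.iloc[0] < 0.05
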