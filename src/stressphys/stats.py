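"""Inference layer: independent t-tests, mixed repeated-measures ANOVA
with Greenhouse-Geisser correction, partial eta squared, Bonferroni.

The ANOVA handles the split-plot designs of the study: one
between-subject factor (group) crossed with one or two within-subject
factors, balanced within cells (exactly one value per participant and
within-cell). Sums of squares are partitioned classically: the group
effect is tested against subjects-within-groups, and each within-subject
effect (and its interaction with group) against its own
factor-by-subject-within-group stratum. Greenhouse-Geisser epsilon is
computed from the pooled within-group covariance of the orthonormalized
within-subject contrasts; corrected (fractional) degrees of freedom are
reported whenever a within factor has three or more levels, and epsilon
is exactly 1 for two-level factors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert


# --------------------------------------------------------------------------
# t-tests
# --------------------------------------------------------------------------

@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float
    ci95: tuple

    def __post_init__(self):
        lo, hi = self.ci95
        assert lo <= hi and 0.0 <= self.p <= 1.0


def ttest_ind(mean1, sd1=None, n1=None, mean2=None, sd2=None, n2=None) -> TTestResult:
    """Two-tailed pooled-variance independent-samples t-test.

    Accepts either summary statistics ``(mean1, sd1, n1, mean2, sd2,
    n2)`` or two raw sample arrays ``(sample1, sample2)``. The 95% CI is
    on the mean difference via the central t quantile.
    """
    if sd1 is None or n1 is None:
        x, y = np.asarray(mean1, float), np.asarray(mean2, float)
        n1, n2 = len(x), len(y)
        mean1, mean2 = x.mean(), y.mean()
        sd1, sd2 = x.std(ddof=1), y.std(ddof=1)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = mean1 - mean2
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.975, df)
    return TTestResult(float(t), float(df), float(p), float(diff),
                       (float(diff - tcrit * se), float(diff + tcrit * se)))


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p values: min(1, m * p)."""
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


# --------------------------------------------------------------------------
# mixed repeated-measures ANOVA
# --------------------------------------------------------------------------

@dataclass
class EffectResult:
    name: str
    ss_effect: float
    ss_error: float
    df_num: float
    df_den: float
    epsilon: float
    df_num_gg: float
    df_den_gg: float
    F: float
    p_uncorrected: float
    p: float
    partial_eta_sq: float


@dataclass
class AnovaResult:
    effects: list
    posthoc: pd.DataFrame | None = None
    family: str = ""

    def __getitem__(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects])


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal matrix with columns orthogonal to ones."""
    if k < 2:
        raise ValueError("factor needs at least two levels")
    return helmert(k, full=False).T


def _gg_epsilon(S: np.ndarray, M: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of contrast subspace M given the
    pooled within-group covariance S of the cell scores."""
    E = M.T @ S @ M
    df = M.shape[1]
    tr = np.trace(E)
    tr2 = np.trace(E @ E)
    if tr2 <= 0:
        return 1.0
    eps = tr**2 / (df * tr2)
    return float(np.clip(eps, 1.0 / df, 1.0))


def mixed_rmanova(data: pd.DataFrame, dv: str, subject: str,
                  between: str, within) -> AnovaResult:
    """Split-plot ANOVA: one between factor, one or two within factors.

    Requires complete, balanced within-subject data (exactly one value
    per subject x within-cell); unbalanced input raises with the missing
    cells listed, nothing is imputed. Greenhouse-Geisser corrected
    degrees of freedom and p values are reported for every
    within-subject effect (epsilon is exactly 1 when the stratum has a
    single numerator degree of freedom). Partial eta squared is
    SS_effect / (SS_effect + SS_error).
    """
    if isinstance(within, str):
        within = [within]
    if not 1 <= len(within) <= 2:
        raise ValueError("supports one or two within factors")
    df = data[[subject, between, dv] + list(within)].dropna()
    if len(df) < len(data):
        missing = data[data[dv].isna()]
        raise ValueError(
            f"missing values in {len(missing)} cells; "
            "mixed_rmanova requires complete data")

    levels = [np.sort(df[w].unique()) for w in within]
    cells = list(itertools.product(*levels))
    m = len(cells)

    # subject x cell matrix, cells ordered by itertools.product(*levels)
    counts = df.pivot_table(index=subject, columns=within, values=dv,
                            aggfunc="count")
    if counts.isna().any().any() or (counts != 1).any().any():
        raise ValueError("unbalanced design: need exactly one value per "
                         "subject x within-cell")
    Ypiv = df.pivot_table(index=subject, columns=within, values=dv)
    cols = list(levels[0]) if len(within) == 1 else cells
    Y = Ypiv[cols].to_numpy(dtype=float)
    subj_group = df.groupby(subject)[between].agg("unique")
    if subj_group.map(len).max() > 1:
        raise ValueError("a subject appears in more than one group")
    subj_group = subj_group.map(lambda u: u[0])
    groups = np.sort(subj_group.unique())
    a = len(groups)
    gidx = subj_group.loc[Ypiv.index].to_numpy()
    n_g = np.array([(gidx == g).sum() for g in groups])
    if (n_g < 2).any():
        raise ValueError("need at least two subjects per group")
    N = int(n_g.sum())

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    group_means = np.array([subj_means[gidx == g].mean() for g in groups])

    ss_total = ((Y - grand) ** 2).sum()
    ss_between_subj = m * ((subj_means - grand) ** 2).sum()
    ss_group = m * (n_g * (group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group

    # pooled within-group covariance of cell scores (for GG epsilon)
    Yc = Y.copy()
    for g in groups:
        sel = gidx == g
        Yc[sel] -= Y[sel].mean(axis=0)
    S = Yc.T @ Yc / (N - a)

    shape = tuple(len(l) for l in levels)

    def level_collapse(Ymat, axis_keep):
        # mean over the other within factor -> subjects x levels[axis_keep]
        Y3 = Ymat.reshape(Ymat.shape[0], *shape)
        if len(shape) == 2:
            other = 1 - axis_keep
            return Y3.mean(axis=other + 1)
        return Y3

    effects = []

    def add_effect(name, ss_e, df_n, ss_err, df_d, eps):
        ms_e = ss_e / df_n
        ms_r = ss_err / df_d
        F = ms_e / ms_r if ms_r > 0 else np.inf
        p_unc = float(sps.f.sf(F, df_n, df_d))
        dfn_gg, dfd_gg = eps * df_n, eps * df_d
        p_gg = float(sps.f.sf(F, dfn_gg, dfd_gg))
        effects.append(EffectResult(
            name, float(ss_e), float(ss_err), float(df_n), float(df_d),
            float(eps), float(dfn_gg), float(dfd_gg), float(F), p_unc, p_gg,
            float(ss_e / (ss_e + ss_err)) if (ss_e + ss_err) > 0 else 0.0))

    add_effect(between, ss_group, a - 1, ss_subj_within, N - a, 1.0)

    ss_within_strata = 0.0
    contrasts = {}
    for wi, w in enumerate(within):
        k = shape[wi]
        Kw = _orthonormal_contrasts(k)
        if len(within) == 1:
            M = Kw
        else:
            other = 1 - wi
            u = np.ones((shape[other], 1)) / np.sqrt(shape[other])
            M = (np.kron(Kw, u) if wi == 0 else np.kron(u, Kw))
        contrasts[w] = M
        eps = _gg_epsilon(S, M) if k > 2 else 1.0

        Yl = level_collapse(Y, wi)  # subjects x k
        lev_means = Yl.mean(axis=0)
        q = m // k
        ss_w = q * N * ((lev_means - grand) ** 2).sum()
        glev = np.array([Yl[gidx == g].mean(axis=0) for g in groups])
        ss_wg = q * sum(
            n_g[i] * ((glev[i] - group_means[i] - lev_means + grand) ** 2).sum()
            for i in range(len(groups)))
        resid = 0.0
        for i, g in enumerate(groups):
            sel = gidx == g
            dev = (Yl[sel] - subj_means[sel, None]
                   - glev[i][None, :] + group_means[i])
            resid += (dev ** 2).sum()
        ss_wsub = q * resid
        df_w = k - 1
        df_err = (N - a) * (k - 1)
        add_effect(w, ss_w, df_w, ss_wsub, df_err, eps)
        add_effect(f"{between}*{w}", ss_wg, (a - 1) * df_w, ss_wsub,
                   df_err, eps)
        ss_within_strata += ss_w + ss_wg + ss_wsub

    if len(within) == 2:
        b, c = shape
        Kb, Kc = (_orthonormal_contrasts(b), _orthonormal_contrasts(c))
        Mbc = np.kron(Kb, Kc)
        eps = _gg_epsilon(S, Mbc) if Mbc.shape[1] > 1 else 1.0
        cell_means = Y.mean(axis=0)
        gcell = np.array([Y[gidx == g].mean(axis=0) for g in groups])
        CM = cell_means.reshape(shape)
        rowm = CM.mean(axis=1, keepdims=True)
        colm = CM.mean(axis=0, keepdims=True)
        inter = CM - rowm - colm + grand
        ss_bc = N * (inter ** 2).sum()
        ss_bcg = 0.0
        for i in range(len(groups)):
            GM = gcell[i].reshape(shape)
            gi = (GM - GM.mean(axis=1, keepdims=True)
                  - GM.mean(axis=0, keepdims=True) + GM.mean())
            ss_bcg += n_g[i] * ((gi - inter) ** 2).sum()
        df_bc = (b - 1) * (c - 1)
        ss_bcsub = (ss_total - ss_between_subj - ss_within_strata
                    - ss_bc - ss_bcg)
        ss_bcsub = max(ss_bcsub, 0.0)
        df_err = (N - a) * df_bc
        name = f"{within[0]}*{within[1]}"
        add_effect(name, ss_bc, df_bc, ss_bcsub, df_err, eps)
        add_effect(f"{between}*{name}", ss_bcg, (a - 1) * df_bc, ss_bcsub,
                   df_err, eps)

    return AnovaResult(effects)


# --------------------------------------------------------------------------
# post hoc contrasts
# --------------------------------------------------------------------------

def posthoc_pairwise(data: pd.DataFrame, dv: str, subject: str,
                     factor: str, paired: bool,
                     family_size: int | None = None) -> pd.DataFrame:
    """All pairwise level contrasts of ``factor`` with Bonferroni
    adjustment over the comparison family.

    ``paired=True`` treats the factor as within-subject (paired t on
    subject cell means); otherwise the levels are independent groups.
    The family defaults to the number of pairs and is recorded in the
    output.
    """
    levels = np.sort(data[factor].unique())
    pairs = list(itertools.combinations(levels, 2))
    fam = family_size if family_size is not None else len(pairs)
    cellmeans = data.groupby([subject, factor])[dv].mean().unstack(factor)
    rows = []
    for l1, l2 in pairs:
        if paired:
            d = (cellmeans[l1] - cellmeans[l2]).dropna()
            t, p = sps.ttest_rel(cellmeans[l1].dropna(),
                                 cellmeans[l2].dropna())
            diff = float(d.mean())
            dfree = len(d) - 1
        else:
            x = cellmeans[l1].dropna()
            y = cellmeans[l2].dropna()
            res = ttest_ind(x.to_numpy(), mean2=y.to_numpy())
            t, p, diff, dfree = res.t, res.p, res.mean_diff, res.df
        rows.append({"level_1": l1, "level_2": l2, "mean_diff": diff,
                     "t": float(t), "df": dfree, "p": float(p),
                     "p_bonf": float(bonferroni([p], fam)[0]),
                     "family_size": fam})
    return pd.DataFrame(rows)
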