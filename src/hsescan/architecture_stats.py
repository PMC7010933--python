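"""Statistics relating HSE architecture to heat-stress response.

Covers the pipeline's inferential battery:

* Pearson chi-squared (no continuity correction) on gene-class x
  response contingency tables;
* MANOVA (Pillai's trace) of (promoter position, subunit number)
  against response status, with per-variable univariate F tests;
* ANCOVA of response magnitude (MFH) on a factor plus the promoter
  position covariate;
* Pearson correlation between position and MFH;
* per-mismatch-group ANCOVA contrasts against the typical-HSE baseline
  (3-subunit HSEs only), and Tukey-adjusted pairwise nucleotide
  comparisons on the covariate-adjusted linear predictor, with a
  compact letter display.

Position convention: bp upstream of the ATG, measured to the HSE's 3'
end, always positive; "closer to the start codon" means a smaller
value.  Slopes and correlations are reported under this convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.manova import MANOVA

from hsescan.hse_scanner import HSEMatch


@dataclass(frozen=True)
class ContingencyResult:
    statistic: float
    df: int
    p: float
    observed: np.ndarray
    expected: np.ndarray

    @property
    def valid(self) -> bool:
        return bool((self.expected > 0).all())


@dataclass(frozen=True)
class ManovaResult:
    overall_F: float
    overall_p: float
    statistic_name: str
    per_variable_p: dict[str, float]


@dataclass(frozen=True)
class AncovaResult:
    factor_F: Optional[float]
    factor_p: Optional[float]
    covariate_coefficient: float
    covariate_F: float
    covariate_p: float
    level_effects: dict = field(default_factory=dict)
    n_per_level: dict = field(default_factory=dict)
    df_resid: int = 0


@dataclass(frozen=True)
class MismatchGroupKey:
    orientation_label: str  # "G" (nGAAn first) or "C" (nTTCn first)
    subunit_index: int  # 1-based
    position_in_subunit: int  # 2..4

    @property
    def label(self) -> str:
        return f"{self.orientation_label} {self.subunit_index}-{self.position_in_subunit}"


# ---------------------------------------------------------------------------
# contingency


def response_proportion_test(
    counts: Mapping[str, tuple[int, int]]
) -> ContingencyResult:
    """Pearson chi-squared on class x {responsive, non-responsive}.

    ``counts`` maps each gene class to (responsive, total).  No
    continuity correction is applied.
    """
    if len(counts) < 2:
        raise ValueError("need at least two classes")
    table = []
    for cls, (resp, total) in counts.items():
        if total == 0:
            raise ValueError(f"class {cls!r} has zero total")
        if resp > total:
            raise ValueError(f"class {cls!r}: responsive > total")
        table.append([resp, total - resp])
    observed = np.asarray(table, dtype=float)
    chi2, p, dof, expected = stats.chi2_contingency(observed, correction=False)
    return ContingencyResult(float(chi2), int(dof), float(p), observed, expected)


# ---------------------------------------------------------------------------
# small OLS core (kept in numpy: these run inside calibration loops)


def _fit_ols(y: np.ndarray, X: np.ndarray):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("collinear design matrix")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = len(y) - X.shape[1]
    return beta, rss, df_resid


def _nested_f(rss0: float, rss1: float, df_extra: int, df_resid: int):
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    num = max(rss0 - rss1, 0.0) / df_extra
    den = rss1 / df_resid
    if den == 0:
        return np.inf, 0.0
    F = num / den
    return F, float(stats.f.sf(F, df_extra, df_resid))


def ancova_magnitude(
    records: pd.DataFrame,
    factor: Optional[str] = None,
    covariate: str = "position",
    response: str = "mfh",
) -> AncovaResult:
    """Linear model ``mfh ~ factor + position``.

    Reports the factor's F test (nested-model comparison), the position
    slope with its F test, and per-level effect estimates relative to
    the first level.  ``factor=None`` fits the pure covariate model.
    """
    y = records[response].to_numpy(dtype=float)
    pos = records[covariate].to_numpy(dtype=float)
    n = len(y)
    cols = [np.ones(n)]
    level_index: dict = {}
    if factor is not None:
        levels = sorted(pd.unique(records[factor]))
        if len(levels) < 2:
            raise ValueError("factor needs at least two levels")
        fac = records[factor].to_numpy()
        for lev in levels[1:]:
            cols.append((fac == lev).astype(float))
        level_index = {lev: i + 1 for i, lev in enumerate(levels[1:])}
    X = np.column_stack(cols + [pos])
    beta, rss_full, df_resid = _fit_ols(y, X)

    # position slope test: drop the covariate
    _, rss_nopos, _ = _fit_ols(y, X[:, :-1])
    cov_F, cov_p = _nested_f(rss_nopos, rss_full, 1, df_resid)

    factor_F = factor_p = None
    level_effects: dict = {}
    n_per_level: dict = {}
    if factor is not None:
        keep = [0, X.shape[1] - 1]
        _, rss_nofac, _ = _fit_ols(y, X[:, keep])
        factor_F, factor_p = _nested_f(
            rss_nofac, rss_full, len(level_index), df_resid
        )
        level_effects = {lev: float(beta[i]) for lev, i in level_index.items()}
        n_per_level = records[factor].value_counts().to_dict()
    return AncovaResult(
        factor_F=factor_F,
        factor_p=factor_p,
        covariate_coefficient=float(beta[-1]),
        covariate_F=cov_F,
        covariate_p=cov_p,
        level_effects=level_effects,
        n_per_level=n_per_level,
        df_resid=df_resid,
    )


# ---------------------------------------------------------------------------
# MANOVA


def manova_arch_vs_response(
    records: pd.DataFrame,
    dependent: tuple[str, str] = ("position", "subunit_count"),
    group: str = "responsive",
    statistic: str = "Pillai's trace",
) -> ManovaResult:
    """Multivariate test of (position, subunit number) vs response status.

    Pillai's trace with the standard F approximation; per-variable
    one-way F tests are reported alongside.
    """
    for var in dependent:
        if records[var].nunique() < 2:
            raise ValueError(f"dependent variable {var!r} is constant")
    groups = records[group].unique()
    if len(groups) < 2:
        raise ValueError("both response groups must be non-empty")
    if records.groupby(group).size().min() < 3:
        raise ValueError("need >= 3 observations per response group")
    data = records.loc[:, [*dependent, group]].copy()
    data.columns = ["dv1", "dv2", "grp"]
    mv = MANOVA.from_formula("dv1 + dv2 ~ C(grp)", data=data)
    try:
        table = mv.mv_test().results["C(grp)"]["stat"]
        F = float(table.loc[statistic, "F Value"])
        p = float(table.loc[statistic, "Pr > F"])
    except ValueError:
        # zero between-group scatter: every test statistic degenerates
        F, p = 0.0, 1.0
    per_var = {}
    for var in dependent:
        samples = [g[var].to_numpy(dtype=float) for _, g in records.groupby(group)]
        per_var[var] = float(stats.f_oneway(*samples).pvalue)
    return ManovaResult(F, p, statistic, per_var)


# ---------------------------------------------------------------------------
# correlation


def position_magnitude_correlation(
    records: pd.DataFrame, covariate: str = "position", response: str = "mfh"
) -> tuple[float, float]:
    """Pearson r between promoter position and MFH, two-sided p."""
    x = records[covariate].to_numpy(dtype=float)
    y = records[response].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3 for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in position or magnitude")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# mismatch architecture


def mismatch_group_key(match: HSEMatch) -> MismatchGroupKey:
    """Fig-style mismatch group label, e.g. ``G 2-3``.

    The orientation letter is the first subunit's consensus (G for
    nGAAn-first, C for nTTCn-first); the numeric part is
    ``<subunit>-<position within subunit>``.
    """
    if match.hse_class == "typical" or match.mismatch is None:
        raise ValueError("typical HSEs carry no mismatch group")
    label = "G" if match.first_orientation == "GAA" else "C"
    return MismatchGroupKey(
        orientation_label=label,
        subunit_index=match.mismatch.subunit_index,
        position_in_subunit=match.mismatch.position_in_subunit,
    )


@dataclass(frozen=True)
class GroupEffect:
    group: str
    effect: float
    F: float
    p: float
    n: int
    direction: int  # sign of the group effect vs the typical baseline


def mismatch_position_effect(
    records: pd.DataFrame,
    group_col: str = "mismatch_group",
    baseline: str = "typical",
    min_group_n: int = 3,
    subunit_count: Optional[int] = 3,
) -> dict[str, GroupEffect]:
    """Per-group ANCOVA of MFH against the typical-HSE baseline.

    For each mismatch group the model ``mfh ~ is_group + position`` is
    fitted on that group pooled with the typical baseline; subunit
    number effects are excluded by restricting to 3-subunit HSEs
    (``subunit_count=None`` disables the restriction).  Groups with
    fewer than ``min_group_n`` members are skipped.
    """
    df = records
    if subunit_count is not None and "subunit_count" in df.columns:
        df = df[df["subunit_count"] == subunit_count]
    base = df[df[group_col] == baseline]
    if len(base) < min_group_n:
        raise ValueError("typical baseline too small")
    out: dict[str, GroupEffect] = {}
    for grp, sub in df[df[group_col] != baseline].groupby(group_col):
        if len(sub) < min_group_n:
            continue
        pooled = pd.concat([base, sub], ignore_index=True)
        pooled["_is_group"] = (pooled[group_col] == grp).astype(int)
        res = ancova_magnitude(pooled, factor="_is_group")
        effect = res.level_effects.get(1, 0.0)
        out[str(grp)] = GroupEffect(
            group=str(grp),
            effect=effect,
            F=res.factor_F,
            p=res.factor_p,
            n=len(sub),
            direction=int(np.sign(effect)),
        )
    return out


# ---------------------------------------------------------------------------
# Tukey pairwise nucleotide comparison + compact letter display


@dataclass(frozen=True)
class PairwiseComparison:
    levels: list
    adjusted_means: dict
    pairwise_p: pd.DataFrame  # symmetric matrix of adjusted p-values
    letters: dict  # level -> compact letter display
    method: str


def _compact_letters(levels, means, sig) -> dict:
    """Letters such that two levels share one iff not significantly
    different (maximal cliques of the non-significance graph)."""
    order = sorted(levels, key=lambda l: -means[l])
    k = len(order)
    adj = {
        (a, b): not sig[(a, b)]
        for a, b in itertools.combinations(order, 2)
    }

    def compatible(subset):
        return all(
            adj[(a, b)] for a, b in itertools.combinations(subset, 2)
        )

    cliques = []
    for r in range(k, 0, -1):
        for subset in itertools.combinations(order, r):
            if compatible(subset) and not any(
                set(subset) <= set(c) for c in cliques
            ):
                cliques.append(subset)
    letters = {lev: "" for lev in order}
    for i, clique in enumerate(cliques):
        sym = chr(ord("a") + i)
        for lev in clique:
            letters[lev] += sym
    return letters


def nucleotide_multiple_comparison(
    records: pd.DataFrame,
    level_col: str = "observed_base",
    response: str = "mfh",
    covariate: str = "position",
    alpha: float = 0.05,
    method: str = "tukey",
) -> PairwiseComparison:
    """Pairwise contrasts of MFH between mismatch nucleotides.

    Contrasts are taken on the linear predictor of the model
    ``mfh ~ C(base) + position`` (i.e. covariate-adjusted level means);
    the family-wise adjustment is Tukey single-step by default
    (``bonferroni`` and ``holm`` are also available).
    """
    levels = sorted(pd.unique(records[level_col]))
    if len(levels) < 2:
        raise ValueError("need at least two nucleotide groups")
    sizes = records[level_col].value_counts()
    if sizes.min() < 2:
        raise ValueError("every nucleotide group needs n >= 2")
    y = records[response].to_numpy(dtype=float)
    pos = records[covariate].to_numpy(dtype=float)
    fac = records[level_col].to_numpy()
    n = len(y)
    cols = [np.ones(n)]
    for lev in levels[1:]:
        cols.append((fac == lev).astype(float))
    X = np.column_stack(cols + [pos])
    beta, rss, df_resid = _fit_ols(y, X)
    sigma2 = rss / df_resid
    XtX_inv = np.linalg.inv(X.T @ X)

    # contrast vector for each level's adjusted mean (at mean position)
    mean_pos = pos.mean()
    cvec = {}
    for idx, lev in enumerate(levels):
        c = np.zeros(X.shape[1])
        c[0] = 1.0
        if idx > 0:
            c[idx] = 1.0
        c[-1] = mean_pos
        cvec[lev] = c
    adjusted_means = {lev: float(cvec[lev] @ beta) for lev in levels}

    k = len(levels)
    raw = {}
    tstats = {}
    for a, b in itertools.combinations(levels, 2):
        d = cvec[a] - cvec[b]
        se = float(np.sqrt(sigma2 * d @ XtX_inv @ d))
        t = (adjusted_means[a] - adjusted_means[b]) / se
        tstats[(a, b)] = t
        raw[(a, b)] = 2.0 * float(stats.t.sf(abs(t), df_resid))

    pairs = list(itertools.combinations(levels, 2))
    if method == "tukey":
        padj = {
            pair: float(
                stats.studentized_range.sf(
                    abs(tstats[pair]) * np.sqrt(2.0), k, df_resid
                )
            )
            for pair in pairs
        }
    elif method in ("bonferroni", "holm"):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([raw[p] for p in pairs], method=method)[1]
        padj = dict(zip(pairs, map(float, adj)))
    else:
        raise ValueError(f"unknown adjustment method {method!r}")

    mat = pd.DataFrame(np.ones((k, k)), index=levels, columns=levels)
    sig = {}
    for (a, b), p in padj.items():
        mat.loc[a, b] = mat.loc[b, a] = p
        sig[(a, b)] = sig[(b, a)] = p < alpha
    letters = _compact_letters(levels, adjusted_means, sig)
    return PairwiseComparison(
        levels=levels,
        adjusted_means=adjusted_means,
        pairwise_p=mat,
        letters=letters,
        method=method,
    )
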