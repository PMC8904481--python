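"""Factorial ANOVA, Fisher's LSD and compact-letter displays.

The analysis layout mirrors how agronomic mean-comparison tables are built:
a two-factor completely randomized design is decomposed into main effects,
interaction and error; the 15 treatment combinations are then compared as a
one-way layout of cells using the factorial model's error mean square, with
Fisher's least significant difference LSD = t(1−α/2, df_E)·√(2·MS_E/n); and
groups are annotated with letters such that sharing any letter means "not
significantly different".
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, QpcrMineError


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects two-way ANOVA decomposition.

    ``table`` has one row per source (factor_a, factor_b, interaction,
    error, total) with columns sum_sq, df, mean_sq, F, p.  F and p are NaN
    where undefined (error row, or zero error variance).
    """

    table: pd.DataFrame

    @property
    def ms_error(self) -> float:
        return float(self.table.loc["error", "mean_sq"])

    @property
    def df_error(self) -> int:
        return int(self.table.loc["error", "df"])


@dataclass(frozen=True)
class CldResult:
    """Group means annotated with LSD significance letters.

    ``groups`` rows are ordered by descending mean and carry columns
    group, mean, se, n, letters.  ``lsd`` is the critical difference in
    response units.
    """

    groups: pd.DataFrame
    lsd: float
    alpha: float


def anova_two_way(data: pd.DataFrame, factor_a: str, factor_b: str, response: str) -> AnovaResult:
    """Classical balanced two-way fixed-effects ANOVA.

    ``data`` holds replicate-level observations.  Requires a balanced
    design with at least 2 replicates per cell (an unbalanced table is
    rejected rather than silently reinterpreted; for unbalanced data use a
    model-based route instead).
    """
    counts = data.groupby([factor_a, factor_b], observed=True)[response].count()
    levels_a = data[factor_a].nunique()
    levels_b = data[factor_b].nunique()
    if len(counts) < levels_a * levels_b or (counts < 1).any():
        raise DesignError("every factor-level cell needs at least one observation")
    if counts.nunique() != 1:
        raise DesignError(
            f"unbalanced design (cell sizes {sorted(counts.unique())}); "
            "balanced cells are required"
        )
    n_rep = int(counts.iloc[0])
    if n_rep < 2:
        raise DesignError("zero error degrees of freedom: need >= 2 replicates per cell")

    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    frame = data.rename(columns={factor_a: "A", factor_b: "B", response: "y"})[
        ["A", "B", "y"]
    ].copy()
    frame["A"] = frame["A"].astype(str)
    frame["B"] = frame["B"].astype(str)
    df_a, df_b = levels_a - 1, levels_b - 1
    df_ab = df_a * df_b
    df_e = levels_a * levels_b * (n_rep - 1)
    if np.ptp(frame["y"].to_numpy(float)) == 0:
        # constant response: every SS is exactly zero, F/p undefined
        sums = [0.0, 0.0, 0.0, 0.0]
    else:
        fit = ols("y ~ C(A) * C(B)", data=frame).fit()
        # Type-I and Type-III coincide for balanced data; Type-I keeps exact sums.
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = anova_lm(fit, typ=1)
        sums = [
            raw.loc["C(A)", "sum_sq"],
            raw.loc["C(B)", "sum_sq"],
            raw.loc["C(A):C(B)", "sum_sq"],
            raw.loc["Residual", "sum_sq"],
        ]
    table = pd.DataFrame(
        {"sum_sq": sums, "df": [df_a, df_b, df_ab, df_e]},
        index=["factor_a", "factor_b", "interaction", "error"],
    )
    table["mean_sq"] = table["sum_sq"] / table["df"]
    ms_e = table.loc["error", "mean_sq"]
    df_e = table.loc["error", "df"]
    if ms_e > 0:
        table["F"] = table["mean_sq"] / ms_e
        table["p"] = stats.f.sf(table["F"], table["df"], df_e)
    else:
        table["F"] = np.nan
        table["p"] = np.nan
    table.loc["error", ["F", "p"]] = np.nan
    total = pd.DataFrame(
        {
            "sum_sq": [table["sum_sq"].sum()],
            "df": [int(table["df"].sum())],
            "mean_sq": [np.nan],
            "F": [np.nan],
            "p": [np.nan],
        },
        index=["total"],
    )
    return AnovaResult(pd.concat([table, total]))


def lsd_value(ms_error: float, df_error: int, n_per_group: float, alpha: float = 0.05) -> float:
    """Fisher's least significant difference t(1−α/2, df_E)·√(2·MS_E/n)."""
    if n_per_group <= 0:
        raise DesignError(f"n_per_group must be positive, got {n_per_group}")
    if df_error < 1:
        raise DesignError(f"df_error must be >= 1, got {df_error}")
    if not ms_error > 0:
        raise DesignError(f"ms_error must be > 0, got {ms_error}")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df_error)
    return float(t_crit * np.sqrt(2.0 * ms_error / n_per_group))


def harmonic_mean_n(counts) -> float:
    """Approximate per-group n for LSD with mildly unbalanced groups.

    The harmonic mean of the group sizes; plugging it into
    :func:`lsd_value` gives the common approximate single-LSD comparison
    for unequal replication.  It is an approximation — for seriously
    unbalanced data use per-pair t tests instead.
    """
    counts = np.asarray(list(counts), dtype=float)
    if (counts <= 0).any():
        raise DesignError("all group sizes must be positive")
    return float(len(counts) / (1.0 / counts).sum())


def lsd_pairwise(
    means: pd.Series,
    n_per_group: float,
    ms_error: float,
    df_error: int,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """All-pairs LSD verdicts: ``True`` where |mean_i − mean_j| > LSD.

    The boundary |difference| == LSD is non-significant (strict
    inequality).  Returns the symmetric boolean verdict matrix (False on
    the diagonal) and the LSD value itself.
    """
    lsd = lsd_value(ms_error, df_error, n_per_group, alpha)
    m = means.to_numpy(dtype=float)
    diff = np.abs(m[:, None] - m[None, :])
    sig = diff > lsd
    np.fill_diagonal(sig, False)
    return pd.DataFrame(sig, index=means.index, columns=means.index), lsd


def compact_letters(
    significant: pd.DataFrame,
    means: pd.Series,
    se: pd.Series | None = None,
    n: int | None = None,
    lsd: float = float("nan"),
    alpha: float = 0.05,
) -> CldResult:
    """Compact letter display over a symmetric significance-verdict matrix.

    One letter is assigned per maximal clique of the non-significance
    graph, so any two groups sharing a letter are non-significantly
    different (soundness) and every non-significant pair lies in some
    maximal clique and hence shares a letter (completeness).  LSD verdicts
    are threshold rules on ordered means, so the cliques are consecutive
    runs of the descending-mean order and the letter count is minimal —
    the familiar "a, ab, b, ..." pattern of agronomic tables.
    """
    if not significant.index.equals(significant.columns):
        raise QpcrMineError("verdict matrix must be square with matching labels")
    arr = significant.to_numpy(dtype=bool)
    if not np.array_equal(arr, arr.T):
        raise QpcrMineError("verdict matrix must be symmetric")
    if arr.diagonal().any():
        raise QpcrMineError("verdict matrix diagonal must be False (no self-difference)")

    # stable sort: ties in means keep input order
    order = sorted(range(len(means)), key=lambda i: -float(means.iloc[i]))

    nonsig = nx.Graph()
    nonsig.add_nodes_from(range(len(means)))
    for i in range(len(means)):
        for j in range(i + 1, len(means)):
            if not arr[i, j]:
                nonsig.add_edge(i, j)
    letters_sets = [set(c) for c in nx.find_cliques(nonsig)]

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    if len(letters_sets) > len(alphabet):
        raise QpcrMineError("more than 26 letters required")
    # letters named in order of first use along the descending-mean sweep
    first_use = {id(s): min(order.index(m) for m in s) for s in letters_sets}
    letters_sets.sort(key=lambda s: first_use[id(s)])
    group_letters = {g: "" for g in range(len(means))}
    for letter, members in zip(alphabet, letters_sets):
        for m in members:
            group_letters[m] += letter
    group_letters = {g: "".join(sorted(v)) for g, v in group_letters.items()}

    rows = []
    for g in order:
        rows.append(
            {
                "group": means.index[g],
                "mean": float(means.iloc[g]),
                "se": float(se.iloc[g]) if se is not None else np.nan,
                "n": n if n is not None else np.nan,
                "letters": group_letters[g],
            }
        )
    return CldResult(pd.DataFrame(rows), lsd=float(lsd), alpha=alpha)


def lsd_compare(
    data: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    response: str,
    alpha: float = 0.05,
    *,
    marginal: str | None = None,
) -> tuple[AnovaResult, CldResult]:
    """ANOVA + LSD letters for a replicate-level two-factor table.

    By default the A×B cells are compared as one one-way layout of
    (levels_a × levels_b) treatment combinations using the factorial
    model's MS_error — the layout of agronomic interaction tables.  Pass
    ``marginal="a"`` or ``"b"`` to compare a single factor's marginal means
    instead.
    """
    anova = anova_two_way(data, factor_a, factor_b, response)
    if marginal is None:
        grouped = data.groupby([factor_a, factor_b], observed=True)[response]
    elif marginal in ("a", "b"):
        grouped = data.groupby(factor_a if marginal == "a" else factor_b, observed=True)[response]
    else:
        raise DesignError(f"marginal must be None, 'a' or 'b', got {marginal!r}")
    means = grouped.mean()
    ses = grouped.std(ddof=1) / np.sqrt(grouped.count())
    n = int(grouped.count().iloc[0])
    sig, lsd = lsd_pairwise(means, n, anova.ms_error, anova.df_error, alpha)
    cld = compact_letters(sig, means, ses, n, lsd, alpha)
    return anova, cld
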