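"""Inferential toolkit: factorial ANOVA, Tukey–Kramer, correlations.

The analysis a zoometric characterization runs on grouped trait data:

* a two-factor fixed-effects ANOVA with interaction,
  ``y = A + B + A:B + e``, on (typically unbalanced) group sizes.  The
  default decomposition is Type II — each main effect is adjusted for
  the other, the interaction is tested last — which is the conventional
  choice for unbalanced observational designs; Type I (sequential) and
  Type III (sum-to-zero contrasts) are available by flag;
* Tukey's studentized-range pairwise comparison in its Tukey–Kramer
  form for unequal group sizes, with a compact letter display (groups
  share a letter iff not significantly different);
* a Pearson correlation matrix with per-pair p-values from the exact
  t transform, pairwise-complete, with optional Bonferroni/Holm
  adjustment (off by default: per-pair significance reporting is the
  norm in this literature);
* advisory normality (Shapiro–Wilk) and homoscedasticity
  (Brown–Forsythe, i.e. Levene on medians) checks.

Model fitting is ordinary least squares on dummy-coded designs via
``numpy.linalg.lstsq``; sums of squares come from residual-sum
comparisons of nested models, so the decomposition is coding-invariant
where it should be (Types I and II) and uses sum-to-zero contrasts
where it must (Type III).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateDesignError(ValueError):
    """The factorial design cannot support the requested model."""


# ---------------------------------------------------------------------------
# design-matrix helpers


def _dummy(levels: pd.Series, *, sum_to_zero: bool) -> np.ndarray:
    """Coding for one factor, reference level dropped.

    Treatment coding by default; sum-to-zero ("effects") coding assigns
    -1 to the reference level, as Type III requires.
    """
    cats = pd.Categorical(levels)
    k = len(cats.categories)
    codes = np.asarray(cats.codes)
    if (codes < 0).any():
        raise ValueError("missing factor level")
    out = np.zeros((len(codes), k - 1))
    for j in range(1, k):
        out[codes == j, j - 1] = 1.0
    if sum_to_zero:
        out[codes == 0, :] = -1.0
    return out


def _interaction(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    cols = [a[:, i] * b[:, j] for i in range(a.shape[1]) for j in range(b.shape[1])]
    return np.column_stack(cols) if cols else np.empty((len(a), 0))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


# ---------------------------------------------------------------------------
# ANOVA


@dataclass(frozen=True)
class AnovaResult:
    """Decomposition table plus bookkeeping for post hoc tests."""

    table: pd.DataFrame          # term, ss, df, ms, F, p
    ss_type: int
    residual_ms: float
    residual_df: int

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str = "biotype",
    factor_b: str = "sex",
    *,
    ss_type: int = 2,
    interaction: bool = True,
    allow_empty_cells: bool = False,
) -> AnovaResult:
    """Fixed-effects factorial ANOVA ``response = A + B + A:B + e``.

    Raises :class:`DegenerateDesignError` when a factor cell is empty
    and the interaction is requested; pass ``allow_empty_cells=True``
    (or ``interaction=False``) to fall back to main effects only.
    """
    frame = data[[response, factor_a, factor_b]].dropna()
    y = frame[response].to_numpy(dtype=float)
    n = len(y)
    levels_a = frame[factor_a].nunique()
    levels_b = frame[factor_b].nunique()
    if levels_a < 2 or levels_b < 2:
        raise DegenerateDesignError(
            "each factor needs at least two represented levels"
        )
    cells = frame.groupby([factor_a, factor_b], observed=True).size()
    if interaction and len(cells) < levels_a * levels_b:
        present = set(cells.index)
        empty = [
            (a, b)
            for a in frame[factor_a].unique()
            for b in frame[factor_b].unique()
            if (a, b) not in present
        ]
        if not allow_empty_cells:
            raise DegenerateDesignError(
                f"empty design cells {empty}: the interaction is not "
                "estimable; rerun with interaction=False or "
                "allow_empty_cells=True for a main-effects model"
            )
        interaction = False

    sum_to_zero = ss_type == 3
    ones = np.ones((n, 1))
    A = _dummy(frame[factor_a], sum_to_zero=sum_to_zero)
    B = _dummy(frame[factor_b], sum_to_zero=sum_to_zero)
    AB = _interaction(A, B) if interaction else np.empty((n, 0))

    full = np.hstack([ones, A, B, AB])
    df_a, df_b, df_ab = A.shape[1], B.shape[1], AB.shape[1]
    df_resid = n - 1 - df_a - df_b - df_ab
    if df_resid < 1:
        raise DegenerateDesignError("no residual degrees of freedom")

    rss_full = _rss(full, y)
    ss_total = float(((y - y.mean()) ** 2).sum())
    constant_response = ss_total == 0.0

    if ss_type == 1:
        rss_1 = _rss(ones, y)
        rss_1a = _rss(np.hstack([ones, A]), y)
        rss_1ab = _rss(np.hstack([ones, A, B]), y)
        ss_a = rss_1 - rss_1a
        ss_b = rss_1a - rss_1ab
        ss_ab = rss_1ab - rss_full
    elif ss_type == 2:
        # main effects adjusted for each other (marginality: models used
        # to test A or B exclude the interaction); interaction last
        rss_1b = _rss(np.hstack([ones, B]), y)
        rss_1a = _rss(np.hstack([ones, A]), y)
        rss_1ab = _rss(np.hstack([ones, A, B]), y)
        ss_a = rss_1b - rss_1ab
        ss_b = rss_1a - rss_1ab
        ss_ab = rss_1ab - rss_full
    elif ss_type == 3:
        ss_a = _rss(np.hstack([ones, B, AB]), y) - rss_full
        ss_b = _rss(np.hstack([ones, A, AB]), y) - rss_full
        ss_ab = _rss(np.hstack([ones, A, B]), y) - rss_full
    else:
        raise ValueError("ss_type must be 1, 2 or 3")

    if constant_response:
        # nothing to decompose; avoid lstsq round-off masquerading as SS
        ss_a = ss_b = ss_ab = rss_full = 0.0
    ms_resid = rss_full / df_resid
    rows = []
    terms = [(factor_a, ss_a, df_a), (factor_b, ss_b, df_b)]
    if interaction:
        terms.append((f"{factor_a}:{factor_b}", ss_ab, df_ab))
    for term, ss, df in terms:
        ss = max(ss, 0.0)  # guard tiny negative round-off
        ms = ss / df
        if ms_resid == 0:
            warnings.warn(
                f"zero residual variance: F/p undefined for {term}",
                stacklevel=2,
            )
            f_stat, p = math.nan, math.nan
        else:
            f_stat = ms / ms_resid
            p = float(stats.f.sf(f_stat, df, df_resid))
        rows.append((term, ss, df, ms, f_stat, p))
    rows.append(("residual", rss_full, df_resid, ms_resid, math.nan, math.nan))
    table = pd.DataFrame(rows, columns=["term", "ss", "df", "ms", "F", "p"])
    table.attrs["ss_total"] = ss_total
    return AnovaResult(
        table=table, ss_type=ss_type,
        residual_ms=ms_resid, residual_df=df_resid,
    )


def one_way_anova(
    data: pd.DataFrame, response: str, factor: str = "biotype"
) -> AnovaResult:
    """Single-factor ANOVA (used for biotype-only comparisons)."""
    frame = data[[response, factor]].dropna()
    y = frame[response].to_numpy(dtype=float)
    n = len(y)
    A = _dummy(frame[factor], sum_to_zero=False)
    if A.shape[1] < 1:
        raise DegenerateDesignError("factor needs at least two levels")
    ones = np.ones((n, 1))
    rss_0 = _rss(ones, y)
    rss_full = _rss(np.hstack([ones, A]), y)
    df_a = A.shape[1]
    df_resid = n - 1 - df_a
    if df_resid < 1:
        raise DegenerateDesignError("no residual degrees of freedom")
    ss_a = max(rss_0 - rss_full, 0.0)
    ms_resid = rss_full / df_resid
    if ms_resid == 0:
        f_stat, p = math.nan, math.nan
    else:
        f_stat = (ss_a / df_a) / ms_resid
        p = float(stats.f.sf(f_stat, df_a, df_resid))
    table = pd.DataFrame(
        [
            (factor, ss_a, df_a, ss_a / df_a, f_stat, p),
            ("residual", rss_full, df_resid, ms_resid, math.nan, math.nan),
        ],
        columns=["term", "ss", "df", "ms", "F", "p"],
    )
    return AnovaResult(
        table=table, ss_type=1, residual_ms=ms_resid, residual_df=df_resid
    )


# ---------------------------------------------------------------------------
# Tukey–Kramer and the compact letter display


def compact_letter_display(
    names: Sequence[str], significant: Mapping[tuple[str, str], bool]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment.

    ``significant[(a, b)]`` is True when groups a and b differ.  The
    returned letters satisfy: two groups share a letter iff their pair
    is not significant.  Works for any significance pattern (the
    algorithm splits a letter column whenever it would join a
    significant pair, then absorbs redundant columns).
    """
    columns: list[set[str]] = [set(names)]
    for a, b in itertools.combinations(names, 2):
        if not significant.get((a, b), significant.get((b, a), False)):
            continue
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop empty columns, proper subsets and duplicates
        columns = []
        for col in new_columns:
            if not col:
                continue
            if any(col < other for other in new_columns):
                continue
            if col not in columns:
                columns.append(col)
    # order columns by first member in the input ordering, label a, b, c...
    position = {name: i for i, name in enumerate(names)}
    columns.sort(key=lambda col: min(position[g] for g in col))
    letters = {name: "" for name in names}
    for letter_index, col in enumerate(columns):
        letter = chr(ord("a") + letter_index)
        for name in names:
            if name in col:
                letters[name] += letter
    return letters


@dataclass(frozen=True)
class TukeyResult:
    """Pairwise comparisons and letter groups."""

    pairs: pd.DataFrame      # group1, group2, diff, se, q, p_adj, significant
    letters: dict[str, str]
    alpha: float
    ms_resid: float
    df_resid: int


def tukey_kramer(
    groups: Mapping[str, np.ndarray],
    *,
    alpha: float = 0.05,
    ms_resid: float | None = None,
    df_resid: int | None = None,
) -> TukeyResult:
    """Tukey's range test with the Kramer unequal-n standard error.

    ``SE_ij = sqrt(MS_res / 2 * (1/n_i + 1/n_j))``, ``q = |diff| / SE``,
    adjusted p from the studentized-range distribution with parameters
    (k, df_res).  By default the residual mean square is the pooled
    within-group variance (the one-way ANOVA residual); pass
    ``ms_resid``/``df_resid`` to post-hoc a factorial fit instead.
    """
    names = list(groups)
    k = len(names)
    if k < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    sizes = {g: len(v) for g, v in arrays.items()}
    if min(sizes.values()) < 2:
        raise ValueError("each group needs at least two observations")
    means = {g: float(v.mean()) for g, v in arrays.items()}
    if ms_resid is None:
        sse = sum(float(((v - v.mean()) ** 2).sum()) for v in arrays.values())
        df_resid = sum(sizes.values()) - k
        ms_resid = sse / df_resid
    elif df_resid is None:
        raise ValueError("df_resid required when ms_resid is supplied")

    rows = []
    significant: dict[tuple[str, str], bool] = {}
    for a, b in itertools.combinations(names, 2):
        diff = means[a] - means[b]
        se = math.sqrt(ms_resid / 2.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            q = 0.0 if diff == 0 else math.inf
            p_adj = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_resid))
            p_adj = min(max(p_adj, 0.0), 1.0)
        sig = p_adj <= alpha
        significant[(a, b)] = sig
        rows.append((a, b, diff, se, q, p_adj, sig))
    pairs = pd.DataFrame(
        rows,
        columns=["group1", "group2", "diff", "se", "q", "p_adj", "significant"],
    )
    letters = compact_letter_display(names, significant)
    return TukeyResult(
        pairs=pairs, letters=letters, alpha=alpha,
        ms_resid=float(ms_resid), df_resid=int(df_resid),
    )


# ---------------------------------------------------------------------------
# Pearson correlations


@dataclass(frozen=True)
class CorrelationMatrix:
    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def pearson_matrix(
    data: pd.DataFrame,
    variables: Sequence[str] | None = None,
    *,
    adjust: str | None = None,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson r with exact-t p-values.

    ``adjust`` may be ``"bonferroni"`` or ``"holm"`` to correct the
    off-diagonal p-values for the number of pairs; default is none.
    Zero-variance variables yield NaN r/p for their pairs.
    """
    if variables is None:
        variables = [
            c for c in data.columns
            if pd.api.types.is_numeric_dtype(data[c])
        ]
    variables = list(variables)
    m = len(variables)
    r = np.eye(m)
    p = np.zeros((m, m))
    counts = np.zeros((m, m), dtype=int)
    np.fill_diagonal(counts, data[variables].notna().sum().to_numpy())
    for i, j in itertools.combinations(range(m), 2):
        pair = data[[variables[i], variables[j]]].dropna()
        n = len(pair)
        counts[i, j] = counts[j, i] = n
        if n < 3:
            r[i, j] = r[j, i] = math.nan
            p[i, j] = p[j, i] = math.nan
            continue
        x = pair.iloc[:, 0].to_numpy(dtype=float)
        y = pair.iloc[:, 1].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            r[i, j] = r[j, i] = math.nan
            p[i, j] = p[j, i] = math.nan
            continue
        rij = float(np.corrcoef(x, y)[0, 1])
        rij = min(max(rij, -1.0), 1.0)
        if abs(rij) == 1.0:
            pij = 0.0
        else:
            t = rij * math.sqrt((n - 2) / (1.0 - rij * rij))
            pij = 2.0 * float(stats.t.sf(abs(t), n - 2))
        r[i, j] = r[j, i] = rij
        p[i, j] = p[j, i] = pij
    if adjust is not None:
        p = _adjust_offdiagonal(p, method=adjust)
    index = pd.Index(variables)
    return CorrelationMatrix(
        variables=tuple(variables),
        r=pd.DataFrame(r, index=index, columns=index),
        p=pd.DataFrame(p, index=index, columns=index),
        n=pd.DataFrame(counts, index=index, columns=index),
    )


def _adjust_offdiagonal(p: np.ndarray, *, method: str) -> np.ndarray:
    m = p.shape[0]
    idx = list(itertools.combinations(range(m), 2))
    raw = np.array([p[i, j] for i, j in idx])
    finite = ~np.isnan(raw)
    adjusted = raw.copy()
    k = int(finite.sum())
    if method == "bonferroni":
        adjusted[finite] = np.minimum(raw[finite] * k, 1.0)
    elif method == "holm":
        order = np.argsort(raw[finite])
        vals = raw[finite][order] * (k - np.arange(k))
        vals = np.minimum.accumulate(vals[::-1])[::-1]  # enforce monotone
        vals = np.maximum.accumulate(np.minimum(vals, 1.0))
        out = np.empty(k)
        out[order] = vals
        adjusted[finite] = out
    else:
        raise ValueError(f"unknown adjustment {method!r}")
    q = p.copy()
    for (i, j), value in zip(idx, adjusted):
        q[i, j] = q[j, i] = value
    return q


# ---------------------------------------------------------------------------
# assumption checks


def assumption_checks(
    groups: Mapping[str, np.ndarray], *, alpha: float = 0.05
) -> pd.DataFrame:
    """Advisory normality and homoscedasticity screening.

    Shapiro–Wilk per group (n >= 3 and non-constant) plus a single
    Brown–Forsythe test (Levene on medians) across groups.  The result
    is a report, never a gate: degenerate groups are flagged, not
    fatal.
    """
    rows = []
    usable = []
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        values = values[~np.isnan(values)]
        if len(values) < 3:
            rows.append(("shapiro_wilk", name, math.nan, math.nan,
                         "too few observations"))
            continue
        if np.ptp(values) == 0:
            rows.append(("shapiro_wilk", name, math.nan, math.nan,
                         "constant group"))
            usable.append(values)
            continue
        stat, p = stats.shapiro(values)
        flag = "" if p > alpha else "non-normal"
        rows.append(("shapiro_wilk", name, float(stat), float(p), flag))
        usable.append(values)
    if len(usable) >= 2 and all(len(v) >= 2 for v in usable):
        if all(np.ptp(v) == 0 for v in usable):
            rows.append(("brown_forsythe", "all", math.nan, math.nan,
                         "all groups constant"))
        else:
            stat, p = stats.levene(*usable, center="median")
            flag = "" if p > alpha else "heteroscedastic"
            rows.append(("brown_forsythe", "all", float(stat), float(p), flag))
    return pd.DataFrame(
        rows, columns=["check", "group", "statistic", "p", "flag"]
    )
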