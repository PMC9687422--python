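"""Treatment and depth statistics: ANOVA, LSD comparisons, letter displays.

One-way ANOVA with Fisher's least-significant-difference (LSD) pairwise
comparisons drives the per-treatment significance letters; a balanced
two-factor ANOVA with interaction (warming x soil layer) reproduces the
inter-subject-effects table for the 5 x 5 x 3 study design.  Only the
balanced complete two-way layout is supported: with unbalanced data the
Type-I/II/III sums-of-squares choice changes the answer, and nothing in a
balanced field design motivates picking one, so unbalanced input is rejected.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DesignError, ValidationError


@dataclass(frozen=True)
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float | None
    f: float | None
    p: float | None


@dataclass(frozen=True)
class AnovaResult:
    """An ANOVA decomposition: ordered source rows plus model R^2."""

    rows: tuple[AnovaRow, ...]
    r_squared: float

    def row(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"source": r.source, "df": r.df, "ss": r.ss,
                 "mean_square": r.ms, "F": r.f, "p": r.p}
                for r in self.rows
            ]
        )


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(out) < 2:
        raise DesignError("need at least 2 groups")
    if any(g.size < 1 for g in out):
        raise DesignError("every group needs at least 1 value")
    return out


def one_way_anova(groups) -> AnovaResult:
    """Standard one-way decomposition: between / within / corrected total.

    F = MSB/MSW with p from the F distribution.  With zero within-group
    variance the F statistic is undefined (reported as None) unless the
    between-group SS is also zero, in which case F = 0.
    """
    gs = _as_groups(groups)
    k = len(gs)
    n_total = sum(g.size for g in gs)
    if n_total <= k:
        raise DesignError(
            f"no residual degrees of freedom (n = {n_total}, groups = {k})"
        )
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    sst = ssb + ssw
    df_b, df_w = k - 1, n_total - k
    msb, msw = ssb / df_b, ssw / df_w
    if msw > 0:
        f = msb / msw
        p = float(scipy.stats.f.sf(f, df_b, df_w))
    elif ssb == 0:
        f, p = 0.0, 1.0
    else:
        f, p = None, None
    r2 = ssb / sst if sst > 0 else 0.0
    rows = (
        AnovaRow("between", df_b, float(ssb), float(msb), f, p),
        AnovaRow("within", df_w, float(ssw), float(msw), None, None),
        AnovaRow("total_corrected", n_total - 1, float(sst), None, None, None),
    )
    return AnovaResult(rows=rows, r_squared=float(r2))


def lsd_pairwise(groups, alpha: float = 0.05, labels=None) -> dict:
    """Fisher's LSD on every group pair using the pooled within-group MS.

    A pair differs significantly when
    |mean_i - mean_j| > t_{1-alpha/2, df_w} * sqrt(MSW * (1/n_i + 1/n_j)).
    Returns ``{(label_i, label_j): bool}`` for i < j.
    """
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    gs = _as_groups(groups)
    if labels is None:
        labels = list(range(len(gs)))
    if len(labels) != len(gs):
        raise ValidationError("labels length must match number of groups")
    anova = one_way_anova(gs)
    msw, df_w = anova.row("within").ms, anova.row("within").df
    t_crit = scipy.stats.t.ppf(1 - alpha / 2, df_w)
    out = {}
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            lsd = t_crit * np.sqrt(msw * (1 / gs[i].size + 1 / gs[j].size))
            diff = abs(gs[i].mean() - gs[j].mean())
            out[(labels[i], labels[j])] = bool(diff > lsd)
    return out


def compact_letters(means: dict, sig_pairs: set) -> dict:
    """Compact letter display via insert-and-absorb.

    ``means`` maps group label -> mean (letters are ordered so that the
    largest mean gets 'a').  ``sig_pairs`` is a set of unordered significant
    pairs.  The result is exact: two groups share a letter if and only if
    their pair is NOT in ``sig_pairs``.

    Starting from one letter covering all groups, each significant pair
    splits every letter containing both members into two (one without each
    member); letters that become subsets of another are absorbed.  Splitting
    never separates a pair that was not asked to be separated, so the
    encode/decode round trip is exact.
    """
    order = sorted(means, key=lambda g: (-means[g], str(g)))
    norm_sig = set()
    for a, b in sig_pairs:
        if a not in means or b not in means:
            raise ValidationError(f"pair ({a}, {b}) references unknown group")
        if a == b:
            raise ValidationError("a group cannot differ from itself")
        norm_sig.add(frozenset((a, b)))

    letters: list[set] = [set(order)]
    for pair in sorted(norm_sig, key=lambda p: sorted(map(str, p))):
        a, b = sorted(pair, key=str)
        new_letters = []
        for letter in letters:
            if a in letter and b in letter:
                new_letters.append(letter - {a})
                new_letters.append(letter - {b})
            else:
                new_letters.append(letter)
        # absorb subsets
        new_letters = [s for s in new_letters if s]
        letters = [
            s for i, s in enumerate(new_letters)
            if not any(s < t or (s == t and i > j)
                       for j, t in enumerate(new_letters))
        ]
    # label letters 'a', 'b', ... ordered by their highest-mean member
    letters.sort(key=lambda s: min(order.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: dict = {g: [] for g in means}
    for idx, letter in enumerate(letters):
        ch = alphabet[idx] if idx < len(alphabet) else f"l{idx}"
        for g in letter:
            assigned[g].append(ch)
    return {g: "".join(sorted(chs)) for g, chs in assigned.items()}


def two_way_anova_balanced(values, factor_a: str = "warming",
                           factor_b: str = "soil_layer") -> AnovaResult:
    """Balanced two-factor ANOVA with interaction on an a x b x r array.

    ``values[i, j, k]`` is replicate k of factor-A level i and factor-B
    level j.  For a balanced complete design the df are a-1, b-1,
    (a-1)(b-1), ab(r-1) with corrected total abr-1, and the sums of squares
    are unambiguous.  Fitting goes through an OLS two-factor model with
    interaction; R^2 = 1 - SSE/SST.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 3:
        raise DesignError(
            "expected a balanced a x b x r array; for unbalanced designs "
            "use one_way_anova per factor instead"
        )
    a, b, r = arr.shape
    if a < 2 or b < 2:
        raise DesignError("both factors need at least 2 levels")
    if r < 2:
        raise DesignError("balanced two-way ANOVA needs r >= 2 replicates")
    if not np.isfinite(arr).all():
        raise DesignError("missing cells: design must be balanced and complete")

    ai, bi, _ = np.meshgrid(np.arange(a), np.arange(b), np.arange(r),
                            indexing="ij")
    data = pd.DataFrame({
        "y": arr.ravel(),
        "fa": ai.ravel().astype(str),
        "fb": bi.ravel().astype(str),
    })
    model = smf.ols("y ~ C(fa) * C(fb)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)

    def _row(source, key):
        df = int(table.loc[key, "df"])
        ss = float(table.loc[key, "sum_sq"])
        ms = ss / df
        if key == "Residual":
            return AnovaRow(source, df, ss, ms, None, None)
        fval = float(table.loc[key, "F"])
        pval = float(table.loc[key, "PR(>F)"])
        return AnovaRow(source, df, ss, ms, fval, pval)

    rows = [
        _row(factor_a, "C(fa)"),
        _row(factor_b, "C(fb)"),
        _row(f"{factor_a} * {factor_b}", "C(fa):C(fb)"),
        _row("error", "Residual"),
    ]
    sst = sum(row.ss for row in rows)
    rows.append(AnovaRow("total_corrected", a * b * r - 1, float(sst),
                         None, None, None))
    return AnovaResult(rows=tuple(rows), r_squared=float(model.rsquared))


def write_anova_report(result: AnovaResult, path) -> None:
    """CSV report mirroring an inter-subject-effects table."""
    result.to_frame().rename(columns={"ss": "sum_of_squares"}).to_csv(
        path, index=False, na_rep=""
    )
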