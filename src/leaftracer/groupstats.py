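"""Group-comparison statistics: ANOVA + Tukey compact letters, t-tests.

Means across leaf ranks are compared with one-way ANOVA followed by Tukey's
HSD post-hoc test, summarised as a compact letter display (groups sharing a
letter are not significantly different at alpha).  Paired conditions
(light/dark, control/stress) are compared with two-sided equal-variance
Student t-tests.  Relative expression values are log-transformed before
testing to approximate normality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class TukeyLetters:
    """Result of one-way ANOVA + Tukey HSD with compact letter display."""

    anova_f: float
    anova_p: float
    letters: dict[str, str]  # group -> letter code, e.g. "a", "ab"
    pairwise: pd.DataFrame  # group1, group2, p_adj, significant
    alpha: float


def _compact_letter_display(
    groups: list[str], sig_pairs: set[frozenset], alphabet: str = "abcdefghijklmnopqrstuvwxyz"
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Builds letter sets such that two groups share a letter iff their pair is
    not in ``sig_pairs``.  Groups are processed in the given (stable) order;
    the letters themselves are arbitrary labels, only the sharing pattern is
    meaningful.
    """
    # each letter is a set of group indices that may share it
    letter_sets: list[set[int]] = [set(range(len(groups)))] if groups else []
    index = {g: i for i, g in enumerate(groups)}

    for g1, g2 in sorted(
        (tuple(sorted(p)) for p in sig_pairs), key=lambda p: (index[p[0]], index[p[1]])
    ):
        i, j = index[g1], index[g2]
        for s in [s for s in letter_sets if i in s and j in s]:
            # split the violating letter into two, then absorb duplicates
            letter_sets.remove(s)
            s1 = s - {j}
            s2 = s - {i}
            for new in (s1, s2):
                if new and not any(new <= other for other in letter_sets):
                    letter_sets.append(new)
            # absorb: drop any set contained in another
            letter_sets = [
                s for s in letter_sets if not any(s < other for other in letter_sets)
            ]

    # order letters by their first group so that output reads naturally
    letter_sets.sort(key=lambda s: min(s))
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for i in sorted(s):
            out[groups[i]] += letter
    return out


def anova_tukey_letters(
    data: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "value",
    alpha: float = 0.05,
    log_transform: bool = False,
) -> TukeyLetters:
    """One-way ANOVA, Tukey HSD pairwise p-values and compact letters.

    ``data`` is tidy (one row per replicate).  Every group needs at least two
    replicates for the pooled variance.  With ``log_transform`` the values are
    natural-log transformed first (used for relative expression).
    """
    df = data[[group_col, value_col]].dropna()
    if log_transform:
        df = df.assign(**{value_col: log_transform_expression(df[value_col].to_numpy())})
    groups = list(dict.fromkeys(df[group_col]))  # stable order of appearance
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    samples = [df.loc[df[group_col] == g, value_col].to_numpy(dtype=float) for g in groups]
    for g, s in zip(groups, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has {len(s)} replicate(s); >= 2 required")

    f_stat, p_val = stats.f_oneway(*samples)

    tukey = pairwise_tukeyhsd(
        endog=df[value_col].to_numpy(dtype=float),
        groups=df[group_col].to_numpy(),
        alpha=alpha,
    )
    pw = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )[["group1", "group2", "p-adj"]].rename(columns={"p-adj": "p_adj"})
    # recover full-precision p-values (the summary table rounds)
    pw["p_adj"] = tukey.pvalues
    pw["significant"] = pw["p_adj"] < alpha

    sig_pairs = {
        frozenset((str(r.group1), str(r.group2)))
        for r in pw.itertuples()
        if r.significant
    }
    letters = _compact_letter_display([str(g) for g in groups], sig_pairs)
    return TukeyLetters(
        anova_f=float(f_stat),
        anova_p=float(p_val),
        letters=letters,
        pairwise=pw,
        alpha=alpha,
    )


def two_sample_t(
    a: np.ndarray, b: np.ndarray, alpha: float = 0.05
) -> tuple[float, bool]:
    """Two-sided pooled-variance Student t-test; returns (p-value, significant).

    Degenerate zero-variance inputs follow the conventions: equal means give
    p = 1, different means give p = 0 (flagged significant).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        return p, p < alpha
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue), bool(res.pvalue < alpha)


def log_transform_expression(values: np.ndarray) -> np.ndarray:
    """Natural-log transform of positive expression values (errors otherwise)."""
    arr = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("log transform requires strictly positive finite values")
    return np.log(arr)
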