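"""Shared statistical utilities: Welch tests, BH adjustment, ANOVA + Tukey
HSD with compact letter displays.

The tests themselves are delegated to scipy/statsmodels; only the compact
letter display (the "shared letter = not significantly different"
annotation used on boxplots) is implemented here, using the standard
insert-and-absorb algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

STAR_THRESHOLDS = ((0.01, "***"), (0.05, "**"), (0.1, "*"))


def stars(q: float) -> str:
    """Significance stars at adjusted-p thresholds 0.1 / 0.05 / 0.01."""
    if not np.isfinite(q):
        return ""
    for thr, s in STAR_THRESHOLDS:
        if q < thr:
            return s
    return ""


def welch_t(
    a: Sequence[float],
    b: Sequence[float] | None = None,
    popmean: float = 0.0,
    alternative: str = "two-sided",
) -> float:
    """Welch t-test p-value of ``a`` vs ``b`` (or vs ``popmean`` if b is None)."""
    a = np.asarray(a, dtype=float)
    if b is None or len(b) == 0:
        res = sps.ttest_1samp(a, popmean, alternative=alternative)
    else:
        res = sps.ttest_ind(a, np.asarray(b, dtype=float), equal_var=False,
                            alternative=alternative)
    p = float(res.pvalue)
    return p if np.isfinite(p) else 1.0


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaNs pass through)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def compact_letters(
    labels: Sequence[str], different: Mapping[tuple, bool]
) -> dict[str, str]:
    """Compact letter display from a pairwise "significantly different" map.

    Groups sharing at least one letter are not significantly different.
    Implements insert-and-absorb: start with one letter column containing
    every group; for each significant pair that still shares a column,
    split the column in two (one without each member) and absorb duplicate
    columns.
    """
    columns: list[set] = [set(labels)]
    for (a, b), diff in sorted(different.items()):
        if not diff:
            continue
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                ca, cb = col - {b}, col - {a}
                for new in (ca, cb):
                    if not any(new <= other for other in columns):
                        columns.append(new)
        # absorb columns that became subsets of others
        columns = [c for c in columns
                   if not any(c < other for other in columns)]
    # deterministic letter order: by first (alphabetical) member
    columns.sort(key=lambda c: sorted(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, list[str]] = {lab: [] for lab in labels}
    for letter, col in zip(alphabet, columns):
        for lab in sorted(col):
            out[lab].append(letter)
    return {lab: "".join(ls) if ls else "?" for lab, ls in out.items()}


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD post hoc and a compact letter display."""

    anova_p: float
    pairwise: dict  # (group_a, group_b) -> Tukey adjusted p
    letters: dict  # group -> letter string
    degenerate: bool = False  # zero within-group variance everywhere


def anova_tukey(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaTukeyResult:
    """One-way ANOVA followed by Tukey HSD at 95% confidence.

    ``groups`` maps condition labels to replicate values (each with >= 2
    values).  When every group has zero variance the parametric tests are
    undefined; the result is flagged degenerate and the letters are built
    from exact ties instead.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    for k, arr in zip(labels, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")

    if all(np.ptp(a) == 0 for a in arrays):
        means = {k: float(a[0]) for k, a in zip(labels, arrays)}
        different = {
            (a, b): means[a] != means[b]
            for i, a in enumerate(labels)
            for b in labels[i + 1:]
        }
        return AnovaTukeyResult(
            anova_p=float("nan"),
            pairwise={k: (0.0 if d else 1.0) for k, d in different.items()},
            letters=compact_letters(labels, different),
            degenerate=True,
        )

    anova_p = float(sps.f_oneway(*arrays).pvalue)
    tk = sps.tukey_hsd(*arrays)
    pairwise = {}
    different = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            p = float(tk.pvalue[i, j])
            pairwise[(a, b)] = p
            different[(a, b)] = p < alpha
    return AnovaTukeyResult(anova_p, pairwise, compact_letters(labels, different))
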