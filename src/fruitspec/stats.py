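"""Ripening-stage statistics: one-way ANOVA, Duncan's multiple range test
with compact letter display, descriptive summaries and trait correlations.

Duncan's test compares the ordered group means with stepwise studentized-range
critical values.  For a span of p consecutive ordered means the protection
level is alpha_p = 1 - (1 - alpha)**(p - 1); the critical range is

    R_p = q(1 - alpha_p, p, df_error) * sqrt(MS_within / n_h)

with n_h the harmonic mean of the span's group sizes (Kramer adjustment for
unbalanced groups).  Two groups differ iff some significant range separates
them once larger non-significant spans have been honoured; letters follow the
agronomy convention that the largest mean is lettered "a".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spectra import STAGES, TraitTable

__all__ = [
    "AnovaResult",
    "DuncanResult",
    "anova_oneway",
    "duncan_mrt",
    "describe_by_stage",
    "pearson_matrix",
]


@dataclass
class AnovaResult:
    """Classical one-way ANOVA decomposition."""

    F: float
    p: float
    ms_between: float
    ms_within: float
    df_between: int
    df_error: int
    ss_between: float
    ss_within: float
    ss_total: float


@dataclass
class DuncanResult:
    """Duncan's multiple range test outcome.

    ``letters`` maps each group label to its letter string; groups sharing a
    letter are not significantly different at ``alpha``.
    """

    group_means: dict[str, float]  # insertion order: descending mean
    group_sizes: dict[str, int]
    ms_within: float
    df_error: int
    alpha: float
    letters: dict[str, str]


def _group_arrays(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    out: dict[str, np.ndarray] = {}
    for g in groups:
        if g not in out:
            out[g] = values[groups == g]
    return out


def anova_oneway(values, groups) -> AnovaResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within.

    Degenerate cases: all observations identical gives F = NaN; separated
    means with zero within-group variance gives F = inf and p = 0.
    """
    by_group = _group_arrays(values, groups)
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    v = np.asarray(values, dtype=float)
    n = v.size
    k = len(by_group)
    if n - k < 1:
        raise ValueError("no error degrees of freedom")
    grand = v.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in by_group.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in by_group.values())
    ss_total = ((v - grand) ** 2).sum()
    df_b, df_e = k - 1, n - k
    ms_b, ms_w = ss_between / df_b, ss_within / df_e
    if ms_w > 0:
        F = ms_b / ms_w
        p = float(sps.f.sf(F, df_b, df_e))
    elif ms_b > 0:
        F, p = np.inf, 0.0
    else:
        F, p = np.nan, np.nan  # all values identical: F undefined
    return AnovaResult(F=float(F), p=p, ms_between=float(ms_b), ms_within=float(ms_w),
                       df_between=df_b, df_error=df_e, ss_between=float(ss_between),
                       ss_within=float(ss_within), ss_total=float(ss_total))


def _duncan_critical_range(p_span: int, df_error: int, alpha: float,
                           ms_within: float, n_harmonic: float) -> float:
    alpha_p = 1.0 - (1.0 - alpha) ** (p_span - 1)
    q = sps.studentized_range.ppf(1.0 - alpha_p, p_span, df_error)
    return float(q * np.sqrt(ms_within / n_harmonic))


def _nonsignificant_spans(means: np.ndarray, sizes: np.ndarray, ms_within: float,
                          df_error: int, alpha: float) -> set[tuple[int, int]]:
    """Set of (i, j) spans of the descending-sorted means declared
    non-significant, honouring the containment protection rule: a span inside
    a non-significant larger span is itself non-significant."""
    g = means.size
    ns: set[tuple[int, int]] = set()
    for length in range(g, 1, -1):
        for i in range(0, g - length + 1):
            j = i + length - 1
            if any(a <= i and j <= b for a, b in ns):
                ns.add((i, j))
                continue
            n_h = length / np.sum(1.0 / sizes[i:j + 1])
            if ms_within == 0:
                significant = means[i] != means[j]
            else:
                rp = _duncan_critical_range(length, df_error, alpha, ms_within, n_h)
                significant = (means[i] - means[j]) > rp
            if not significant:
                ns.add((i, j))
    return ns


def _letters_from_spans(g: int, ns: set[tuple[int, int]]) -> list[str]:
    """Compact letter display from maximal non-significant spans (means are
    index-ordered descending, so index 0 receives 'a')."""
    maximal = [
        (i, j) for (i, j) in ns
        if not any((a <= i and j <= b and (a, b) != (i, j)) for a, b in ns)
    ]
    covered = {x for i, j in maximal for x in range(i, j + 1)}
    for i in range(g):
        if i not in covered:
            maximal.append((i, i))
    maximal.sort()
    letters = [""] * g
    for rank, (i, j) in enumerate(maximal):
        if rank >= 26:
            raise ValueError("more than 26 letter groups")
        ch = chr(ord("a") + rank)
        for x in range(i, j + 1):
            letters[x] += ch
    return letters


def duncan_mrt(values, groups, alpha: float = 0.05) -> DuncanResult:
    """Duncan's multiple range test at protection level ``alpha``.

    Returns letters per group; the largest mean is lettered "a".
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    by_group = _group_arrays(values, groups)
    anova = anova_oneway(values, groups)
    if anova.df_error < 1:
        raise ValueError("Duncan's test requires at least 1 error df")
    labels = list(by_group)
    means = np.array([by_group[g].mean() for g in labels])
    sizes = np.array([by_group[g].size for g in labels], dtype=float)
    order = np.argsort(-means, kind="stable")
    labels = [labels[i] for i in order]
    means, sizes = means[order], sizes[order]
    ns = _nonsignificant_spans(means, sizes, anova.ms_within, anova.df_error, alpha)
    letters = _letters_from_spans(means.size, ns)
    return DuncanResult(
        group_means={lab: float(m) for lab, m in zip(labels, means)},
        group_sizes={lab: int(s) for lab, s in zip(labels, sizes)},
        ms_within=anova.ms_within,
        df_error=anova.df_error,
        alpha=alpha,
        letters=dict(zip(labels, letters)),
    )


def describe_by_stage(t: TraitTable, trait: str, alpha: float = 0.05) -> pd.DataFrame:
    """Per-stage Min/Max/Mean/SD/n summary with Duncan letters.

    SD is the sample standard deviation (ddof=1); a single-sample stage
    reports SD 0 with a warning.  Stages appear in ripening order.
    """
    y = t.values(trait)
    stage = t.stage_array()
    present = [s for s in STAGES if np.any(stage == s)]
    if not present:
        raise ValueError("no stage labels present")
    missing = set(STAGES) - set(present)
    if missing:
        warnings.warn(f"stages absent from data: {sorted(missing)}", stacklevel=2)

    letters: dict[str, str] = {s: "" for s in present}
    if len(present) >= 2 and np.sum(np.isin(stage, present)) - len(present) >= 1:
        mask = np.isin(stage, present)
        letters.update(duncan_mrt(y[mask], stage[mask], alpha=alpha).letters)

    rows = []
    for s in present:
        vals = y[stage == s]
        if vals.size == 1:
            warnings.warn(f"stage {s!r} has a single sample; SD reported as 0",
                          stacklevel=2)
            sd = 0.0
        else:
            sd = float(np.std(vals, ddof=1))
        rows.append({
            "stage": s, "min": float(vals.min()), "max": float(vals.max()),
            "mean": float(vals.mean()), "sd": sd, "n": int(vals.size),
            "letter": letters[s],
        })
    out = pd.DataFrame(rows)
    out.insert(0, "trait", trait)
    return out


def pearson_matrix(t: TraitTable) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix of all traits (unit diagonal).

    Zero-variance traits have their row and column flagged NaN (diagonal
    included), since r is undefined for them.
    """
    if t.n_samples < 3:
        raise ValueError("need at least 3 samples")
    names = t.trait_names
    M = np.column_stack([t.values(n) for n in names])
    sd = M.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(M, rowvar=False)
    corr = np.atleast_2d(corr)
    degenerate = sd == 0
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, np.where(degenerate, np.nan, 1.0))
    return pd.DataFrame(corr, index=names, columns=names)
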