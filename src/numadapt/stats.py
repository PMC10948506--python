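"""Inferential machinery: paired sign-flip permutation tests, BH-FDR,
two-way repeated-measures ANOVA with Greenhouse-Geisser correction,
Bonferroni post-hocs, Spearman correlation, and the adaptation-percentage
statistic.

Permutation scheme for paired two-condition data: participant-level sign
flipping of within-participant difference vectors (equivalent to exchanging
condition labels within participant).  The statistic is the paired t on the
differences; the two-sided Monte-Carlo p-value is (1 + #{|t_perm| >=
|t_obs|}) / (n_permutations + 1), so p is never zero.  When 2**n does not
exceed the permutation budget the null is enumerated exhaustively and the
p-value is exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CONDITIONS, NUMEROSITIES

__all__ = [
    "paired_permutation_test",
    "fdr_bh",
    "rm_anova_gg",
    "bonferroni_posthoc",
    "adaptation_percentage",
    "spearman_correlation",
    "cell_means",
]


def _t_from_signs(signs: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Paired t for every sign pattern: signs (P, n), d (n, F) -> (P, F)."""
    n = d.shape[0]
    mean = signs @ d / n
    ssq = np.sum(d**2, axis=0)  # invariant under sign flips
    var = np.maximum(ssq[None, :] - n * mean**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
        zero_var = var <= 0
        tz = np.sign(mean[zero_var]) * np.inf
    tz[np.isnan(tz)] = 0.0
    t[zero_var] = tz
    return t


def _count_as_extreme(t_perm: np.ndarray, t_obs: np.ndarray) -> np.ndarray:
    """#{|t_perm| >= |t_obs|} per feature, robust to float rounding of ties
    (the identity and global-flip permutations reproduce +/-t_obs exactly,
    so tie handling must not depend on last-bit noise)."""
    thresh = np.abs(t_obs) * (1.0 - 1e-12) - 1e-12
    return np.sum(np.abs(t_perm) >= thresh[None, :], axis=0)


def paired_permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_permutations: int = 15000,
    seed: "int | np.random.Generator | None" = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided paired sign-flip permutation test, feature-wise.

    ``values_a``/``values_b``: (n_participants,) or (n_participants,
    n_features), participant-paired.  Returns (t_obs, p) with the feature
    axis preserved (scalars for 1-D input).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have identical shape")
    scalar = a.ndim == 1
    d = (a - b).reshape(a.shape[0], -1)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    if not np.all(np.isfinite(d)):
        raise ValueError("missing/non-finite condition values")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")

    t_obs = _t_from_signs(np.ones((1, n)), d)[0]
    if 2**n <= n_permutations:
        # exhaustive enumeration: exact p over all 2^n sign patterns
        bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
        signs = 1.0 - 2.0 * bits
        t_perm = _t_from_signs(signs, d)
        p = _count_as_extreme(t_perm, t_obs) / 2.0**n
    else:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        t_perm = _t_from_signs(signs, d)
        p = (1.0 + _count_as_extreme(t_perm, t_obs)) / (n_permutations + 1.0)
    if scalar:
        return float(t_obs[0]), float(p[0])
    return t_obs, p


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and significance mask.

    adjusted_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1;
    mask = adjusted <= q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat, kind="stable")
    ranked = flat[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    out = out.reshape(p.shape)
    return out, out <= q


def cell_means(behavior: pd.DataFrame) -> pd.DataFrame:
    """Per-participant (adaptation x numerosity) mean estimates, long format."""
    return (
        behavior.groupby(["participant", "adaptation", "true_numerosity"])["estimate"]
        .mean()
        .rename("value")
        .reset_index()
        .rename(columns={"true_numerosity": "numerosity"})
    )


def _pivot_cells(table: pd.DataFrame) -> tuple[np.ndarray, list, list, list]:
    """Balanced (n_subj, a, b) array from a long participant/adaptation/
    numerosity/value table; missing cells are rejected."""
    required = {"participant", "adaptation", "numerosity", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    subjects = sorted(table["participant"].unique())
    a_levels = [c for c in CONDITIONS if c in set(table["adaptation"])]
    b_levels = sorted(table["numerosity"].unique())
    wide = table.pivot_table(
        index="participant",
        columns=["adaptation", "numerosity"],
        values="value",
        aggfunc="mean",
    )
    try:
        cols = pd.MultiIndex.from_product([a_levels, b_levels])
        wide = wide.reindex(index=subjects, columns=cols)
    except KeyError as err:  # pragma: no cover
        raise ValueError("incomplete design") from err
    if wide.isna().any().any():
        raise ValueError("missing cell in the repeated-measures table")
    y = wide.to_numpy().reshape(len(subjects), len(a_levels), len(b_levels))
    return y, subjects, a_levels, b_levels


def _gg_epsilon(scores: np.ndarray, contrasts: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the covariance of contrast scores.

    ``scores``: (n_subj, k) repeated measurements; ``contrasts``: (k, d)
    orthonormal contrast matrix for the effect (d = effect df).
    epsilon = tr(S)^2 / (d * tr(S^2)) with S = C' Sigma C, bounded to
    [1/d, 1].
    """
    sigma = np.cov(scores, rowvar=False)
    s = contrasts.T @ sigma @ contrasts
    d = contrasts.shape[1]
    eps = np.trace(s) ** 2 / (d * np.sum(s**2))
    return float(np.clip(eps, 1.0 / d, 1.0))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal contrasts spanning the deviation space."""
    c = np.eye(k) - 1.0 / k
    u, s, _ = np.linalg.svd(c)
    return u[:, : k - 1]


def rm_anova_gg(table: pd.DataFrame) -> dict:
    """Two-way within-subjects ANOVA (Adaptation x Numerosity) with
    Greenhouse-Geisser correction and partial eta squared.

    ``table``: long format with columns participant, adaptation, numerosity,
    value (one value per cell per participant; trial-level input should be
    collapsed with :func:`cell_means` first).  Returns a dict keyed by
    effect name with F, df1, df2 (uncorrected), eps, p (GG-corrected), and
    eta_p2.
    """
    y, subjects, a_levels, b_levels = _pivot_cells(table)
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_subj = a * b * np.sum((m_s - grand) ** 2)
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)

    effects = {}
    for name, ss_eff, ss_err, df1, scores, contrasts in [
        ("Adaptation", ss_a, ss_as, a - 1, m_sa, ca),
        ("Numerosity", ss_b, ss_bs, b - 1, m_sb, cb),
        (
            "Adaptation x Numerosity",
            ss_ab,
            ss_abs,
            (a - 1) * (b - 1),
            y.reshape(n, a * b),
            np.kron(ca, cb),
        ),
    ]:
        df2 = df1 * (n - 1)
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        f_val = ms_eff / ms_err if ms_err > 0 else np.inf
        eps = 1.0 if df1 == 1 else _gg_epsilon(scores, contrasts)
        p = float(sps.f.sf(f_val, eps * df1, eps * df2))
        effects[name] = {
            "F": float(f_val),
            "df1": df1,
            "df2": df2,
            "eps": eps,
            "p": p,
            "eta_p2": float(ss_eff / (ss_eff + ss_err)) if ss_eff + ss_err > 0 else 0.0,
        }
    return effects


def bonferroni_posthoc(
    table: pd.DataFrame,
    comparisons: "list[tuple[tuple, tuple]] | None" = None,
) -> pd.DataFrame:
    """Paired-t post-hocs with Bonferroni adjustment.

    ``table`` is the long cell-mean table (see :func:`rm_anova_gg`); each
    comparison pairs two (adaptation, numerosity) cells.  Default: High vs
    Low within every numerosity.  Adjusted p = raw p x n_comparisons,
    capped at 1.
    """
    y, subjects, a_levels, b_levels = _pivot_cells(table)
    if comparisons is None:
        comparisons = [
            (("High", num), ("Low", num)) for num in b_levels
        ]
    if not comparisons:
        raise ValueError("need at least one comparison")

    def cell(cond, num):
        return y[:, a_levels.index(cond), b_levels.index(num)]

    rows = []
    m = len(comparisons)
    for (ca_, na_), (cb_, nb_) in comparisons:
        t, p = sps.ttest_rel(cell(ca_, na_), cell(cb_, nb_))
        rows.append(
            {
                "cell_a": f"{ca_}:{na_}",
                "cell_b": f"{cb_}:{nb_}",
                "t": float(t),
                "p_raw": float(p),
                "p_adj": float(min(1.0, p * m)),
            }
        )
    return pd.DataFrame(rows)


def adaptation_percentage(behavior: pd.DataFrame) -> dict:
    """Percentage of adaptation: (mean Low - mean High estimate) / true x 100.

    Computed per participant and numerosity, then averaged (unweighted) over
    numerosities per participant; the group statistics average over
    participants.  Returns per-participant overall values, group-mean
    per-numerosity values, and the group-mean overall percentage.
    """
    cells = cell_means(behavior)
    wide = cells.pivot_table(
        index="participant", columns=["adaptation", "numerosity"], values="value"
    )
    numerosities = sorted({num for (_, num) in wide.columns})
    for cond in CONDITIONS:
        for num in numerosities:
            if (cond, num) not in wide.columns or wide[(cond, num)].isna().any():
                raise ValueError(f"empty cell: {cond} x {num}")
    per_pn = np.column_stack(
        [
            100.0 * (wide[("Low", num)] - wide[("High", num)]) / num
            for num in numerosities
        ]
    )  # (n_participants, n_numerosities)
    per_participant = per_pn.mean(axis=1)
    return {
        "participants": [int(p) for p in wide.index],
        "numerosities": [int(n) for n in numerosities],
        "per_participant": per_participant,
        "per_numerosity": per_pn.mean(axis=0),
        "overall": float(per_participant.mean()),
    }


def spearman_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(sps.rankdata(x)) == 0 or np.ptp(sps.rankdata(y)) == 0:
        raise ValueError("zero variance in ranks: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
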