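"""Balanced mixed-design ANOVA with sphericity correction.

Classical univariate ANOVA for fully crossed, balanced designs with any
number of between-participant and within-participant factors: sums of
squares via the inclusion-exclusion computing formulas, error strata per
within-effect (the effect x subjects-within-groups interaction),
Greenhouse-Geisser epsilon for within effects, and generalized
eta-squared (effect SS over effect SS plus all subject-related error SS,
the convention for designs where all factors are manipulated).
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["mixed_anova", "AnovaTable"]

AnovaTable = pd.DataFrame  # effect, SS, df1, df2, F, p, ges, eps, df1_gg, df2_gg, p_gg


def _t_term(data: pd.DataFrame, dv: str, factors: Sequence[str]) -> float:
    """Computing-formula term: sum over groups of (group sum)^2 / group size."""
    if not factors:
        total = data[dv].sum()
        return float(total * total / len(data))
    g = data.groupby(list(factors), observed=True)[dv]
    return float((g.sum() ** 2 / g.size()).sum())


def _ss_from_terms(data, dv, effect: tuple[str, ...]) -> float:
    ss = 0.0
    for r in range(len(effect) + 1):
        for sub in itertools.combinations(effect, r):
            ss += (-1) ** (len(effect) - r) * _t_term(data, dv, sub)
    return ss


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis of the centered subspace."""
    c = np.eye(k) - 1.0 / k
    q, r = np.linalg.qr(c)
    # keep the k-1 columns with nonzero diagonal in r
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep]


def _gg_epsilon(
    wide: np.ndarray, groups: np.ndarray, within_levels: Sequence[int],
    effect_axes: Sequence[int],
) -> float:
    """Greenhouse-Geisser epsilon for one within effect.

    ``wide`` is subjects x all-within-cells (cells in itertools.product
    order of the within factors); cells are first averaged over within
    factors not in the effect, then the effect's contrast space is
    applied to the pooled within-group covariance.
    """
    n_sub = wide.shape[0]
    arr = wide.reshape((n_sub, *within_levels))
    for ax in sorted(range(len(within_levels)), reverse=True):
        if ax not in effect_axes:
            arr = arr.mean(axis=ax + 1)
    y = arr.reshape(n_sub, -1)
    # center within between-groups, pool the covariance
    centered = np.empty_like(y)
    n_groups = 0
    for g in np.unique(groups):
        m = groups == g
        centered[m] = y[m] - y[m].mean(axis=0)
        n_groups += 1
    v = centered.T @ centered / max(n_sub - n_groups, 1)
    mats = [_orthonormal_contrasts(within_levels[ax]) for ax in sorted(effect_axes)]
    m_ = mats[0]
    for extra in mats[1:]:
        m_ = np.kron(m_, extra)
    s = m_.T @ v @ m_
    d = s.shape[0]
    tr = np.trace(s)
    tr2 = np.trace(s @ s)
    if tr2 <= 0.0:
        return 1.0
    eps = tr * tr / (d * tr2)
    return float(np.clip(eps, 1.0 / d, 1.0))


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str] = (),
    between: Sequence[str] = (),
    subject: str = "participant",
) -> AnovaTable:
    """Mixed-design ANOVA on a balanced long-format table of cell means.

    ``data`` must hold exactly one row per subject x within-cell, with
    subjects nested in the between cells.  Returns one row per effect
    with uncorrected and Greenhouse-Geisser-corrected tests and
    generalized eta-squared.
    """
    within = list(within)
    between = list(between)
    if not within and not between:
        raise ValueError("need at least one factor")
    data = data.copy()

    w_levels = {f: sorted(data[f].unique()) for f in within}
    subjects = data[[subject] + between].drop_duplicates()
    if subjects[subject].duplicated().any():
        raise ValueError("subjects must be nested within between-participant cells")
    n_sub = len(subjects)
    n_cells_w = int(np.prod([len(w_levels[f]) for f in within])) if within else 1
    n_cells_b = int(np.prod([data[f].nunique() for f in between])) if between else 1
    counts = data.groupby([subject] + within, observed=True).size() if within else data.groupby(subject).size()
    if len(data) != n_sub * n_cells_w or counts.nunique() != 1 or counts.iloc[0] != 1:
        raise ValueError("design is unbalanced: need one value per subject x within-cell")

    # wide subject x within-cell matrix in product order, for epsilon
    if within:
        idx = data.set_index([subject] + within)[dv]
        order = list(itertools.product(*[w_levels[f] for f in within]))
        wide = np.array(
            [[idx.loc[(s, *cell) if within else s] for cell in order]
             for s in subjects[subject]]
        )
    else:
        wide = data.set_index(subject).loc[subjects[subject], dv].to_numpy()[:, None]
    group_labels = (
        subjects[between].astype(str).agg("|".join, axis=1).to_numpy()
        if between else np.zeros(n_sub)
    )

    # error strata: one per within-effect subset (incl. the empty one)
    err_ss: dict[tuple[str, ...], float] = {}
    err_df: dict[tuple[str, ...], float] = {}
    for r in range(len(within) + 1):
        for wsub in itertools.combinations(within, r):
            ss = 0.0
            for r2 in range(len(wsub) + 1):
                for s2 in itertools.combinations(wsub, r2):
                    sign = (-1) ** (len(wsub) - r2)
                    ss += sign * (
                        _t_term(data, dv, (subject,) + s2)
                        - _t_term(data, dv, tuple(between) + s2)
                    )
            err_ss[wsub] = ss
            err_df[wsub] = np.prod([len(w_levels[f]) - 1 for f in wsub]) * (n_sub - n_cells_b)
    total_error_ss = sum(err_ss.values())

    rows = []
    factors = between + within
    for r in range(1, len(factors) + 1):
        for effect in itertools.combinations(factors, r):
            w_eff = tuple(f for f in effect if f in within)
            ss = _ss_from_terms(data, dv, effect)
            df1 = float(np.prod([
                (data[f].nunique() if f in between else len(w_levels[f])) - 1 for f in effect
            ]))
            df2 = float(err_df[w_eff])
            mse = err_ss[w_eff] / df2 if df2 > 0 else np.nan
            f_val = (ss / df1) / mse if mse and mse > 0 else np.nan
            p = float(stats.f.sf(f_val, df1, df2)) if np.isfinite(f_val) else np.nan
            if w_eff:
                axes = [within.index(f) for f in w_eff]
                eps = _gg_epsilon(wide, group_labels, [len(w_levels[f]) for f in within], axes)
            else:
                eps = 1.0
            p_gg = (
                float(stats.f.sf(f_val, df1 * eps, df2 * eps)) if np.isfinite(f_val) else np.nan
            )
            ges = ss / (ss + total_error_ss) if ss + total_error_ss > 0 else 0.0
            rows.append(
                {
                    "effect": " x ".join(effect),
                    "SS": ss,
                    "df1": df1,
                    "df2": df2,
                    "F": f_val,
                    "p": p,
                    "ges": ges,
                    "eps": eps,
                    "df1_gg": df1 * eps,
                    "df2_gg": df2 * eps,
                    "p_gg": p_gg,
                }
            )
    return pd.DataFrame(rows)
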