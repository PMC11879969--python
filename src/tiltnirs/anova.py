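"""Two-way repeated-measures ANOVA with Greenhouse-Geisser correction.

Implements the classical univariate within-subject decomposition for a
complete crossed design (every subject measured in every cell of
factor A x factor B):

    SS_total = SS_subj + SS_A + SS_AxS + SS_B + SS_BxS + SS_AB + SS_ABxS

Each within-subject effect is tested against its own subject-interaction
error term; sphericity violations are handled by the Greenhouse-Geisser
(Box) epsilon computed from the covariance of the effect's orthonormalised
contrast scores, with corrected p-values reported whenever epsilon < 1.
Effect size is partial eta-squared, SS_effect / (SS_effect + SS_error).

The interface follows the statsmodels Model/Results idiom::

    res = RMAnova.from_dataframe(df, dv="hbo_uM", within=("level", "tilt"),
                                 subject="participant").fit()
    print(res.summary())
    res.posthoc("level")
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["RMAnova", "RMAnovaResults", "gg_epsilon", "posthoc_pairwise", "rm_anova"]


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthogonal to the unit vector)."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
    return helmert / np.linalg.norm(helmert, axis=1, keepdims=True)


def gg_epsilon(cov: np.ndarray, n_levels: int | None = None, contrasted: bool = False) -> float:
    """Greenhouse-Geisser (Box) epsilon from a repeated-measures covariance.

    ``cov`` is the k x k sample covariance of the k repeated scores; with
    ``contrasted=True`` it is instead the covariance of scores already
    projected onto orthonormal contrasts.  Epsilon is computed from the
    orthonormalised contrast covariance M = C cov C' as

        eps = tr(M)^2 / (d * tr(M @ M)),   d = rank of the contrast space,

    and clamped to [1/d, 1].  A rank-deficient M yields the lower bound.
    """
    cov = np.asarray(cov, dtype=float)
    if contrasted:
        m = cov
    else:
        k = cov.shape[0] if n_levels is None else n_levels
        if k < 2:
            raise ValueError("need at least 2 levels")
        c = _orthonormal_contrasts(k)
        m = c @ cov @ c.T
    d = m.shape[0]
    tr = np.trace(m)
    tr2 = np.trace(m @ m)
    if tr2 <= 0 or tr <= 0:
        return 1.0 / d
    eps = tr**2 / (d * tr2)
    return float(min(1.0, max(1.0 / d, eps)))


@dataclass
class _Effect:
    name: str
    ss: float
    df: int
    ss_err: float
    df_err: int
    eps: float

    def row(self) -> dict:
        ms = self.ss / self.df
        ms_err = self.ss_err / self.df_err
        if self.ss == 0:
            f = 0.0
        elif ms_err == 0:
            f = float("inf")
        else:
            f = ms / ms_err
        p_unc = float(stats.f.sf(f, self.df, self.df_err)) if ms_err > 0 else np.nan
        p_gg = (
            float(stats.f.sf(f, self.eps * self.df, self.eps * self.df_err))
            if ms_err > 0
            else np.nan
        )
        return {
            "effect": self.name,
            "SS": self.ss,
            "df1": self.df,
            "df2": self.df_err,
            "F": f,
            "p_unc": p_unc,
            "gg_epsilon": self.eps,
            "df1_gg": self.eps * self.df,
            "df2_gg": self.eps * self.df_err,
            "p_gg": p_gg,
            "p": p_gg if self.eps < 1.0 else p_unc,
            "partial_eta_sq": self.ss / (self.ss + self.ss_err) if (self.ss + self.ss_err) else 0.0,
        }


class RMAnova:
    """Two-way fully-within-subject ANOVA model.

    Parameters
    ----------
    y : ndarray, shape (n_subjects, a, b)
        One observation per subject and cell.
    factor_names : pair of str
        Labels for factor A (axis 1) and factor B (axis 2).
    level_names : optional pair of sequences with the factor level labels.
    """

    def __init__(
        self,
        y: np.ndarray,
        factor_names: tuple[str, str] = ("A", "B"),
        level_names: tuple[list, list] | None = None,
    ):
        y = np.asarray(y, dtype=float)
        if y.ndim != 3:
            raise ValueError(f"expected (subjects, a, b) array, got shape {y.shape}")
        if not np.isfinite(y).all():
            raise ValueError("non-finite values in the design (apply listwise deletion first)")
        n, a, b = y.shape
        if a < 2 or b < 2:
            raise ValueError("each factor needs at least 2 levels")
        if n < 2:
            raise ValueError("need at least 2 subjects")
        self.y = y
        self.factor_names = factor_names
        self.level_names = level_names or (
            [f"{factor_names[0]}{i}" for i in range(a)],
            [f"{factor_names[1]}{j}" for j in range(b)],
        )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        dv: str,
        within: tuple[str, str],
        subject: str,
        dropna: bool = True,
    ) -> "RMAnova":
        """Build from a tidy long table; subjects with missing cells are dropped.

        Raises with the missing cells named if, after listwise deletion, the
        design is not complete and balanced (e.g. duplicated cells).
        """
        fa, fb = within
        pivot = data.pivot_table(
            index=subject, columns=[fa, fb], values=dv, aggfunc="mean", dropna=False
        )
        a_levels = list(dict.fromkeys(data[fa]))
        b_levels = list(dict.fromkeys(data[fb]))
        pivot = pivot.reindex(columns=pd.MultiIndex.from_product([a_levels, b_levels]))
        incomplete = pivot.index[pivot.isna().any(axis=1)].tolist()
        if incomplete:
            if not dropna:
                missing = [
                    (s, c)
                    for s in incomplete
                    for c in pivot.columns[pivot.loc[s].isna()].tolist()
                ]
                raise ValueError(f"incomplete design; missing cells: {missing[:10]}")
            pivot = pivot.drop(index=incomplete)
        if len(pivot) < 2:
            raise ValueError("fewer than 2 complete subjects")
        y = pivot.to_numpy().reshape(len(pivot), len(a_levels), len(b_levels))
        model = cls(y, factor_names=within, level_names=(a_levels, b_levels))
        model.dropped_subjects = incomplete
        model.subjects = pivot.index.tolist()
        return model

    def fit(self) -> "RMAnovaResults":
        y = self.y
        n, a, b = y.shape
        grand = y.mean()
        m_s = y.mean(axis=(1, 2))  # per subject
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
        resid = (
            y
            - m_sa[:, :, None]
            - m_sb[:, None, :]
            - m_ab[None, :, :]
            + m_s[:, None, None]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - grand
        )
        ss_abs = np.sum(resid**2)

        eps_a = gg_epsilon(np.cov(m_sa.T, ddof=1)) if a > 2 else 1.0
        eps_b = gg_epsilon(np.cov(m_sb.T, ddof=1)) if b > 2 else 1.0
        # interaction: Kronecker contrasts applied to the per-subject cell vectors
        c_ab = np.kron(_orthonormal_contrasts(a), _orthonormal_contrasts(b))
        scores = y.reshape(n, a * b) @ c_ab.T
        d_ab = (a - 1) * (b - 1)
        eps_ab = gg_epsilon(np.cov(scores.T, ddof=1), contrasted=True) if d_ab > 1 else 1.0

        fa, fb = self.factor_names
        effects = [
            _Effect(fa, ss_a, a - 1, ss_as, (a - 1) * (n - 1), eps_a),
            _Effect(fb, ss_b, b - 1, ss_bs, (b - 1) * (n - 1), eps_b),
            _Effect(f"{fa}:{fb}", ss_ab, d_ab, ss_abs, d_ab * (n - 1), eps_ab),
        ]
        table = pd.DataFrame([e.row() for e in effects]).set_index("effect")
        return RMAnovaResults(self, table)


class RMAnovaResults:
    """Fitted rm-ANOVA: the effect table plus post hoc and summary helpers."""

    def __init__(self, model: RMAnova, table: pd.DataFrame):
        self.model = model
        self.anova_table = table

    def __getitem__(self, effect: str) -> pd.Series:
        return self.anova_table.loc[effect]

    def posthoc(self, factor: str, correction: str = "holm") -> pd.DataFrame:
        """Paired t-tests on subject-level marginal means of ``factor``.

        P-values are corrected across the factor's pairs (Holm by default).
        """
        fa, fb = self.model.factor_names
        if factor == fa:
            scores, levels = self.model.y.mean(axis=2), self.model.level_names[0]
        elif factor == fb:
            scores, levels = self.model.y.mean(axis=1), self.model.level_names[1]
        else:
            raise ValueError(f"unknown factor {factor!r}; have {fa!r}, {fb!r}")
        if len(levels) < 2:
            raise ValueError("factor needs at least 2 levels")
        rows = []
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                diff = scores[:, i] - scores[:, j]
                if np.allclose(diff.std(ddof=1), 0.0):
                    # degenerate paired test: identical columns (p=1) or an
                    # exactly constant nonzero shift (p=0)
                    t = 0.0 if np.allclose(diff.mean(), 0.0) else np.inf * np.sign(diff.mean())
                    p = 1.0 if t == 0.0 else 0.0
                else:
                    t, p = stats.ttest_rel(scores[:, i], scores[:, j])
                rows.append(
                    {
                        "level_1": levels[i],
                        "level_2": levels[j],
                        "mean_diff": float(diff.mean()),
                        "t": float(t),
                        "df": len(diff) - 1,
                        "p_unc": float(p),
                    }
                )
        out = pd.DataFrame(rows)
        out["p_corr"] = multipletests(out["p_unc"], method=correction)[1]
        return out

    def summary(self) -> str:
        n, a, b = self.model.y.shape
        fa, fb = self.model.factor_names
        lines = [
            "Two-way repeated-measures ANOVA",
            f"  n subjects: {n};  {fa}: {a} levels;  {fb}: {b} levels",
            "  Greenhouse-Geisser correction applied whenever epsilon < 1",
            "",
        ]
        hdr = f"{'effect':<16}{'F':>10}{'df':>12}{'eps':>8}{'p(GG)':>10}{'pEta2':>8}"
        lines.append(hdr)
        for name, r in self.anova_table.iterrows():
            df_str = f"({r.df1:.0f},{r.df2:.0f})"
            lines.append(
                f"{name:<16}{r.F:>10.3f}{df_str:>12}{r.gg_epsilon:>8.3f}"
                f"{r.p:>10.4f}{r.partial_eta_sq:>8.3f}"
            )
        return "\n".join(lines)


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: tuple[str, str],
    subject: str,
) -> RMAnovaResults:
    """One-call convenience wrapper: build the model from a tidy table and fit."""
    return RMAnova.from_dataframe(data, dv=dv, within=within, subject=subject).fit()


def posthoc_pairwise(
    data: pd.DataFrame,
    dv: str,
    within: tuple[str, str],
    subject: str,
    factor: str,
    correction: str = "holm",
) -> pd.DataFrame:
    """Post hoc paired comparisons for ``factor`` from a tidy table."""
    return RMAnova.from_dataframe(data, dv=dv, within=within, subject=subject).fit().posthoc(
        factor, correction
    )
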