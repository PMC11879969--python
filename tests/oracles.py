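"""Independent textbook implementations used as oracles by the tests.

Everything here is written from the classical formulas with plain loops and
scalar arithmetic, deliberately sharing no code path with the package.
"""

from __future__ import annotations

import numpy as np


def rm_anova_textbook(y: np.ndarray) -> dict[str, dict[str, float]]:
    """Two-way within-subject ANOVA by explicit sums of squares.

    ``y`` has shape (subjects, a, b).  Returns per-effect F, dfs, GG epsilon
    (scalar Box formula) and partial eta squared.
    """
    n, a, b = y.shape
    grand = y.mean()
    ss_a = ss_b = ss_ab = ss_as = ss_bs = ss_abs = 0.0
    for i in range(a):
        ss_a += n * b * (y[:, i, :].mean() - grand) ** 2
    for j in range(b):
        ss_b += n * a * (y[:, :, j].mean() - grand) ** 2
    for i in range(a):
        for j in range(b):
            ss_ab += n * (
                y[:, i, j].mean() - y[:, i, :].mean() - y[:, :, j].mean() + grand
            ) ** 2
    for s in range(n):
        for i in range(a):
            ss_as += b * (
                y[s, i, :].mean() - y[s].mean() - y[:, i, :].mean() + grand
            ) ** 2
        for j in range(b):
            ss_bs += a * (
                y[s, :, j].mean() - y[s].mean() - y[:, :, j].mean() + grand
            ) ** 2
        for i in range(a):
            for j in range(b):
                ss_abs += (
                    y[s, i, j]
                    - y[s, i, :].mean()
                    - y[s, :, j].mean()
                    - y[:, i, j].mean()
                    + y[s].mean()
                    + y[:, i, :].mean()
                    + y[:, :, j].mean()
                    - grand
                ) ** 2

    def effect(ss, df, ss_err, df_err, eps):
        f = (ss / df) / (ss_err / df_err)
        return {
            "F": f,
            "df1": df,
            "df2": df_err,
            "eps": eps,
            "partial_eta_sq": ss / (ss + ss_err),
        }

    eps_a = box_epsilon_scalar(y.mean(axis=2)) if a > 2 else 1.0
    eps_b = box_epsilon_scalar(y.mean(axis=1)) if b > 2 else 1.0
    eps_ab = interaction_epsilon_scalar(y) if (a - 1) * (b - 1) > 1 else 1.0
    return {
        "A": effect(ss_a, a - 1, ss_as, (a - 1) * (n - 1), eps_a),
        "B": effect(ss_b, b - 1, ss_bs, (b - 1) * (n - 1), eps_b),
        "A:B": effect(ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1), eps_ab),
    }


def box_epsilon_scalar(scores: np.ndarray) -> float:
    """Box/Greenhouse-Geisser epsilon via the classical scalar formula.

    ``scores``: (subjects, k) repeated measures.  Uses the double-centred
    covariance form: eps = k^2 (mean diag - grand mean)^2 /
    ((k-1) * (sum s_ij^2 - 2k sum row_mean^2 + k^2 grand^2)).
    """
    s = np.cov(scores.T, ddof=1)
    k = s.shape[0]
    diag_mean = np.trace(s) / k
    grand = s.mean()
    row = s.mean(axis=1)
    num = k * k * (diag_mean - grand) ** 2
    den = (k - 1) * ((s**2).sum() - 2 * k * (row**2).sum() + k * k * grand**2)
    eps = num / den
    return float(min(1.0, max(1.0 / (k - 1), eps)))


def _orthonormal_polynomial(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts via QR of a polynomial basis.

    A different construction from the package's Helmert route; Box epsilon is
    invariant to the orthonormal basis chosen.
    """
    x = np.arange(k, dtype=float)
    basis = np.vander(x, k, increasing=True)
    q, _ = np.linalg.qr(basis)
    return q[:, 1:].T


def interaction_epsilon_scalar(y: np.ndarray) -> float:
    """GG epsilon for the A x B interaction from Kronecker polynomial contrasts."""
    n, a, b = y.shape
    c = np.kron(_orthonormal_polynomial(a), _orthonormal_polynomial(b))
    scores = y.reshape(n, a * b) @ c.T
    m = np.cov(scores.T, ddof=1)
    d = (a - 1) * (b - 1)
    eps = np.trace(m) ** 2 / (d * np.trace(m @ m))
    return float(min(1.0, max(1.0 / d, eps)))


def correct_response_bruteforce(trials) -> list[str | None]:
    """Recompute n-back correct answers for a trial list by direct lookup."""
    out = []
    for i, t in enumerate(trials):
        if t.level == "control":
            out.append("any")
        elif t.level == "0back":
            out.append("yes" if t.result == 50 else "no")
        elif t.level == "1back":
            out.append(None if i < 1 else ("yes" if t.result == trials[i - 1].result else "no"))
        elif t.level == "2back":
            out.append(None if i < 2 else ("yes" if t.result == trials[i - 2].result else "no"))
        else:
            raise AssertionError(t.level)
    return out
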