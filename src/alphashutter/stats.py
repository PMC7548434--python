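"""Circular utilities and the repeated-measures statistical battery.

The observation-rate analysis ends in a balanced two (amplitude) x four
(phase) within-subjects design on per-participant delta-OR values.  This
module provides the full battery reported for that design:

* the within-subjects ANOVA decomposition with effect-by-subject error terms;
* Mauchly's sphericity test per within effect with >= 3 orthonormal contrasts;
* partial eta squared, ``F*df1 / (F*df1 + df2)``;
* post hoc observed power from a noncentral F with ``lambda = F*df1``
  (the convention used by mainstream statistics packages);
* Tukey HSD over the four phase-bin means within one amplitude level, with
  the error term from the per-level phase-by-subject decomposition;
* one-sample t tests of each cell against zero, Bonferroni-corrected.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError, NumericalError, ZeroResultantError

logger = logging.getLogger("alphashutter.stats")

_EPS = 1e-12


def wrap360(angle):
    """Wrap to [0, 360); maps a float-rounding 360.0 back to 0.0."""
    a = np.asarray(angle, dtype=float) % 360.0
    a = np.where(a >= 360.0, 0.0, a)
    return float(a) if a.ndim == 0 else a


# ---------------------------------------------------------------------------
# Circular utilities
# ---------------------------------------------------------------------------

def circ_mean(
    angles_deg: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float]:
    """Weighted circular mean: (angle in [0, 360) deg, resultant length in [0, 1]).

    Raises ZeroResultantError when the vector sum vanishes.
    """
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if angles.size == 0:
        raise DataError("circ_mean of an empty set")
    if weights is None:
        weights = np.ones_like(angles)
    else:
        weights = np.atleast_1d(np.asarray(weights, dtype=float))
    z = np.sum(weights * np.exp(1j * np.radians(angles))) / np.sum(weights)
    r = float(np.abs(z))
    if r < _EPS:
        raise ZeroResultantError("circular mean undefined: zero resultant")
    return wrap360(np.degrees(np.angle(z))), r


def circ_diff(a: float | np.ndarray, b: float | np.ndarray) -> float | np.ndarray:
    """Signed wrapped difference a - b in (-180, 180] degrees."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    return float(d) if d.ndim == 0 else d


# ---------------------------------------------------------------------------
# Effect sizes and power
# ---------------------------------------------------------------------------

def partial_eta_sq(F: float, df_num: int, df_den: int) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ConfigError("F must be non-negative")
    return F * df_num / (F * df_num + df_den)


def observed_power(F: float, df_num: int, df_den: int, alpha: float = 0.05) -> float:
    """Post hoc power: P(F' > F_crit) for noncentral F' with lambda = F*df1."""
    if F < 0:
        raise ConfigError("F must be non-negative")
    f_crit = sps.f.ppf(1.0 - alpha, df_num, df_den)
    if F == 0:
        return alpha
    return float(sps.ncf.sf(f_crit, df_num, df_den, F * df_num))


# ---------------------------------------------------------------------------
# Within-subjects ANOVA
# ---------------------------------------------------------------------------

def _check_table(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise DataError("expected a participant x factorA x factorB array")
    if np.isnan(data).any():
        raise DataError("missing cells: exclude incomplete participants upstream")
    if data.shape[0] < 2:
        raise DataError("need at least 2 participants")
    return data


def rm_anova_2x4(
    data: np.ndarray,
    factor_names: tuple[str, str] = ("amplitude", "phase"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-way fully-within-subjects ANOVA on a balanced (n x a x b) table.

    Rows: the two main effects and their interaction.  Each effect is tested
    against its own effect-by-subject error term.  Columns include F, dfs,
    p, partial eta squared, and observed power; p-values are also carried at
    full precision in ``p_exact`` (the ``p`` column is rounded to 4 decimals
    and floored at 0.0001 for table formatting).
    """
    data = _check_table(data)
    n, a, b = data.shape

    g = data.mean()
    m_s = data.mean(axis=(1, 2))
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_ab = data.mean(axis=0)
    m_sa = data.mean(axis=2)
    m_sb = data.mean(axis=1)

    ss_a = n * b * np.sum((m_a - g) ** 2)
    ss_b = n * a * np.sum((m_b - g) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + g) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + g) ** 2)
    resid = (
        data
        - m_ab[None, :, :]
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - g
    )
    ss_abs = np.sum(resid**2)

    rows = []
    specs = [
        (factor_names[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        (factor_names[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        (f"{factor_names[0]} x {factor_names[1]}", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ]
    for name, ss_eff, df1, ss_err, df2 in specs:
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        F = 0.0 if ms_err == 0 and ms_eff == 0 else ms_eff / ms_err
        p = float(sps.f.sf(F, df1, df2))
        rows.append(
            {
                "source": name,
                "F": F,
                "df_num": df1,
                "df_den": df2,
                "p": format_p(p),
                "p_exact": p,
                "partial_eta_sq": partial_eta_sq(F, df1, df2),
                "observed_power": observed_power(F, df1, df2, alpha),
                "ss_effect": ss_eff,
                "ms_error": ms_err,
            }
        )
    return pd.DataFrame(rows)


def format_p(p: float, decimals: int = 4) -> float:
    """Round a p-value for reporting; never print exactly zero."""
    floor = 10.0 ** (-decimals)
    return max(round(p, decimals), floor)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast matrix (columns orthogonal to 1)."""
    helmert = np.zeros((k, k - 1))
    for j in range(1, k):
        helmert[:j, j - 1] = 1.0
        helmert[j, j - 1] = -j
        helmert[:, j - 1] /= np.linalg.norm(helmert[:, j - 1])
    return helmert


def mauchly_test(data: np.ndarray, effect: str = "B") -> tuple[float, float, int, float]:
    """Mauchly sphericity test for a within effect of a (n x a x b) table.

    ``effect`` is ``"A"`` or ``"B"`` for a main effect (the other factor is
    averaged out) or ``"AB"`` for the interaction (Kronecker product of the
    two factors' orthonormal contrasts).  Returns (W, chi2, df, p) with
    ``chi2 = -(n-1) * d * ln W``, ``d = 1 - (2m^2 + m + 2)/(6m(n-1))`` and
    ``df = m(m+1)/2 - 1`` for m orthonormal contrasts.  The p-value is the
    first-order chi-square tail probability (some references add a
    second-order Box term; W, chi2 and df are identical either way).
    """
    data = _check_table(data)
    n, a, b = data.shape
    if effect == "A":
        y = data.mean(axis=2)  # n x a
        C = _orthonormal_contrasts(a)
    elif effect == "B":
        y = data.mean(axis=1)  # n x b
        C = _orthonormal_contrasts(b)
    elif effect == "AB":
        y = data.reshape(n, a * b)
        C = np.kron(_orthonormal_contrasts(a), _orthonormal_contrasts(b))
    else:
        raise ConfigError("effect must be 'A', 'B' or 'AB'")
    m = C.shape[1]
    if m < 2:
        raise ConfigError("sphericity is trivial for fewer than 3 levels")
    if n - 1 < m:
        raise DataError("too few participants for the Mauchly test")
    z = y @ C
    S = np.cov(z, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(S)
    if np.any(eig <= 0):
        raise NumericalError("singular contrast covariance")
    W = float(np.prod(eig) / (eig.mean() ** m))
    d = 1.0 - (2.0 * m**2 + m + 2.0) / (6.0 * m * (n - 1.0))
    chi2 = -(n - 1.0) * d * np.log(W)
    df = m * (m + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df))
    return W, float(chi2), df, p


# ---------------------------------------------------------------------------
# Post hoc tests
# ---------------------------------------------------------------------------

def tukey_hsd(
    data: np.ndarray,
    level_names: list | None = None,
    error_ms: float | None = None,
    df_error: int | None = None,
) -> pd.DataFrame:
    """Tukey HSD over k within-subject means from an (n x k) layout.

    By default the error term is the condition-by-subject mean square of the
    given layout (df = (n-1)(k-1)), matching a one-way repeated-measures
    decomposition within one amplitude level.  A pooled omnibus error term
    may be supplied instead via ``error_ms``/``df_error``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise DataError("expected an (n x k) layout with k >= 2")
    n, k = data.shape
    means = data.mean(axis=0)
    if error_ms is None or df_error is None:
        g = data.mean()
        m_s = data.mean(axis=1)
        resid = data - m_s[:, None] - means[None, :] + g
        df_error = (n - 1) * (k - 1)
        error_ms = float(np.sum(resid**2) / df_error)
    if df_error < 1:
        raise DataError("error degrees of freedom must be >= 1")
    se = np.sqrt(error_ms / n)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        if se == 0:
            q = 0.0 if diff == 0 else np.inf
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_error))
        li = level_names[i] if level_names else i
        lj = level_names[j] if level_names else j
        rows.append(
            {
                "level_a": li,
                "level_b": lj,
                "mean_diff": diff,
                "q": q,
                "df_error": df_error,
                "p_adj": format_p(p),
                "p_exact": p,
            }
        )
    return pd.DataFrame(rows)


def one_sample_t_bonferroni(samples: np.ndarray, m_comparisons: int = 8) -> pd.DataFrame:
    """One-sample t of each column against zero, Bonferroni-corrected.

    ``samples`` is participants x cells; the correction multiplies each
    p-value by ``m_comparisons`` (clipped to 1).  A zero-variance nonzero
    mean yields infinite t and adjusted p -> 0, with a warning.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n = samples.shape[0]
    if n < 2:
        raise DataError("need >= 2 participants per cell")
    rows = []
    for j in range(samples.shape[1]):
        col = samples[:, j]
        sd = col.std(ddof=1)
        if sd == 0:
            if col.mean() == 0:
                t, p = 0.0, 1.0
            else:
                logger.warning("zero-variance cell %d: t is infinite", j)
                t, p = np.inf * np.sign(col.mean()), 0.0
        else:
            t = col.mean() / (sd / np.sqrt(n))
            p = float(2.0 * sps.t.sf(abs(t), n - 1))
        rows.append(
            {
                "cell": j,
                "t": float(t),
                "df": n - 1,
                "p_adj": format_p(min(1.0, m_comparisons * p)),
                "p_exact": min(1.0, m_comparisons * p),
            }
        )
    return pd.DataFrame(rows)
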