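"""Signal-detection behavioral analysis of voice-authenticity judgments.

Listeners label each sentence "human" or "AI".  For each speech condition
a 2x2 confusion matrix is built per subject and session:

* target = HS (human speech): both AI conditions are pooled as noise.
* target = one AI condition: human speech is the noise class and trials
  of the other AI condition are discarded.

A hit is the correct class label on a target trial, a correct rejection
the correct label on a noise trial.  Sensitivity and bias follow the
equal-variance Gaussian model, d' = z(H) - z(F) and c = -(z(H)+z(F))/2,
with extreme rates clipped to [1/(2N), 1 - 1/(2N)] using the cell's own
trial count before the inverse-normal transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri
from statsmodels.stats.multitest import multipletests

CONDITIONS = ("HS", "AI-NF", "AI-FT")
AI_CONDITIONS = ("AI-NF", "AI-FT")


@dataclass
class ConfusionCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    target_condition: str

    @property
    def n_target(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections

    @property
    def hit_rate(self) -> float:
        return self.hits / self.n_target

    @property
    def fa_rate(self) -> float:
        return self.false_alarms / self.n_noise


def _target_class_label(target: str) -> str:
    return "human" if target == "HS" else "AI"


def build_confusion(trials: pd.DataFrame, target: str,
                    session: str | None = None,
                    subject=None) -> ConfusionCounts:
    """Confusion counts for one target condition (optionally one cell).

    ``trials`` is a long table with columns ``condition`` (HS/AI-NF/AI-FT)
    and ``response`` (human/AI), plus ``session``/``subject`` for cell
    selection.
    """
    if target not in CONDITIONS:
        raise ValueError(f"unknown target condition {target!r}")
    t = trials
    if session is not None:
        t = t[t["session"] == session]
    if subject is not None:
        t = t[t["subject"] == subject]
    if target == "HS":
        noise_conditions = list(AI_CONDITIONS)
    else:
        noise_conditions = ["HS"]  # the other AI condition is discarded
    tgt = t[t["condition"] == target]
    noi = t[t["condition"].isin(noise_conditions)]
    if len(tgt) == 0:
        raise ValueError(f"no trials for target {target!r} in this cell")
    tgt_label = _target_class_label(target)
    noise_label = "AI" if tgt_label == "human" else "human"
    hits = int((tgt["response"] == tgt_label).sum())
    crs = int((noi["response"] == noise_label).sum())
    return ConfusionCounts(
        hits=hits,
        misses=len(tgt) - hits,
        false_alarms=len(noi) - crs,
        correct_rejections=crs,
        target_condition=target,
    )


def _clip_rate(rate: float, n: int) -> float:
    if n <= 0:
        raise ValueError("cell with zero trials")
    lo = 1.0 / (2 * n)
    return float(np.clip(rate, lo, 1.0 - lo))


def dprime(h_rate: float, f_rate: float, n_target: int, n_noise: int) -> float:
    """Equal-variance sensitivity d' with 1/(2N) extreme-rate clipping."""
    _check_rates(h_rate, f_rate)
    h = _clip_rate(h_rate, n_target)
    f = _clip_rate(f_rate, n_noise)
    return float(ndtri(h) - ndtri(f))


def criterion(h_rate: float, f_rate: float, n_target: int, n_noise: int) -> float:
    """Decision criterion c = -(z(H) + z(F)) / 2 (positive = conservative)."""
    _check_rates(h_rate, f_rate)
    h = _clip_rate(h_rate, n_target)
    f = _clip_rate(f_rate, n_noise)
    return float(-0.5 * (ndtri(h) + ndtri(f)))


def _check_rates(h, f):
    for r in (h, f):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate {r} outside [0, 1]")


def sdt_table(trials: pd.DataFrame) -> pd.DataFrame:
    """d' and c per subject x session x target condition.

    Returns a tidy frame with columns subject, session, condition,
    d_prime, criterion, hit_rate, fa_rate, n_target, n_noise.
    """
    rows = []
    for subject in sorted(trials["subject"].unique()):
        for session in sorted(trials["session"].unique()):
            for cond in CONDITIONS:
                cc = build_confusion(trials, cond, session=session,
                                     subject=subject)
                rows.append(dict(
                    subject=subject, session=session, condition=cond,
                    d_prime=dprime(cc.hit_rate, cc.fa_rate,
                                   cc.n_target, cc.n_noise),
                    criterion=criterion(cc.hit_rate, cc.fa_rate,
                                        cc.n_target, cc.n_noise),
                    hit_rate=cc.hit_rate, fa_rate=cc.fa_rate,
                    n_target=cc.n_target, n_noise=cc.n_noise,
                ))
    return pd.DataFrame(rows)


def rm_anova_2way(values: np.ndarray) -> dict:
    """Two-way fully within-subject ANOVA on a (n, a, b) array.

    ``values[i, j, k]`` is subject i's score at level j of factor A and
    level k of factor B.  Returns F, df, p, and partial eta squared for
    the A and B main effects and the A x B interaction, with uncorrected
    degrees of freedom (no sphericity correction).
    """
    y = np.asarray(values, float)
    if y.ndim != 3:
        raise ValueError("expected (subjects, a, b) array")
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.isnan(y).any():
        raise ValueError("missing cells are not supported")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))          # subject means
    m_a = y.mean(axis=(0, 2))          # factor A level means
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)              # (n, a)
    m_sb = y.mean(axis=1)              # (n, b)
    m_ab = y.mean(axis=0)              # (a, b)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - grand)
    ss_abs = np.sum(resid ** 2)

    out = {}
    for name, ss_eff, ss_err, df_eff in (
            ("A", ss_a, ss_as, a - 1),
            ("B", ss_b, ss_bs, b - 1),
            ("AxB", ss_ab, ss_abs, (a - 1) * (b - 1))):
        df_err = df_eff * (n - 1)
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(stats.f.sf(F, df_eff, df_err)) if ms_err > 0 else 1.0
        out[name] = dict(
            F=float(F), df=(df_eff, df_err), p=p,
            partial_eta_sq=float(ss_eff / (ss_eff + ss_err))
            if (ss_eff + ss_err) > 0 else 0.0,
        )
    return out


def paired_t(x, y) -> dict:
    """Paired t test with Cohen's d = mean(diff) / sd(diff)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero-variance differences: t undefined")
    res = stats.ttest_rel(x, y)
    return dict(t=float(res.statistic), df=len(x) - 1,
                p=float(res.pvalue), cohens_d=float(d.mean() / sd))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (original order)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
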