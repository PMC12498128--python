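"""Scalar inferential statistics: Welch t, chi-square, Cohen's d (incl. the
circular/PLA variant), Spearman with Bonferroni control, the Watson-Williams
test for equal mean directions, and the 2 x 2 mixed-design rmANOVA with
Bonferroni post hocs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as st

from .timefreq import circular_mean, wrap_angle


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_sample(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(n=x.size, mean=float(x.mean()), sd=float(x.std(ddof=1)))


def _as_summary(sample) -> GroupSummary:
    return sample if isinstance(sample, GroupSummary) else GroupSummary.from_sample(sample)


def welch_t(sample1, sample2) -> dict:
    """Welch's unequal-variance t test from raw samples or (n, mean, SD) summaries."""
    s1, s2 = _as_summary(sample1), _as_summary(sample2)
    if s1.sd == 0 and s2.sd == 0:
        raise ValueError("both groups have zero variance")
    res = st.ttest_ind_from_stats(
        s1.mean, s1.sd, s1.n, s2.mean, s2.sd, s2.n, equal_var=False
    )
    se1, se2 = s1.sd**2 / s1.n, s2.sd**2 / s2.n
    df = (se1 + se2) ** 2 / (se1**2 / (s1.n - 1) + se2**2 / (s2.n - 1))
    return {"t": float(res.statistic), "df": float(df), "p": float(res.pvalue)}


def chi_square(table) -> dict:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("table has a zero row or column total")
    res = st.chi2_contingency(obs, correction=False)
    return {"chi2": float(res.statistic), "df": int(res.dof), "p": float(res.pvalue)}


def cohens_d(sample1, sample2) -> float:
    """Cohen's d with the (n-1)-weighted pooled SD.

    Sign convention: positive when the *first* sample's mean is larger
    (d = (m1 - m2) / s_pooled).
    """
    s1, s2 = _as_summary(sample1), _as_summary(sample2)
    pooled = np.sqrt(
        ((s1.n - 1) * s1.sd**2 + (s2.n - 1) * s2.sd**2) / (s1.n + s2.n - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled variance")
    return float((s1.mean - s2.mean) / pooled)


def pla_effect_size(nc_angles, sz_angles) -> float:
    """Cohen's d for phase angles via the control-anchored z transform.

    Both samples (angles already wrapped around the control reference, so a
    linear treatment is meaningful) are z-scored by the control group's mean
    and SD, then ordinary Cohen's d is applied.
    """
    nc = np.asarray(nc_angles, dtype=float)
    sz = np.asarray(sz_angles, dtype=float)
    mu, sd = nc.mean(), nc.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("control angular SD is ~0; z transform undefined")
    return cohens_d((nc - mu) / sd, (sz - mu) / sd)


def _resultant_length(theta: np.ndarray) -> float:
    return float(np.abs(np.exp(1j * np.asarray(theta, dtype=float)).mean()))


def _kappa_from_r(r: float) -> float:
    """Maximum-likelihood von Mises concentration from mean resultant length."""
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1 / (r**3 - 4 * r**2 + 3 * r)


def watson_williams(sample1, sample2) -> dict:
    """Watson-Williams test for a common mean direction of two circular samples.

    Classical F with the 1 + 3/(8*kappa) correction, kappa estimated from
    the pooled mean resultant length.  The test assumes reasonably
    concentrated samples; a ``warning`` string is set (not raised) when the
    pooled resultant length falls below the usual 0.45 validity bound.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    n1, n2 = a.size, b.size
    n = n1 + n2
    if n < 3:
        raise ValueError("need at least three observations in total")
    r1 = n1 * _resultant_length(a)
    r2 = n2 * _resultant_length(b)
    rall = n * _resultant_length(np.concatenate([a, b]))
    rw = (r1 + r2) / n
    kappa = _kappa_from_r(rw)
    correction = 1 + 3 / (8 * kappa) if kappa > 0 else 1.0
    denom = n - r1 - r2
    if denom <= 0:
        return {"F": np.inf, "df": (1, n - 2), "p": 0.0, "warning": None}
    F = correction * (n - 2) * (r1 + r2 - rall) / denom
    F = max(F, 0.0)
    p = float(st.f.sf(F, 1, n - 2))
    warning = None
    if rw < 0.45:
        warning = (
            f"pooled mean resultant length {rw:.3f} < 0.45: Watson-Williams "
            "concentration assumption is doubtful"
        )
    return {"F": float(F), "df": (1, n - 2), "p": p, "warning": warning}


def spearman(x, y, bonferroni_m: int = 1) -> dict:
    """Spearman rank correlation (average ranks on ties) with a Bonferroni-
    adjusted significance level alpha = 0.05 / m."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input vector")
    rho, p = st.spearmanr(x, y)
    alpha = 0.05 / bonferroni_m
    return {
        "rho": float(rho), "p": float(p), "alpha": alpha,
        "significant": bool(p < alpha), "m": bonferroni_m,
    }


@dataclass
class RmanovaResult:
    F_group: float
    F_state: float
    F_interaction: float
    df1: int
    df2: int
    p_group: float
    p_state: float
    p_interaction: float
    cell_means: dict
    post_hoc: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "F_group": self.F_group, "F_state": self.F_state,
            "F_interaction": self.F_interaction,
            "df": [self.df1, self.df2],
            "p_group": self.p_group, "p_state": self.p_state,
            "p_interaction": self.p_interaction,
            "cell_means": self.cell_means,
        }
        if self.post_hoc is not None:
            d["post_hoc"] = self.post_hoc
        return d


def rmanova_2x2(rest: np.ndarray, task: np.ndarray, groups: np.ndarray) -> RmanovaResult:
    """Mixed-design 2 x 2 ANOVA: group (between) x state (within).

    ``rest``/``task`` are per-subject values of the two states; ``groups``
    holds two distinct labels.  Sums of squares: the group effect is tested
    against subjects-within-groups; state and group x state against the
    state x subjects-within-groups error.  With only two within levels no
    sphericity correction is needed.  df2 = n_total - 2 for all three
    effects.  When the interaction is significant (p < 0.05) the four
    Bonferroni post hocs (alpha = 0.05/4) are attached: paired t within each
    group, unpaired (Student) t within each state.
    """
    rest = np.asarray(rest, dtype=float)
    task = np.asarray(task, dtype=float)
    groups = np.asarray(groups)
    if rest.shape != task.shape or rest.shape != groups.shape:
        raise ValueError("rest, task and groups must align per subject")
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two groups required")
    y = np.stack([rest, task], axis=1)  # subjects x states
    n = y.shape[0]
    ga, gb = (groups == labels[0]), (groups == labels[1])
    n_a, n_b = int(ga.sum()), int(gb.sum())

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[ga].mean(), subj_means[gb].mean()])
    state_means = y.mean(axis=0)
    cell = np.array([
        [y[ga, 0].mean(), y[ga, 1].mean()],
        [y[gb, 0].mean(), y[gb, 1].mean()],
    ])

    k = 2  # states
    ss_group = k * (n_a * (group_means[0] - grand) ** 2 + n_b * (group_means[1] - grand) ** 2)
    ss_subj_within = k * (
        ((subj_means[ga] - group_means[0]) ** 2).sum()
        + ((subj_means[gb] - group_means[1]) ** 2).sum()
    )
    ss_state = n * ((state_means - grand) ** 2).sum()
    ss_cells = n_a * ((cell[0] - grand) ** 2).sum() + n_b * ((cell[1] - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_state
    ss_total = ((y - grand) ** 2).sum()
    ss_err_within = ss_total - ss_cells - ss_subj_within

    df1, df2 = 1, n - 2
    ms_group, ms_subj = ss_group / df1, ss_subj_within / df2
    ms_state, ms_inter, ms_err = ss_state / df1, ss_inter / df1, ss_err_within / df2
    F_group = ms_group / ms_subj
    F_state = ms_state / ms_err
    F_inter = ms_inter / ms_err
    p = lambda F: float(st.f.sf(F, df1, df2))

    result = RmanovaResult(
        F_group=float(F_group), F_state=float(F_state), F_interaction=float(F_inter),
        df1=df1, df2=df2,
        p_group=p(F_group), p_state=p(F_state), p_interaction=p(F_inter),
        cell_means={
            str(labels[0]): {"rest": float(cell[0, 0]), "task": float(cell[0, 1])},
            str(labels[1]): {"rest": float(cell[1, 0]), "task": float(cell[1, 1])},
        },
    )
    if result.p_interaction < 0.05:
        result.post_hoc = _post_hoc_2x2(rest, task, groups, labels, alpha=0.05 / 4)
    return result


def _post_hoc_2x2(rest, task, groups, labels, alpha: float) -> dict:
    out = {"alpha": alpha, "family_size": 4, "tests": {}}
    for lab in labels:
        sel = groups == lab
        tt = st.ttest_rel(task[sel], rest[sel])
        out["tests"][f"task_vs_rest_within_{lab}"] = {
            "t": float(tt.statistic), "df": int(sel.sum() - 1),
            "p": float(tt.pvalue), "significant": bool(tt.pvalue < alpha),
        }
    for state_name, vals in (("rest", rest), ("task", task)):
        tt = st.ttest_ind(vals[groups == labels[0]], vals[groups == labels[1]])
        out["tests"][f"{labels[0]}_vs_{labels[1]}_within_{state_name}"] = {
            "t": float(tt.statistic), "df": int(vals.size - 2),
            "p": float(tt.pvalue), "significant": bool(tt.pvalue < alpha),
        }
    return out


__all__ = [
    "GroupSummary", "welch_t", "chi_square", "cohens_d", "pla_effect_size",
    "watson_williams", "spearman", "rmanova_2x2", "RmanovaResult",
    "circular_mean", "wrap_angle",
]
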