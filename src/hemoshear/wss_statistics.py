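"""Regional WSS ratios and the statistical battery of a WSS-plaque study.

Two ratios summarize where low shear sits on the vessel wall:

* ``rwss_vi_ds`` — mean WSS of the ventral+inferior walls over the
  dorsal+superior walls (per segment);
* ``rwss_inner_outer`` — mean WSS of the inner over the outer wall of the
  vessel curve.

The inferential tests mirror standard clinical-study practice: paired and
two-sample t tests, one-way ANOVA with Bonferroni-corrected pairwise
comparisons (capped at 1.000), Fisher's exact test for 2×2 tables, Cohen's
κ and a two-way random-effects, absolute-agreement, single-measurement ICC
for rater agreement; agreement above 0.75 is flagged "excellent" and the
significance level is 0.05 throughout.  Established implementations
(scipy, statsmodels-compatible pingouin, scikit-learn) do the arithmetic
behind this module's surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .vessel_anatomy import (CURVE_SIDE_NAMES, QUADRANT_NAMES, SEGMENT_NAMES,
                             WallRegionLabels)
from .wall_shear import WSSField, regional_mean_wss

ALPHA = 0.05
EXCELLENT_AGREEMENT = 0.75


# ---------------------------------------------------------------------------
# regional tables and ratios


def _align(field: WSSField, labels: WallRegionLabels) -> np.ndarray:
    """Positions of the field's faces inside the label arrays."""
    pos = np.searchsorted(labels.face_ids, field.face_ids)
    if np.any(pos >= len(labels.face_ids)) or np.any(
        labels.face_ids[pos] != field.face_ids
    ):
        raise ValueError("field faces are not a subset of labeled faces")
    return pos


def regional_wss_table(field: WSSField, labels: WallRegionLabels,
                       vessel_id: str = "vessel") -> pd.DataFrame:
    """Long-format per-region area-weighted mean WSS (Pa)."""
    pos = _align(field, labels)
    rows = []
    for s_id, s_name in enumerate(SEGMENT_NAMES):
        seg = labels.segment[pos] == s_id
        for q_id, q_name in enumerate(QUADRANT_NAMES):
            m = seg & (labels.quadrant[pos] == q_id)
            if np.any(m):
                rows.append((vessel_id, s_name, q_name,
                             regional_mean_wss(field, m),
                             float(field.face_areas[m].sum()), int(m.sum())))
    for c_id, c_name in enumerate(CURVE_SIDE_NAMES[:2]):
        m = labels.curve_side[pos] == c_id
        if np.any(m):
            rows.append((vessel_id, "all", c_name, regional_mean_wss(field, m),
                         float(field.face_areas[m].sum()), int(m.sum())))
    df = pd.DataFrame(rows, columns=["vessel_id", "segment", "region",
                                     "mean_wss_pa", "total_area_m2", "n_faces"])
    if (df["mean_wss_pa"] < 0).any():
        raise ValueError("negative mean WSS")
    return df


def rwss_vi_ds(field: WSSField, labels: WallRegionLabels,
               segment: str | None = None) -> float:
    """Ventral+inferior over dorsal+superior mean WSS, optionally per segment."""
    pos = _align(field, labels)
    base = np.ones(len(pos), dtype=bool)
    if segment is not None:
        base = labels.segment_mask(segment)[pos]
    vi = base & labels.quadrant_mask("ventral", "inferior")[pos]
    ds = base & labels.quadrant_mask("dorsal", "superior")[pos]
    if not (np.any(vi) and np.any(ds)):
        raise ValueError("empty wall group in the requested segment")
    return regional_mean_wss(field, vi) / regional_mean_wss(field, ds)


def rwss_inner_outer(field: WSSField, labels: WallRegionLabels,
                     segment: str | None = None) -> float:
    """Inner-curve over outer-curve mean WSS (errors on a straight vessel)."""
    pos = _align(field, labels)
    base = np.ones(len(pos), dtype=bool)
    if segment is not None:
        base = labels.segment_mask(segment)[pos]
    inner = base & labels.curve_side_mask("inner")[pos]
    outer = base & labels.curve_side_mask("outer")[pos]
    if not (np.any(inner) and np.any(outer)):
        raise ValueError("curve sides undefined (straight vessel?)")
    return regional_mean_wss(field, inner) / regional_mean_wss(field, outer)


# ---------------------------------------------------------------------------
# inferential tests


@dataclass
class TestResult:
    statistic: float
    p_value: float

    def __iter__(self):
        yield self.statistic
        yield self.p_value


def paired_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided paired-sample t test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    if np.var(a - b) == 0:
        raise ValueError("zero difference variance")
    t, p = stats.ttest_rel(a, b)
    return TestResult(float(t), float(p))


def two_sample_t(a: Sequence[float], b: Sequence[float],
                 equal_var: bool = False) -> TestResult:
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                           equal_var=equal_var)
    return TestResult(float(t), float(p))


def two_sample_t_summary(mean1, sd1, n1, mean2, sd2, n2,
                         equal_var: bool = False) -> TestResult:
    """Welch (default) two-sample t from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=equal_var)
    return TestResult(float(t), float(p))


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise_p: dict      # (i, j) -> corrected p, capped at 1.000
    correction: str = "bonferroni"


def one_way_anova_posthoc(groups: Sequence[Sequence[float]],
                          correction: str = "bonferroni") -> AnovaResult:
    """Omnibus one-way ANOVA plus corrected pairwise two-sample tests.

    Pairwise p-values are Student t with Bonferroni correction
    min(1, m·p), reported capped at exactly 1.000 as agreement tables do.
    """
    if correction != "bonferroni":
        raise ValueError("only bonferroni correction is supported")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    f, p = stats.f_oneway(*groups)
    m = len(groups) * (len(groups) - 1) // 2
    pairwise = {}
    for i, j in combinations(range(len(groups)), 2):
        if np.var(groups[i]) == 0 and np.var(groups[j]) == 0:
            raw = 1.0 if np.mean(groups[i]) == np.mean(groups[j]) else 0.0
        else:
            raw = stats.ttest_ind(groups[i], groups[j], equal_var=True).pvalue
        pairwise[(i, j)] = min(1.0, m * float(raw))
    return AnovaResult(float(f), float(p), pairwise)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2×2 count table.

    Computed by summing hypergeometric probabilities no larger than the
    observed table's, over all tables with the same margins.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


@dataclass
class AgreementResult:
    value: float          # κ or ICC; nan when undefined
    excellent: bool       # value > 0.75
    defined: bool
    model: str


def cohen_kappa(ratings_a: Sequence, ratings_b: Sequence) -> AgreementResult:
    """Cohen's κ = (p_o − p_e)/(1 − p_e) between two raters."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape:
        raise ValueError("rating vectors must have equal length")
    cats = np.unique(np.concatenate([a, b]))
    if len(cats) < 2:
        return AgreementResult(float("nan"), False, False, "cohen_kappa")
    from sklearn.metrics import cohen_kappa_score

    k = float(cohen_kappa_score(a, b))
    return AgreementResult(k, k > EXCELLENT_AGREEMENT, True, "cohen_kappa")


def icc(measurements: np.ndarray) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``measurements`` is subjects × raters.  Undefined (nan) when there is
    no between-subject variance.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if np.var(m.mean(axis=1)) == 0:
        return AgreementResult(float("nan"), False, False, "ICC2")
    import pingouin as pg

    n_subj, n_rat = m.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_subj), n_rat),
        "rater": np.tile(np.arange(n_rat), n_subj),
        "score": m.ravel(),
    })
    import warnings

    with warnings.catch_warnings():
        # perfect agreement makes some of pingouin's CI ratios 0/0
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
    # two-way random, absolute agreement, single rater — labeled ICC(A,1)
    # (McGraw & Wong) or ICC2 (Shrout & Fleiss) depending on version
    sel = res["Type"].isin(["ICC(A,1)", "ICC2"])
    val = float(res.loc[sel, "ICC"].iloc[0])
    return AgreementResult(val, val > EXCELLENT_AGREEMENT, True, "ICC2")
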