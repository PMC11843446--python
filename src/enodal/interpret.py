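"""Stage 3a: interpretable statistics per feature and rule-based subcluster annotation.

Three sets of standardized statistics summarise how a feature responds to
the experiment:

* Set 1 - overall nutrition association: Fisher z of the correlation
  between the feature and each nutrition variable, scaled to unit null
  variance, sqrt(n-3) * atanh(r).
* Set 2 - marginal treatment response: Welch t statistic of each
  treatment group against the control.
* Set 3 - treatment-dependent nutrition association (the interaction
  signature): the standardized difference of Fisher z transforms between
  a treatment group and the control group.

Statistics are ternarized at the +/- standard-normal quantile (default
0.95 -> 1.6449); a subcluster is annotated with a direction whenever the
fraction of members agreeing strictly exceeds the proportion threshold
(default 0.7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExperimentDesign, OmicsMatrix, RunConfig

logger = logging.getLogger("enodal")

_ATANH_CLAMP = 38.0


def fisher_z(r: float, n: int, literal_scale: bool = False) -> float:
    """Variance-stabilized correlation: sqrt(n-3) * atanh(r).

    With ``literal_scale`` the statistic is instead atanh(r)/sqrt(n-3)
    (a reading whose null variance shrinks with n and which defeats
    normal-quantile thresholding; kept only as an option).
    """
    if n <= 3:
        raise ValueError("fisher_z requires n > 3")
    if abs(r) >= 1.0:
        logger.warning("|r| = 1: Fisher z clamped to +/-%g", _ATANH_CLAMP)
        z = np.sign(r) * _ATANH_CLAMP
    else:
        z = np.arctanh(r)
    scale = 1.0 / np.sqrt(n - 3) if literal_scale else np.sqrt(n - 3)
    return float(scale * z)


def pairwise_t(z_group: np.ndarray, z_control: np.ndarray) -> float:
    """Welch t statistic of a treatment group against the control group."""
    z_group = np.asarray(z_group, dtype=float)
    z_control = np.asarray(z_control, dtype=float)
    nk, n1 = len(z_group), len(z_control)
    if nk < 2 or n1 < 2:
        raise ValueError("both groups need at least 2 samples")
    vk, v1 = z_group.var(ddof=1), z_control.var(ddof=1)
    num = z_group.mean() - z_control.mean()
    den = np.sqrt(vk / nk + v1 / n1)
    if den == 0:
        return 0.0 if num == 0 else float(np.sign(num) * np.inf)
    return float(num / den)


def correlation_shift(r_k: float, n_k: int, r_1: float, n_1: int) -> float:
    """Two-sample Fisher-z comparison of correlations (treatment vs control).

    (atanh r_k - atanh r_1) / sqrt(1/(n_k-3) + 1/(n_1-3)); standard normal
    under equal population correlations.
    """
    if n_k <= 3 or n_1 <= 3:
        raise ValueError("correlation_shift requires more than 3 samples per group")

    def _at(r: float) -> float:
        if abs(r) >= 1.0:
            return float(np.sign(r) * _ATANH_CLAMP)
        return float(np.arctanh(r))

    return (_at(r_k) - _at(r_1)) / np.sqrt(1.0 / (n_k - 3) + 1.0 / (n_1 - 3))


def ternarize(stat: float, quantile: float = 0.95) -> float:
    """Map a standardized statistic to {-1, 0, +1} at the +/- normal quantile.

    Missing statistics (NaN) stay missing.
    """
    if np.isnan(stat):
        return np.nan
    thr = stats.norm.ppf(quantile)
    if stat > thr:
        return 1.0
    if stat < -thr:
        return -1.0
    return 0.0


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class InterpretableFeatures:
    """Standardized response statistics per feature (Sets 1-3)."""

    feature_ids: list[str]
    nutrition_names: list[str]
    treatment_levels: list[str]         # non-control levels, design order
    set1: np.ndarray                    # p x L
    set2: np.ndarray                    # p x (K-1)
    set3: np.ndarray                    # p x L x (K-1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, f in enumerate(self.feature_ids):
            for l, w in enumerate(self.nutrition_names):
                rows.append((f, "set1", w, "", self.set1[j, l]))
            for k, t in enumerate(self.treatment_levels):
                rows.append((f, "set2", "", t, self.set2[j, k]))
            for l, w in enumerate(self.nutrition_names):
                for k, t in enumerate(self.treatment_levels):
                    rows.append((f, "set3", w, t, self.set3[j, l, k]))
        return pd.DataFrame(rows, columns=["feature_id", "set", "nutrition", "treatment", "value"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def compute_interpretable_features(
    omics: OmicsMatrix, design: ExperimentDesign, config: RunConfig | None = None
) -> InterpretableFeatures:
    """Compute Sets 1-3 for every feature.

    Per-group statistics requiring more than 3 samples in both the group
    and the control are NaN where the sample sizes do not permit them.
    """
    config = config or RunConfig()
    Z, W = omics.Z, design.W
    p, n = Z.shape
    L = design.L
    groups = design.group_indices()
    levels = design.levels
    treat = levels[1:]
    ctrl_idx = groups[levels[0]]

    set1 = np.full((p, L), np.nan)
    if n > 3:
        for l in range(L):
            for j in range(p):
                r = _safe_corr(Z[j], W[:, l])
                set1[j, l] = np.nan if np.isnan(r) else fisher_z(
                    np.clip(r, -0.9999999999, 0.9999999999), n, config.literal_set1_scale
                )

    set2 = np.full((p, len(treat)), np.nan)
    for k, lev in enumerate(treat):
        idx = groups[lev]
        if len(idx) < 2 or len(ctrl_idx) < 2:
            continue
        for j in range(p):
            set2[j, k] = pairwise_t(Z[j, idx], Z[j, ctrl_idx])

    set3 = np.full((p, L, len(treat)), np.nan)
    n1 = len(ctrl_idx)
    for k, lev in enumerate(treat):
        idx = groups[lev]
        nk = len(idx)
        if nk <= 3 or n1 <= 3:
            continue
        for l in range(L):
            for j in range(p):
                rk = _safe_corr(Z[j, idx], W[idx, l])
                r1 = _safe_corr(Z[j, ctrl_idx], W[ctrl_idx, l])
                if np.isnan(rk) or np.isnan(r1):
                    continue
                set3[j, l, k] = correlation_shift(
                    np.clip(rk, -0.9999999999, 0.9999999999), nk,
                    np.clip(r1, -0.9999999999, 0.9999999999), n1,
                )
    return InterpretableFeatures(list(omics.feature_ids), list(design.nutrition_names), treat, set1, set2, set3)


@dataclass
class AnnotationRecord:
    """One emitted direction statement about a subcluster."""

    statistic_set: str                  # "set1" | "set2" | "set3"
    nutrition: str | None
    treatment: str | None
    direction: str                      # "increased" | "decreased"
    proportion: float

    def describe(self) -> str:
        if self.statistic_set == "set1":
            word = "positively correlated with" if self.direction == "increased" else "negatively correlated with"
            return f"{word} {self.nutrition}"
        if self.statistic_set == "set2":
            word = "up-regulated" if self.direction == "increased" else "down-regulated"
            return f"{word} under {self.treatment}"
        return f"{self.direction} correlation with {self.nutrition} in treatment group {self.treatment}"


@dataclass
class SubclusterAnnotation:
    subcluster_id: str
    records: list[AnnotationRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (self.subcluster_id, r.statistic_set, r.nutrition or "", r.treatment or "",
                 r.direction, r.proportion, r.describe())
                for r in self.records
            ],
            columns=["subcluster", "set", "nutrition", "treatment", "direction", "proportion", "annotation"],
        )


def _proportions(values: np.ndarray) -> tuple[float, float]:
    """(P, N): fractions of +1 and -1 over ALL members; NaN counts toward neither."""
    total = len(values)
    pos = np.nansum(values == 1)
    neg = np.nansum(values == -1)
    return pos / total, neg / total


def annotate_subcluster(
    member_ids: list[str],
    features: InterpretableFeatures,
    config: RunConfig | None = None,
) -> SubclusterAnnotation:
    """Emit direction records for every statistic cell where member agreement
    strictly exceeds the proportion threshold.

    Missing per-member statistics drop out of the numerator only, so sparse
    cells annotate conservatively.
    """
    config = config or RunConfig()
    if not member_ids:
        raise ValueError("subcluster has no members")
    idx = {f: i for i, f in enumerate(features.feature_ids)}
    rows = np.array([idx[m] for m in member_ids])
    q, thr = config.ternarize_quantile, config.proportion_threshold
    tern = np.vectorize(lambda v: ternarize(v, q))

    records: list[AnnotationRecord] = []
    for l, w in enumerate(features.nutrition_names):
        P, N = _proportions(tern(features.set1[rows, l]))
        if P > thr:
            records.append(AnnotationRecord("set1", w, None, "increased", P))
        if N > thr:
            records.append(AnnotationRecord("set1", w, None, "decreased", N))
    for k, t in enumerate(features.treatment_levels):
        P, N = _proportions(tern(features.set2[rows, k]))
        if P > thr:
            records.append(AnnotationRecord("set2", None, t, "increased", P))
        if N > thr:
            records.append(AnnotationRecord("set2", None, t, "decreased", N))
    for l, w in enumerate(features.nutrition_names):
        for k, t in enumerate(features.treatment_levels):
            P, N = _proportions(tern(features.set3[rows, l, k]))
            if P > thr:
                records.append(AnnotationRecord("set3", w, t, "increased", P))
            if N > thr:
                records.append(AnnotationRecord("set3", w, t, "decreased", N))
    return SubclusterAnnotation(subcluster_id="", records=records)


def annotate_subclusters(
    members_by_subcluster: dict[str, list[str]],
    features: InterpretableFeatures,
    config: RunConfig | None = None,
) -> list[SubclusterAnnotation]:
    out = []
    for sc_id, members in members_by_subcluster.items():
        ann = annotate_subcluster(members, features, config)
        ann.subcluster_id = sc_id
        out.append(ann)
    return out
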