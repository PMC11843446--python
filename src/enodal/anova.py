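"""Stage 1: nested linear models and the ANOVA-like testing cascade.

Each feature's abundance z_j is modelled against the nutrition matrix W
(continuous, L columns) and the treatment factor D (K levels, control as
reference) through five nested linear models:

    M1: mu + W beta + alpha_k + W gamma_k   (interaction)
    M2: mu + W beta + alpha_k               (additive)
    M3: mu + alpha_k                        (treatment only)
    M4: mu + W beta                         (nutrition only)
    M5: mu                                  (null)

The cascade assigns each feature one of five interpretable labels:

    layer 1  permutation F test of M5 vs M1 ("any effect")  -> "sig"/"nonsig"
    layer 2  F test of M2 vs M1 (interaction)               -> "NxD"
    layer 3  F tests of M4 vs M2 (treatment) and M3 vs M2 (nutrition)
             treatment only -> "D"; nutrition only -> "N"; rest -> "N+D"

P-values are adjusted hierarchically: Bonferroni (default) within each
layer, over the number of features actually tested at that layer; a
feature enters a layer only if its parent hypothesis was rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExperimentDesign, OmicsMatrix, RunConfig

logger = logging.getLogger("enodal")

MODEL_NAMES = ("M1", "M2", "M3", "M4", "M5")

_RANK_TOL = 1e-8


def _independent_columns(X: np.ndarray, tol: float = _RANK_TOL) -> np.ndarray:
    """Boolean mask of columns kept by greedy left-to-right rank selection.

    A column is dropped when its residual after projection onto the span of
    earlier kept columns is below ``tol`` relative to its norm. Left-to-right
    order guarantees that submodels built from column prefixes keep nested
    column sets, so the F-test degrees of freedom stay consistent.
    """
    n, p = X.shape
    keep = np.zeros(p, dtype=bool)
    Q = np.empty((n, 0))
    for j in range(p):
        v = X[:, j].astype(float)
        norm0 = np.linalg.norm(v)
        if norm0 == 0:
            continue
        r = v - Q @ (Q.T @ v)
        # one re-orthogonalization pass for numerical safety
        r = r - Q @ (Q.T @ r)
        if np.linalg.norm(r) > tol * norm0:
            keep[j] = True
            Q = np.hstack([Q, (r / np.linalg.norm(r))[:, None]])
    return keep


@dataclass
class ModelMatrix:
    """Predictor matrix of one nested model after collinearity drops."""

    name: str
    X: np.ndarray                 # n x q, kept columns only
    columns: list[str]            # kept column names
    dropped: list[str]            # names of exactly-collinear columns removed
    Q: np.ndarray = field(init=False)  # orthonormal basis of col span

    def __post_init__(self) -> None:
        q, _ = np.linalg.qr(self.X)
        self.Q = q

    @property
    def df_resid(self) -> int:
        return self.X.shape[0] - self.X.shape[1]

    @property
    def rank(self) -> int:
        return self.X.shape[1]


def build_design_matrices(design: ExperimentDesign) -> dict[str, ModelMatrix]:
    """Construct predictor matrices for M5..M1 with dummy-coded treatment.

    Column order: intercept, W columns (file order), treatment dummies
    (control level as reference), then W x dummy interaction products.
    Columns exactly collinear with earlier ones are dropped and recorded.
    """
    n, L = design.W.shape
    levels = design.levels
    d = design.D.astype(str)
    dummies = np.column_stack([(d == lev).astype(float) for lev in levels[1:]])
    names_w = list(design.nutrition_names)
    names_d = [f"trt[{lev}]" for lev in levels[1:]]

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    cols += [design.W[:, l] for l in range(L)]
    names += names_w
    cols += [dummies[:, k] for k in range(dummies.shape[1])]
    names += names_d
    for k in range(dummies.shape[1]):
        for l in range(L):
            cols.append(design.W[:, l] * dummies[:, k])
            names.append(f"{names_w[l]}:{names_d[k]}")
    full = np.column_stack(cols)

    # index ranges of each model within the full M1 column layout
    iw = list(range(1, 1 + L))
    idum = list(range(1 + L, 1 + L + len(names_d)))
    iint = list(range(1 + L + len(names_d), full.shape[1]))
    spec = {
        "M5": [0],
        "M4": [0] + iw,
        "M3": [0] + idum,
        "M2": [0] + iw + idum,
        "M1": [0] + iw + idum + iint,
    }
    out: dict[str, ModelMatrix] = {}
    for name, idx in spec.items():
        Xm = full[:, idx]
        keep = _independent_columns(Xm)
        kept_names = [names[i] for i, k in zip(idx, keep) if k]
        dropped = [names[i] for i, k in zip(idx, keep) if not k]
        if dropped:
            logger.warning("model %s: dropped collinear column(s) %s", name, dropped)
        out[name] = ModelMatrix(name, Xm[:, keep], kept_names, dropped)
    return out


@dataclass
class FittedNestedModels:
    """Least-squares fits of the five nested models for one feature."""

    rss: dict[str, float]
    df_resid: dict[str, int]
    coef: dict[str, dict[str, float]]   # model -> column name -> estimate
    dropped: dict[str, list[str]]


def _rss_via_basis(mm: ModelMatrix, z: np.ndarray) -> float:
    proj = mm.Q.T @ z
    return float(max(z @ z - proj @ proj, 0.0))


def fit_nested_models(
    matrices: dict[str, ModelMatrix], z: np.ndarray
) -> FittedNestedModels:
    """Fit all five models to one abundance vector by least squares."""
    z = np.asarray(z, dtype=float)
    rss: dict[str, float] = {}
    dfs: dict[str, int] = {}
    coefs: dict[str, dict[str, float]] = {}
    dropped: dict[str, list[str]] = {}
    for name in MODEL_NAMES:
        mm = matrices[name]
        beta, *_ = np.linalg.lstsq(mm.X, z, rcond=None)
        resid = z - mm.X @ beta
        rss[name] = float(resid @ resid)
        dfs[name] = mm.df_resid
        coefs[name] = dict(zip(mm.columns, beta.tolist()))
        dropped[name] = list(mm.dropped)
    return FittedNestedModels(rss, dfs, coefs, dropped)


def nested_f_test(
    rss_null: float, df_null: int, rss_full: float, df_full: int
) -> tuple[float, float]:
    """Extra-sum-of-squares F test of a null model nested in a full model.

    Returns (F, p). Degenerate cases: zero full-model residual gives p = 0
    when the null model leaves residual, else p = 1.
    """
    ddf = df_null - df_full
    if ddf < 1:
        raise ValueError("null model must have strictly more residual df than full model")
    if rss_full <= 0:
        return (np.inf, 0.0) if rss_null > 0 else (0.0, 1.0)
    F = ((rss_null - rss_full) / ddf) / (rss_full / df_full)
    F = max(F, 0.0)
    return F, float(stats.f.sf(F, ddf, df_full))


def _feature_rng(master_seed: int, feature_index: int) -> np.random.Generator:
    """Counter-based per-feature generator: stable under adding features."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(1, feature_index))
    return np.random.Generator(np.random.PCG64(ss))


def _lc_stat(z: np.ndarray, Q1: np.ndarray, ddf: int, df1: int) -> float:
    n = z.shape[0]
    zz = z @ z
    rss5 = zz - n * z.mean() ** 2
    proj = Q1.T @ z
    rss1 = max(zz - proj @ proj, 0.0)
    if rss1 <= 0:
        return np.inf if rss5 > 0 else 0.0
    return max(((rss5 - rss1) / ddf) / (rss1 / df1), 0.0)


def lc_test(
    matrices: dict[str, ModelMatrix],
    z: np.ndarray,
    B: int,
    seed: int,
    feature_index: int = 0,
) -> float:
    """Global permutation F test of M5 (pure noise) against M1 (full model).

    The observed statistic is the extra-sum-of-squares F comparing the
    intercept-only model with the full interaction model; the null
    distribution is formed by B random permutations of the abundance
    entries with the design held fixed. Permutations for feature j are
    seeded as (master seed, j), so results do not depend on how many other
    features are processed. Returns p = (1 + #{F_perm >= F_obs}) / (B + 1).
    """
    z = np.asarray(z, dtype=float)
    if np.ptp(z) == 0:
        return 1.0
    m1 = matrices["M1"]
    ddf = matrices["M5"].df_resid - m1.df_resid
    f_obs = _lc_stat(z, m1.Q, ddf, m1.df_resid)
    rng = _feature_rng(seed, feature_index)
    n = z.shape[0]
    perms = np.argsort(rng.random((B, n)), axis=1)
    # sorted values assigned to canonically ordered design rows: the draws
    # become a function of the data multiset only, so p is exactly invariant
    # to any sample reordering applied jointly to (W, D, z)
    canon = np.lexsort(np.vstack([z[None, :], m1.X.T]))
    Zp = np.sort(z)[perms]              # B x n
    zz = z @ z
    rss5 = zz - n * z.mean() ** 2       # permutation invariant
    proj = m1.Q[canon].T @ Zp.T         # q x B
    rss1 = np.maximum(zz - np.einsum("qb,qb->b", proj, proj), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = ((rss5 - rss1) / ddf) / (rss1 / m1.df_resid)
    f_perm = np.where(rss1 <= 0, np.inf, f_perm)
    return float((1 + np.sum(f_perm >= f_obs)) / (B + 1))


def hierarchical_adjust(
    p_values: np.ndarray, n_tested: int, alpha: float, method: str = "bonferroni"
) -> tuple[np.ndarray, np.ndarray]:
    """Within-layer multiplicity adjustment over the features tested there.

    Bonferroni multiplies by the layer's test count (FWER control); the
    "bh" option applies Benjamini-Hochberg step-up instead. Returns
    (adjusted p, reject flags at level alpha).
    """
    p = np.asarray(p_values, dtype=float)
    if method == "bonferroni":
        adj = np.minimum(p * n_tested, 1.0)
    elif method == "bh":
        from statsmodels.stats.multitest import multipletests

        if len(p) == 0:
            adj = p.copy()
        else:
            adj = multipletests(p, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown adjustment method '{method}'")
    return adj, adj <= alpha


@dataclass
class GroupAssignment:
    """Per-feature interpretable-group labels and the cascade's p-values."""

    feature_ids: list[str]
    labels: np.ndarray                  # str array, values in GROUP_LABELS
    p_global: np.ndarray
    p_global_adj: np.ndarray
    p_interaction: np.ndarray           # NaN when layer not entered
    p_interaction_adj: np.ndarray
    p_treatment: np.ndarray
    p_treatment_adj: np.ndarray
    p_nutrition: np.ndarray
    p_nutrition_adj: np.ndarray
    tested_interaction: np.ndarray
    tested_main: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "label": self.labels,
                "p_global": self.p_global,
                "p_global_adj": self.p_global_adj,
                "p_interaction": self.p_interaction,
                "p_interaction_adj": self.p_interaction_adj,
                "p_treatment": self.p_treatment,
                "p_treatment_adj": self.p_treatment_adj,
                "p_nutrition": self.p_nutrition,
                "p_nutrition_adj": self.p_nutrition_adj,
                "tested_interaction": self.tested_interaction,
                "tested_main": self.tested_main,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    def members(self, label: str) -> list[str]:
        return [f for f, lab in zip(self.feature_ids, self.labels) if lab == label]


def _batch_rss(mm: ModelMatrix, Z: np.ndarray) -> np.ndarray:
    """Residual sum of squares of one model for every feature (rows of Z)."""
    proj = Z @ mm.Q                    # p x q
    zz = np.einsum("ij,ij->i", Z, Z)
    return np.maximum(zz - np.einsum("ij,ij->i", proj, proj), 0.0)


def classify_features(
    omics: OmicsMatrix, design: ExperimentDesign, config: RunConfig
) -> GroupAssignment:
    """Run the three-layer testing cascade over all features.

    Layer 1 (global): permutation F test M5 vs M1, adjusted over all p
    features; non-rejections are labelled "nonsig". Layer 2 (interaction):
    F test M2 vs M1 on the survivors; rejections are "NxD". Layer 3 (main
    effects) on the remainder: treatment (M4 vs M2) and nutrition
    (M3 vs M2); treatment only -> "D", nutrition only -> "N", both or
    neither -> "N+D".
    """
    Z = omics.Z
    p, n = Z.shape
    matrices = build_design_matrices(design)
    if config.rank_transform:
        Z = np.apply_along_axis(stats.rankdata, 1, Z)
    if n <= matrices["M1"].rank:
        logger.warning(
            "n = %d too small for the %d-column interaction model; all features untestable",
            n, matrices["M1"].rank,
        )
        nan = np.full(p, np.nan)
        return GroupAssignment(
            omics.feature_ids, np.full(p, "nonsig", dtype=object),
            np.ones(p), np.ones(p), nan, nan.copy(), nan.copy(), nan.copy(),
            nan.copy(), nan.copy(), np.zeros(p, bool), np.zeros(p, bool),
        )

    m1 = matrices["M1"]
    ddf_global = matrices["M5"].df_resid - m1.df_resid

    # layer 1: vectorised permutation F test with per-feature seeding
    if config.adjust_method == "bonferroni" and p / (config.n_permutations + 1) > config.alpha:
        logger.warning(
            "smallest permutation p-value 1/%d cannot clear the Bonferroni "
            "threshold %g/%d; use n_permutations >= %d or adjust_method='bh'",
            config.n_permutations + 1, config.alpha, p,
            int(np.ceil(p / config.alpha)) - 1,
        )
    p_global = np.empty(p)
    zz = np.einsum("ij,ij->i", Z, Z)
    rss5_all = zz - n * Z.mean(axis=1) ** 2
    rss1_all = _batch_rss(m1, Z)
    B = config.n_permutations
    for j in range(p):
        z = Z[j]
        if np.ptp(z) == 0:
            p_global[j] = 1.0
            continue
        rss1, rss5 = rss1_all[j], rss5_all[j]
        if rss1 <= 0:
            f_obs = np.inf if rss5 > 0 else 0.0
        else:
            f_obs = max(((rss5 - rss1) / ddf_global) / (rss1 / m1.df_resid), 0.0)
        rng = _feature_rng(config.seed, j)
        perms = np.argsort(rng.random((B, n)), axis=1)
        canon = np.lexsort(np.vstack([z[None, :], m1.X.T]))
        proj = m1.Q[canon].T @ np.sort(z)[perms].T
        rss1_perm = np.maximum(zz[j] - np.einsum("qb,qb->b", proj, proj), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = ((rss5 - rss1_perm) / ddf_global) / (rss1_perm / m1.df_resid)
        f_perm = np.where(rss1_perm <= 0, np.inf, f_perm)
        p_global[j] = (1 + np.sum(f_perm >= f_obs)) / (B + 1)

    p_global_adj, reject_global = hierarchical_adjust(
        p_global, p, config.alpha, config.adjust_method
    )

    labels = np.full(p, "nonsig", dtype=object)
    nan = np.full(p, np.nan)
    p_int, p_int_adj = nan.copy(), nan.copy()
    p_trt, p_trt_adj = nan.copy(), nan.copy()
    p_nut, p_nut_adj = nan.copy(), nan.copy()
    tested_int = reject_global.copy()
    tested_main = np.zeros(p, bool)

    c0 = np.flatnonzero(reject_global)
    if c0.size:
        # layer 2: interaction, M2 vs M1
        rss2 = _batch_rss(matrices["M2"], Z[c0])
        rss1 = rss1_all[c0]
        praw = np.array(
            [
                nested_f_test(r2, matrices["M2"].df_resid, r1, m1.df_resid)[1]
                for r2, r1 in zip(rss2, rss1)
            ]
        )
        p_int[c0] = praw
        adj, rej = hierarchical_adjust(praw, c0.size, config.alpha, config.adjust_method)
        p_int_adj[c0] = adj
        labels[c0[rej]] = "NxD"

        # layer 3: main effects on C0 \ C_int
        rest = c0[~rej]
        tested_main[rest] = True
        if rest.size:
            rss2r = _batch_rss(matrices["M2"], Z[rest])
            rss4 = _batch_rss(matrices["M4"], Z[rest])
            rss3 = _batch_rss(matrices["M3"], Z[rest])
            df2 = matrices["M2"].df_resid
            ptrt = np.array(
                [
                    nested_f_test(r4, matrices["M4"].df_resid, r2, df2)[1]
                    for r4, r2 in zip(rss4, rss2r)
                ]
            )
            pnut = np.array(
                [
                    nested_f_test(r3, matrices["M3"].df_resid, r2, df2)[1]
                    for r3, r2 in zip(rss3, rss2r)
                ]
            )
            p_trt[rest], p_nut[rest] = ptrt, pnut
            adj_t, rej_t = hierarchical_adjust(ptrt, rest.size, config.alpha, config.adjust_method)
            adj_n, rej_n = hierarchical_adjust(pnut, rest.size, config.alpha, config.adjust_method)
            p_trt_adj[rest], p_nut_adj[rest] = adj_t, adj_n
            lab = np.where(
                rej_t & ~rej_n, "D", np.where(rej_n & ~rej_t, "N", "N+D")
            )
            labels[rest] = lab

    return GroupAssignment(
        omics.feature_ids, labels, p_global, p_global_adj,
        p_int, p_int_adj, p_trt, p_trt_adj, p_nut, p_nut_adj,
        tested_int, tested_main,
    )
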