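"""Core data containers, validation, and tabular I/O.

All downstream stages consume only the types defined here. Sample
alignment between the design table, the omics matrix and the phenotype
matrix is established exactly once, at load time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("enodal")

GROUP_LABELS = ("NxD", "N+D", "N", "D", "nonsig")


class ValidationError(ValueError):
    """Raised when an input table violates a structural precondition."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class ExperimentDesign:
    """Factorial design: continuous nutrition intakes W and a treatment factor D.

    Parameters
    ----------
    sample_ids : list of str
        Sample identifiers, one per row of ``W``.
    W : ndarray, shape (n, L)
        Continuous nutrition intakes (e.g. grams of food, kJ of protein,
        carbohydrate and fat). Columns may be nearly collinear (energy is
        close to the sum of macronutrient energies); downstream model
        fitting handles exact rank deficiency.
    D : ndarray of str, shape (n,)
        Treatment level per sample (K levels).
    control_level : str
        The level of ``D`` treated as the reference (control) group.
    nutrition_names : list of str
        Column names of ``W``.
    """

    sample_ids: list[str]
    W: np.ndarray
    D: np.ndarray
    control_level: str
    nutrition_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.D = np.asarray(self.D, dtype=object)
        n = len(self.sample_ids)
        if self.W.ndim != 2 or self.W.shape[0] != n:
            raise ValidationError(
                f"W has shape {self.W.shape}, expected ({n}, L) aligned to sample_ids"
            )
        if len(self.D) != n:
            raise ValidationError("treatment vector length does not match sample count")
        if not np.all(np.isfinite(self.W)):
            bad = np.argwhere(~np.isfinite(self.W))[0]
            raise ValidationError(
                f"non-finite nutrition value at sample {self.sample_ids[bad[0]]}, "
                f"column {self.nutrition_names[bad[1]] if self.nutrition_names else bad[1]}"
            )
        if any(d is None or (isinstance(d, float) and np.isnan(d)) for d in self.D):
            raise ValidationError("missing values in treatment column")
        levels, counts = np.unique(self.D.astype(str), return_counts=True)
        if len(levels) < 2:
            raise ValidationError("treatment factor needs at least 2 levels")
        for lev, c in zip(levels, counts):
            if c < 2:
                raise ValidationError(
                    f"treatment level '{lev}' has only {c} sample(s); at least 2 required"
                )
        if self.control_level not in levels:
            raise ValidationError(f"control level '{self.control_level}' not found in treatment column")
        if not self.nutrition_names:
            self.nutrition_names = [f"w{l + 1}" for l in range(self.W.shape[1])]

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def L(self) -> int:
        return self.W.shape[1]

    @property
    def levels(self) -> list[str]:
        """Treatment levels: control first, the rest sorted lexicographically.

        Sorting makes the dummy-coding order independent of sample order.
        """
        others = sorted(set(self.D.astype(str)) - {self.control_level})
        return [self.control_level] + others

    @property
    def K(self) -> int:
        return len(self.levels)

    def group_indices(self) -> dict[str, np.ndarray]:
        """Sample indices per treatment level (control first)."""
        d = self.D.astype(str)
        return {lev: np.flatnonzero(d == lev) for lev in self.levels}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.W, columns=self.nutrition_names)
        df.insert(0, "treatment", self.D.astype(str))
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


@dataclass
class OmicsMatrix:
    """Abundance matrix, features in rows (p x n), aligned to a design."""

    feature_ids: list[str]
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dup = pd.Index(self.feature_ids)
            dup = dup[dup.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature IDs: {dup}")
        if self.Z.ndim != 2 or self.Z.shape[0] != len(self.feature_ids):
            raise ValidationError(
                f"Z has shape {self.Z.shape}, expected ({len(self.feature_ids)}, n)"
            )

    @property
    def p(self) -> int:
        return self.Z.shape[0]

    @property
    def n(self) -> int:
        return self.Z.shape[1]

    def drop_incomplete(self) -> "OmicsMatrix":
        """Drop features (rows) containing any missing value, with a warning."""
        keep = np.all(np.isfinite(self.Z), axis=1)
        if not keep.all():
            dropped = [f for f, k in zip(self.feature_ids, keep) if not k]
            logger.warning(
                "dropping %d feature(s) with missing values: %s%s",
                len(dropped), ", ".join(dropped[:5]), "..." if len(dropped) > 5 else "",
            )
            return OmicsMatrix(
                [f for f, k in zip(self.feature_ids, keep) if k], self.Z[keep]
            )
        return self

    def subset(self, feature_ids: list[str]) -> "OmicsMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in feature_ids]
        return OmicsMatrix(list(feature_ids), self.Z[rows])

    def to_frame(self, sample_ids: list[str] | None = None) -> pd.DataFrame:
        cols = sample_ids if sample_ids is not None else [f"s{i + 1}" for i in range(self.n)]
        df = pd.DataFrame(self.Z, columns=cols)
        df.insert(0, "feature_id", self.feature_ids)
        return df

    def write(self, path: str | Path, sample_ids: list[str] | None = None) -> None:
        # %.17g round-trips IEEE doubles exactly
        self.to_frame(sample_ids).to_csv(
            path, sep=_sep_for(path), index=False, float_format="%.17g"
        )


@dataclass
class PhenotypeMatrix:
    """Continuous traits per sample (n x m), aligned to the design order."""

    phenotype_ids: list[str]
    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[1] != len(self.phenotype_ids):
            raise ValidationError(
                f"P has shape {self.P.shape}, expected (n, {len(self.phenotype_ids)})"
            )
        if len(self.phenotype_ids) < 1:
            raise ValidationError("at least one phenotype required")

    @property
    def m(self) -> int:
        return len(self.phenotype_ids)

    def write(self, path: str | Path, sample_ids: list[str] | None = None) -> None:
        df = pd.DataFrame(self.P, columns=self.phenotype_ids)
        cols = sample_ids if sample_ids is not None else [f"s{i + 1}" for i in range(self.P.shape[0])]
        df.insert(0, "sample_id", cols)
        df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


@dataclass
class GeneSetCollection:
    """Named feature sets (GMT semantics) used for over-representation analysis."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set '{name}' is empty")


@dataclass
class RunConfig:
    """Tunable parameters for a full run.

    alpha : per-layer significance level of the testing cascade.
    n_permutations : permutation count B of the stage-1 global test.
    ternarize_quantile : standard-normal quantile used to ternarize the
        interpretable statistics (0.95 -> threshold 1.6449).
    proportion_threshold : fraction of subcluster members that must agree
        before an annotation record is emitted (strict inequality).
    """

    alpha: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    distance_metrics: tuple[str, ...] = ("pearson", "spearman", "euclidean")
    consensus_edge_threshold: float = 0.5
    louvain_resolution: float = 1.0
    ternarize_quantile: float = 0.95
    proportion_threshold: float = 0.7
    min_group_size_for_clustering: int = 10
    adjust_method: str = "bonferroni"  # or "bh"
    rank_transform: bool = False       # nonparametric stage-1 variant
    literal_set1_scale: bool = False   # keep the (1/sqrt(n-3)) reading of Set 1
    network_p_cut: float = 0.01
    multiset_method: str = "ranksum"   # or "meanrank"
    tree_cut_sensitivity: float = 0.5  # deep-split-like parameter in (0, 1)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.n_permutations < 99:
            raise ValidationError("n_permutations must be >= 99")
        if not 0 < self.proportion_threshold < 1:
            raise ValidationError("proportion_threshold must lie in (0, 1)")
        if self.adjust_method not in ("bonferroni", "bh"):
            raise ValidationError("adjust_method must be 'bonferroni' or 'bh'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        extra = set(data) - known
        if extra:
            raise ValidationError(f"unknown config keys: {sorted(extra)}")
        if "distance_metrics" in data:
            data["distance_metrics"] = tuple(data["distance_metrics"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["distance_metrics"] = list(d["distance_metrics"])
        return d


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_design(
    path: str | Path,
    sample_col: str = "sample_id",
    treatment_col: str = "treatment",
    control_level: str | None = None,
) -> ExperimentDesign:
    """Read a sample table: sample ID, treatment level, nutrition columns.

    Nutrition columns are every column other than the sample and treatment
    columns, in file order; all must be numeric. The control level defaults
    to the first level occurring in the file.
    """
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if treatment_col not in df.columns:
        raise ValidationError(f"missing treatment column '{treatment_col}' in {path}")
    if sample_col not in df.columns:
        raise ValidationError(f"missing sample column '{sample_col}' in {path}")
    if df[treatment_col].isna().any():
        raise ValidationError("missing values in treatment column")
    nut_cols = [c for c in df.columns if c not in (sample_col, treatment_col)]
    if not nut_cols:
        raise ValidationError("no nutrition columns found")
    W = np.empty((len(df), len(nut_cols)))
    for jc, c in enumerate(nut_cols):
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValidationError(
                f"non-numeric value in nutrition column '{c}' at row {row + 2} "
                f"(sample {df[sample_col].iloc[row]})"
            )
        W[:, jc] = vals.to_numpy()
    ctrl = control_level if control_level is not None else str(df[treatment_col].iloc[0])
    return ExperimentDesign(
        sample_ids=[str(s) for s in df[sample_col]],
        W=W,
        D=df[treatment_col].astype(str).to_numpy(dtype=object),
        control_level=ctrl,
        nutrition_names=nut_cols,
    )


def read_matrix(path: str | Path, design: ExperimentDesign) -> OmicsMatrix:
    """Read a features-in-rows abundance table and align columns to the design.

    First column holds feature IDs; remaining headers are sample IDs. The
    returned matrix columns follow the design's sample order exactly.
    """
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    feat_col = df.columns[0]
    feature_ids = [str(f) for f in df[feat_col]]
    if len(set(feature_ids)) != len(feature_ids):
        dup = pd.Index(feature_ids)
        raise ValidationError(
            f"duplicate feature IDs: {dup[dup.duplicated()].unique().tolist()}"
        )
    have = set(df.columns[1:])
    missing = [s for s in design.sample_ids if s not in have]
    if missing:
        raise ValidationError(f"samples in design but not in matrix: {missing}")
    Z = df[design.sample_ids].to_numpy(dtype=float)
    return OmicsMatrix(feature_ids, Z).drop_incomplete()


def read_phenotypes(path: str | Path, design: ExperimentDesign) -> PhenotypeMatrix:
    """Read a samples-in-rows phenotype table and align rows to the design."""
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    sample_col = df.columns[0]
    df = df.set_index(df[sample_col].astype(str))
    missing = [s for s in design.sample_ids if s not in df.index]
    if missing:
        raise ValidationError(f"samples in design but not in phenotypes: {missing}")
    df = df.loc[design.sample_ids].drop(columns=[sample_col])
    return PhenotypeMatrix(list(df.columns), df.to_numpy(dtype=float))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB member IDs. Empty lines skipped."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            name, desc, *members = parts
            if name in sets:
                raise ValidationError(f"GMT line {lineno}: duplicate set name '{name}'")
            members = frozenset(m for m in members if m)
            if not members:
                raise ValidationError(f"GMT line {lineno}: set '{name}' has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)
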