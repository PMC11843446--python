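"""Synthetic factorial nutrition-by-treatment datasets with known ground truth.

The generator emulates the structure of a geometric-framework feeding
study: a grid of diets (macronutrient ratios crossed with energy
densities) times a categorical treatment arm (control plus drugs), with
per-animal intake noise. Features are drawn from the five nested linear
model classes with configurable effect scales (in units of the residual
noise standard deviation), and features sharing a planted pattern share
coefficient directions, giving recoverable subcluster structure.
Phenotypes can be linked to planted patterns for end-to-end network tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExperimentDesign, OmicsMatrix, PhenotypeMatrix

# expected cascade label for each generating model class
MODEL_TO_LABEL = {"M1": "NxD", "M2": "N+D", "M3": "D", "M4": "N", "M5": "nonsig"}

_DEFAULT_RATIOS = (
    (0.60, 0.20, 0.20),
    (0.42, 0.29, 0.29),
    (0.25, 0.42, 0.33),
    (0.14, 0.57, 0.29),
    (0.10, 0.45, 0.45),
)


@dataclass
class SimulationSpec:
    """Study-shape and effect-size parameters of a simulated experiment.

    Defaults mirror the mouse feeding design: 10 diets (five protein:
    carbohydrate:fat ratios at two energy densities), four treatment arms
    (control + three drugs), two replicates per diet x treatment cell
    (n = 80), and four correlated intake variables (food grams, protein,
    carbohydrate and fat energy). Effect scales are expressed in noise-sd
    units so power statements transfer across noise levels.
    """

    n_per_cell: int = 2
    n_treatments: int = 4
    macronutrient_ratios: tuple = _DEFAULT_RATIOS
    energy_densities: tuple = (8.0, 13.0)
    mean_intake_g: float = 3.0
    intake_noise_cv: float = 0.10
    feature_counts: dict = field(
        default_factory=lambda: {"M1": 50, "M2": 50, "M3": 50, "M4": 50, "M5": 50}
    )
    beta_scale: float = 1.0
    alpha_scale: float = 2.0
    gamma_scale: float = 1.0
    noise_sd: float = 1.0
    patterns_per_group: int = 2
    phenotype_links: tuple = ()        # ((pattern_id, strength), ...)
    n_null_phenotypes: int = 1
    phenotype_noise_sd: float = 1.0
    seed: int = 0

    @property
    def n_diets(self) -> int:
        return len(self.macronutrient_ratios) * len(self.energy_densities)

    @property
    def n_samples(self) -> int:
        return self.n_diets * self.n_treatments * self.n_per_cell


@dataclass
class GroundTruth:
    """Generating model class, pattern, and coefficients per feature."""

    feature_ids: list[str]
    models: np.ndarray                  # "M1".."M5" per feature
    patterns: np.ndarray                # pattern id, e.g. "M1_P1"
    beta: np.ndarray                    # p x L (standardized-W scale)
    alpha: np.ndarray                   # p x (K-1)
    gamma: np.ndarray                   # p x L x (K-1)
    links: dict = field(default_factory=dict)  # phenotype -> (pattern, strength)

    @property
    def expected_labels(self) -> np.ndarray:
        return np.array([MODEL_TO_LABEL[m] for m in self.models], dtype=object)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "model": self.models,
                "pattern": self.patterns,
                "expected_label": self.expected_labels,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(7, stream))
    return np.random.Generator(np.random.PCG64(ss))


def simulate_design(spec: SimulationSpec) -> ExperimentDesign:
    """Balanced diet-grid x treatment design with per-animal intake noise.

    Nutrition columns: food intake (g), then protein, carbohydrate and fat
    intake (kJ), computed from each animal's intake, its diet's energy
    density, and the diet's macronutrient ratio. The energy columns sum to
    the total energy implied by grams x density, so W is near-collinear by
    construction, as in real feeding data.
    """
    rng = _rng(spec, 0)
    treatments = ["control"] + [f"drug{i}" for i in range(1, spec.n_treatments)]
    sample_ids, rows, D = [], [], []
    i = 0
    for di, (ratio, dens) in enumerate(
        (r, e) for e in spec.energy_densities for r in spec.macronutrient_ratios
    ):
        for trt in treatments:
            for _ in range(spec.n_per_cell):
                # compensatory feeding: eat fewer grams of denser food
                base = spec.mean_intake_g * (np.mean(spec.energy_densities) / dens)
                grams = base * (1 + spec.intake_noise_cv * rng.standard_normal())
                grams = max(grams, 0.1 * base)
                energy = grams * dens
                rows.append([grams, energy * ratio[0], energy * ratio[1], energy * ratio[2]])
                D.append(trt)
                i += 1
                sample_ids.append(f"s{i:03d}")
    return ExperimentDesign(
        sample_ids=sample_ids,
        W=np.array(rows),
        D=np.array(D, dtype=object),
        control_level="control",
        nutrition_names=["intake_g", "protein_kj", "carb_kj", "fat_kj"],
    )


def simulate_omics(
    design: ExperimentDesign, spec: SimulationSpec
) -> tuple[OmicsMatrix, GroundTruth]:
    """Draw features from their assigned nested-model class.

    z_j = mu_j + Ws beta_j + alpha_jk + Ws gamma_jk + eps, with Ws the
    column-standardized nutrition matrix (so effect scales are per
    noise-sd), eps ~ N(0, noise_sd^2). Coefficient direction vectors are
    shared within a pattern; magnitudes jitter by +/-20%.
    """
    rng = _rng(spec, 1)
    n, L = design.W.shape
    K = design.K
    sd = design.W.std(axis=0)
    Ws = (design.W - design.W.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    d = design.D.astype(str)
    dummies = np.column_stack([(d == lev).astype(float) for lev in design.levels[1:]])

    feature_ids, models, patterns = [], [], []
    p_total = sum(spec.feature_counts.get(m, 0) for m in ("M1", "M2", "M3", "M4", "M5"))
    beta = np.zeros((p_total, L))
    alpha = np.zeros((p_total, K - 1))
    gamma = np.zeros((p_total, L, K - 1))

    j = 0
    for model in ("M1", "M2", "M3", "M4", "M5"):
        count = spec.feature_counts.get(model, 0)
        if count == 0:
            continue
        n_pat = max(1, spec.patterns_per_group) if model != "M5" else 1
        # shared direction vectors per pattern
        dirs = []
        for _ in range(n_pat):
            db = rng.choice([-1.0, 1.0], size=L)
            da = rng.choice([-1.0, 1.0], size=K - 1)
            dg = rng.choice([-1.0, 1.0], size=(L, K - 1))
            dirs.append((db, da, dg))
        for c in range(count):
            pat = c % n_pat
            db, da, dg = dirs[pat]
            jit = lambda size: rng.uniform(0.8, 1.2, size=size)  # noqa: E731
            if model in ("M1", "M2", "M4"):
                beta[j] = spec.beta_scale * db * jit(L)
            if model in ("M1", "M2", "M3"):
                alpha[j] = spec.alpha_scale * da * jit(K - 1)
            if model == "M1":
                gamma[j] = spec.gamma_scale * dg * jit((L, K - 1))
            feature_ids.append(f"{model}_f{c + 1:04d}")
            models.append(model)
            patterns.append(f"{model}_P{pat + 1}")
            j += 1

    mu = rng.normal(0, 1, size=p_total)
    eps = rng.normal(0, spec.noise_sd, size=(p_total, n))
    signal = (
        beta @ Ws.T
        + alpha @ dummies.T
        + np.einsum("jlk,nl,nk->jn", gamma, Ws, dummies)
    )
    Z = mu[:, None] + signal + eps
    truth = GroundTruth(
        feature_ids, np.array(models, dtype=object), np.array(patterns, dtype=object),
        beta, alpha, gamma,
    )
    return OmicsMatrix(feature_ids, Z), truth


def simulate_phenotypes(
    omics: OmicsMatrix, truth: GroundTruth, spec: SimulationSpec
) -> PhenotypeMatrix:
    """Phenotypes driven by planted patterns plus pure-noise phenotypes.

    A linked phenotype equals strength x the standardized per-sample mean
    of its driving pattern's features, plus N(0, phenotype_noise_sd^2)
    noise. Unlinked phenotypes are pure noise.
    """
    rng = _rng(spec, 2)
    n = omics.n
    cols, names = [], []
    links: dict[str, tuple[str, float]] = {}
    for li, (pattern, strength) in enumerate(spec.phenotype_links):
        rows = np.flatnonzero(truth.patterns == pattern)
        if rows.size == 0:
            raise ValueError(f"phenotype link references unknown pattern '{pattern}'")
        profile = omics.Z[rows].mean(axis=0)
        psd = profile.std()
        profile = (profile - profile.mean()) / (psd if psd > 0 else 1.0)
        name = f"pheno_{pattern}"
        cols.append(strength * profile + rng.normal(0, spec.phenotype_noise_sd, n))
        names.append(name)
        links[name] = (pattern, strength)
    for q in range(spec.n_null_phenotypes):
        names.append(f"pheno_null{q + 1}")
        cols.append(rng.normal(0, spec.phenotype_noise_sd, n))
    truth.links = links
    return PhenotypeMatrix(names, np.column_stack(cols) if cols else np.empty((n, 0)))


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[ExperimentDesign, OmicsMatrix, GroundTruth, PhenotypeMatrix]:
    """Convenience wrapper: design, omics, ground truth, phenotypes."""
    design = simulate_design(spec)
    omics, truth = simulate_omics(design, spec)
    phenotypes = simulate_phenotypes(omics, truth, spec)
    return design, omics, truth, phenotypes
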