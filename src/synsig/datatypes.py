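"""Core domain containers shared across the pipeline stages.

All containers are thin dataclasses around pandas objects; the matrices
are genes x samples on log2 scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

#: z threshold for calling a gene up/down-regulated after treatment
#: (two-sided 5% normal critical value).
Z_THRESHOLD = 1.96

#: Probabilities are clamped to [CLAMP_EPS, 1 - CLAMP_EPS] before any
#: logarithm or normal quantile, which bounds |z| at about 7.94.
CLAMP_EPS = 1e-15

Direction = Literal["up", "down"]
Regulation = Literal["up", "down", "none"]


class ValidationError(ValueError):
    """Raised when an input matrix or annotation violates the contract."""


@dataclass
class ExpressionDataset:
    """A two-group log2 expression matrix.

    Parameters
    ----------
    values
        DataFrame of log2 expression, genes as index, samples as columns.
    groups
        Series mapping sample id -> group label.  Disease data uses
        ``case`` / ``control``; drug data uses ``treated`` / ``control``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in matrix")
        if self.groups.index.duplicated().any():
            raise ValidationError("sample annotated more than once")
        matrix_samples = set(self.values.columns)
        annot_samples = set(self.groups.index)
        if matrix_samples != annot_samples:
            missing = sorted(matrix_samples - annot_samples)
            extra = sorted(annot_samples - matrix_samples)
            raise ValidationError(
                f"sample ids disagree between matrix and annotation "
                f"(unannotated: {missing[:5]}, unknown: {extra[:5]})"
            )
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)]
            raise ValidationError(
                f"missing values are not accepted (first gene: {bad[0]!r})"
            )
        # align annotation order with matrix columns
        self.groups = self.groups.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def group_matrix(self, label: str) -> np.ndarray:
        """Return the genes x samples sub-matrix for one group label."""
        cols = self.groups.index[self.groups == label]
        return self.values.loc[:, cols].to_numpy(dtype=float)

    def group_size(self, label: str) -> int:
        return int((self.groups == label).sum())


@dataclass
class DiseaseSignature:
    """Up/down DEG calls for one disease after significance + fold-change
    filtering; ``N`` is the signature size entering the score denominator."""

    disease_id: str
    calls: pd.Series  # gene -> "up" | "down"
    alpha_bh: float
    min_fold_change: float
    stats: Optional[pd.DataFrame] = None  # per-gene t, p, p_adj, log2fc

    @property
    def N(self) -> int:
        return int(len(self.calls))


@dataclass
class DrugZProfile:
    """Per-gene signed z-scores for a single treatment.

    ``regulation`` is derived from ``z`` by the +/-1.96 rule; treatments
    are single drugs here and unordered pairs in :class:`ComboZProfile`.
    """

    treatment_id: str
    z: pd.Series  # gene -> signed z
    regulation: pd.Series  # gene -> up/down/none
    t: Optional[pd.Series] = None

    @property
    def gene_ids(self) -> pd.Index:
        return self.z.index


@dataclass
class ComboZProfile:
    """Combined z'-profile for an unordered drug pair."""

    pair: tuple[str, str]
    p_s: pd.Series  # gene -> combined probability
    z: pd.Series  # gene -> z' = Phi^-1(p_s)
    regulation: pd.Series

    @property
    def treatment_id(self) -> str:
        return f"{self.pair[0]}+{self.pair[1]}"

    @property
    def gene_ids(self) -> pd.Index:
        return self.z.index


@dataclass
class MatchTable:
    """Signature genes with a non-null drug response, with the matching
    coefficient I (+1 opposite direction, -1 same direction) and |z|."""

    treatment_id: str
    disease_id: str
    rows: pd.DataFrame  # gene, disease_direction, drug_regulation, I, magnitude

    @property
    def k(self) -> int:
        return int(len(self.rows))


@dataclass
class ScoreRecord:
    """Indicator score of one treatment against one disease.

    ``score = mean_signed * k / N`` where ``mean_signed`` is the mean of
    I*|z| over matched genes; ``p_k = Phi(mean_signed)`` is reported for
    reference.  ``flag`` is non-empty for unrankable records (k = 0 or
    N = 0), whose score is NaN rather than a silent zero.
    """

    treatment_id: str
    disease_id: str
    k: int
    N: int
    mean_signed: float
    p_k: float
    score: float
    flag: str = ""

    @property
    def rankable(self) -> bool:
        return self.flag == ""


@dataclass
class RankingResult:
    """Verdict for one (drug A, drug B, combination) triplet on a disease."""

    disease_id: str
    pair: tuple[str, str]
    score_a: float
    score_b: float
    score_ab: float
    verdict: Literal[
        "combination_more_effective",
        "single_A_best",
        "single_B_best",
        "none_effective",
    ]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic generator.

    Defaults describe the reference study condition: 5,000 genes with a
    planted signature of 200 DEGs (2% up, 2% down), a 2 log2-unit shift,
    Gaussian noise of sd 0.5, and 25 case / 25 control samples.
    """

    n_genes: int = 5000
    n_case: int = 25
    n_control: int = 25
    frac_up: float = 0.02
    frac_down: float = 0.02
    effect_size: float = 2.0
    noise_sd: float = 0.5
    drug_mode: str = "reverse"  # reverse | mimic | null | partial
    drug_partial_fraction: float = 0.5
    drug_effect_size: float = 2.0
    n_treated: int = 25
    n_drug_control: int = 25
    baseline_range: tuple[float, float] = (4.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise ValueError("frac_up and frac_down must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must not exceed 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.drug_mode not in {"reverse", "mimic", "null", "partial"}:
            raise ValueError(f"unknown drug_mode {self.drug_mode!r}")
        if not (0 <= self.drug_partial_fraction <= 1):
            raise ValueError("drug_partial_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted per-gene directions for a simulated dataset."""

    disease_direction: pd.Series  # gene -> up/down/null
    drug_direction: dict[str, pd.Series] = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """End-to-end run configuration with the published default thresholds:
    BH-adjusted p < 0.01 (microarray) or < 0.05 (rnaseq), fold change >= 2,
    |z| > 1.96."""

    mode: str = "microarray"  # microarray | rnaseq
    alpha_bh: Optional[float] = None  # None -> mode default
    min_fold_change: float = 2.0
    z_threshold: float = Z_THRESHOLD
    clamp_eps: float = CLAMP_EPS
    equal_var: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"microarray", "rnaseq"}:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def effective_alpha(self) -> float:
        if self.alpha_bh is not None:
            return self.alpha_bh
        return 0.01 if self.mode == "microarray" else 0.05
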