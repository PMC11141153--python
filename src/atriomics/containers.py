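"""Shared in-memory containers for the analysis pipeline.

The canonical abundance container is :class:`OmicsMatrix`, a feature-by-sample
table (protein intensities or transcript counts) with an explicit missingness
convention: a ``NaN`` cell means "not observed", never "observed as zero".
Sample condition labels (``AF`` vs ``sham``) travel with the matrix so every
downstream statistic can locate its two groups without a side table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Condition labels used throughout: paced atrial-fibrillation animals vs
#: instrumented sinus-rhythm controls.
GROUP_AF = "AF"
GROUP_SHAM = "sham"

#: Dataset tags: tissue lysate, endolysosome fraction, mitochondrial fraction
#: (proteomics) and the transcriptomics dataset.
PROTEOMICS_TAGS = ("TL", "EL", "Mito")
RNA_TAG = "RNA"


@dataclass
class OmicsMatrix:
    """Feature-by-sample numeric matrix with missing mask and group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
        ``NaN`` marks a missing cell.
    groups
        Mapping from sample id to condition label (``"AF"`` or ``"sham"``).
        Every column of ``values`` must be covered.
    dataset_tag
        Which dataset this matrix belongs to (``TL``/``EL``/``Mito``/``RNA``).
    value_kind
        ``"intensity"`` (continuous, positive) or ``"count"`` (non-negative
        integers).
    """

    values: pd.DataFrame
    groups: Mapping[str, str]
    dataset_tag: str = "TL"
    value_kind: str = "intensity"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index.name = "feature_id"
        self.values.columns.name = None
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        uncovered = [s for s in self.values.columns if s not in self.groups]
        if uncovered:
            raise ValueError(f"samples without a group label: {uncovered}")
        bad = {s: g for s, g in self.groups.items()
               if s in self.values.columns and g not in (GROUP_AF, GROUP_SHAM)}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")

    # -- basic views ---------------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, ``True`` where the value is absent."""
        return self.values.isna()

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def group_columns(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """The AF and sham sub-matrices, in column order."""
        return (self.values[self.samples_in(GROUP_AF)],
                self.values[self.samples_in(GROUP_SHAM)])

    def replace_values(self, values: pd.DataFrame) -> "OmicsMatrix":
        """New matrix sharing group labels and tags, with different values."""
        return OmicsMatrix(values=values, groups=dict(self.groups),
                           dataset_tag=self.dataset_tag,
                           value_kind=self.value_kind)

    def subset_features(self, feature_ids: Iterable) -> "OmicsMatrix":
        return self.replace_values(self.values.loc[list(feature_ids)])

    def subset_samples(self, sample_ids: Iterable) -> "OmicsMatrix":
        keep = [s for s in self.values.columns if s in set(sample_ids)]
        return OmicsMatrix(values=self.values[keep],
                           groups={s: self.groups[s] for s in keep},
                           dataset_tag=self.dataset_tag,
                           value_kind=self.value_kind)


@dataclass
class PathwayAnnotation:
    """Pathway id -> member gene id set, with optional display names."""

    members: dict[str, frozenset]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [p for p, m in self.members.items() if not m]
        if empty:
            raise ValueError(f"pathways with empty member sets: {empty[:5]}")
        self.members = {p: frozenset(m) for p, m in self.members.items()}

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def display_name(self, pathway_id: str) -> str:
        return self.names.get(pathway_id, pathway_id)

    def universe(self) -> frozenset:
        out: set = set()
        for m in self.members.values():
            out |= m
        return frozenset(out)


@dataclass
class EMImage:
    """Calibrated grayscale electron micrograph.

    ``pixels`` is a 2-D array (uint8/uint16 or float); ``nm_per_px`` converts
    pixel lengths to nanometres.
    """

    pixels: np.ndarray
    nm_per_px: float
    image_id: str = "image"
    group: str | None = None
    animal_id: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("EMImage requires a 2-D grayscale array")
        if not self.nm_per_px > 0:
            raise ValueError("nm_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle, 0-based, half-open: rows y0:y0+h, cols x0:x0+w."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI width and height must be positive")

    @property
    def area_px(self) -> int:
        return self.width * self.height

    def area_nm2(self, nm_per_px: float) -> float:
        return self.area_px * nm_per_px ** 2


@dataclass
class StandardCurve:
    """Ordinary-least-squares line fitted to known amounts vs responses."""

    slope: float
    intercept: float
    r2: float
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    def inverse(self, response: float) -> float:
        """Back-calculate an amount from a measured response."""
        if self.slope == 0:
            raise ZeroDivisionError("standard curve has zero slope")
        return (response - self.intercept) / self.slope


@dataclass
class TTestResult:
    """Two-sample t-test outcome with its configuration."""

    t: float
    df: float
    p: float
    tails: str = "two"          # "one" or "two"
    variance: str = "pooled"    # "pooled" or "welch"
    flag: str | None = None     # degenerate-case annotation

    def __post_init__(self) -> None:
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")


@dataclass
class AssaySummary:
    """Replicate values with mean and sample SD (n-1 denominator)."""

    group: str
    values: np.ndarray
    unit: str = "nmol/min/mg"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("replicate values must be a non-empty 1-D array")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        """Sample SD; NaN (flagged degenerate) when n < 2."""
        if self.n < 2:
            return float("nan")
        return float(np.std(self.values, ddof=1))

    def rounded(self, decimals: int = 2) -> tuple[float, float]:
        """Mean and SD rounded for reporting; full precision kept internally."""
        return (round(self.mean, decimals), round(self.sd, decimals))
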