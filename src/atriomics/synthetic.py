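"""Synthetic study generator with known ground truth.

Every pipeline input — protein intensity matrices over the three fractions
(tissue lysate TL, endolysosome EL, mitochondria Mito), transcript count
matrices, pathway membership, electron micrographs with planted glycogen
granules, and fluorometric assay plates — can be generated here with the
"answers" recorded, so each downstream stage is testable without the
deposited study data.

Statistical model (stand-ins; the study describes its data only through
replicate counts):

* log2 protein intensities are Normal with feature baselines ~ N(23, 2) and
  feature SDs ~ Uniform(0.2, 0.8), spanning the dynamic range typical of
  label-free data; values are stored on the raw 2**x scale so the log2
  transform downstream is exercised.
* regulated features are shifted by a signed ``effect_log2`` in the AF group;
  the regulated set and its signs derive from the config seed alone, so the
  TL/EL/Mito/RNA matrices of one study share them.
* missingness is either uniform at random or left-censoring-like: missing
  probability logistic in minus log2 intensity, calibrated so the overall
  rate matches ``missing_rate``.
* transcript counts are negative binomial with per-sample library-size
  factors; regulated genes are shifted multiplicatively by ``2**effect_log2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import rng_for, stage_seed
from .containers import (GROUP_AF, GROUP_SHAM, PROTEOMICS_TAGS, RNA_TAG,
                         EMImage, OmicsMatrix, PathwayAnnotation, ROI)

__all__ = [
    "SimStudyConfig", "GroundTruth", "GranuleImageSpec", "AssayPlate",
    "simulate_proteomics", "simulate_transcript_counts", "simulate_study",
    "simulate_pathway_annotation", "simulate_em_image", "simulate_rois",
    "simulate_assay_plate",
]


@dataclass
class SimStudyConfig:
    """Parameters of one simulated AF-vs-sham study.

    ``n_per_group`` defaults to 3, the study design (3 AF vs 3 sham
    biological replicates). ``datasets`` lists the matrices the study
    comprises. ``dispersion`` is the negative-binomial size parameter for
    transcript counts (larger = closer to Poisson).
    """

    seed: int = 0
    n_features: int = 1000
    n_per_group: int = 3
    datasets: tuple[str, ...] = PROTEOMICS_TAGS + (RNA_TAG,)
    frac_regulated: float = 0.1
    effect_log2: float = 2.0
    missing_rate: float = 0.0
    missing_mode: str = "random"          # "random" | "intensity-dependent"
    dispersion: float = 10.0
    baseline_mean: float = 23.0
    baseline_sd: float = 2.0
    sigma_range: tuple[float, float] = (0.2, 0.8)

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if not 0.0 <= self.frac_regulated <= 1.0:
            raise ValueError("frac_regulated must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.missing_mode not in ("random", "intensity-dependent"):
            raise ValueError(f"unknown missing_mode {self.missing_mode!r}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.sigma_range
        if not (0 < lo <= hi):
            raise ValueError("sigma_range must be positive and ordered")

    def feature_ids(self) -> list[str]:
        width = max(4, len(str(self.n_features - 1)))
        return [f"F{i:0{width}d}" for i in range(self.n_features)]

    def sample_ids(self, dataset_tag: str) -> list[str]:
        return ([f"{dataset_tag}_AF{i+1}" for i in range(self.n_per_group)]
                + [f"{dataset_tag}_sham{i+1}" for i in range(self.n_per_group)])

    def groups(self, dataset_tag: str) -> dict[str, str]:
        out = {}
        for s in self.sample_ids(dataset_tag):
            out[s] = GROUP_AF if f"{dataset_tag}_AF" in s else GROUP_SHAM
        return out


@dataclass
class GroundTruth:
    """The planted truth behind one simulated artifact."""

    regulated_features: dict[str, float] = field(default_factory=dict)
    regulated_pathways: dict[str, float] = field(default_factory=dict)
    granule_coordinates: list[tuple[float, float, float]] = field(default_factory=list)
    organelle_boxes: list[tuple[int, int, int, int]] = field(default_factory=list)
    true_activities: dict[str, float] = field(default_factory=dict)


def _regulated_assignment(config: SimStudyConfig) -> dict[str, float]:
    """Regulated feature ids with signed log2 effects.

    Derived from the config seed alone (not the per-dataset stream), so all
    datasets of one study agree on which features are regulated and how.
    """
    n_reg = int(round(config.frac_regulated * config.n_features))
    if n_reg == 0 or config.effect_log2 == 0:
        return {}
    rng = rng_for(config.seed, "regulated-assignment")
    ids = np.array(config.feature_ids())
    chosen = rng.choice(config.n_features, size=n_reg, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_reg)
    return {ids[i]: float(s * config.effect_log2)
            for i, s in zip(sorted(chosen), signs)}


def _calibrated_censoring_mask(log2_values: np.ndarray, rate: float,
                               rng: np.random.Generator,
                               steepness: float = 1.0) -> np.ndarray:
    """Left-censoring-like missingness: P(missing) logistic in -log2 intensity.

    The logistic midpoint is solved by bisection so the expected overall
    missing fraction equals ``rate``.
    """
    score = -log2_values.ravel()

    def mean_p(mid: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-steepness * (score - mid)))))

    lo, hi = score.min() - 60.0, score.max() + 60.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) > rate:
            lo = mid
        else:
            hi = mid
    p = 1.0 / (1.0 + np.exp(-steepness * (score - 0.5 * (lo + hi))))
    return (rng.random(score.shape) < p).reshape(log2_values.shape)


def simulate_proteomics(config: SimStudyConfig,
                        dataset_tag: str = "TL") -> tuple[OmicsMatrix, GroundTruth]:
    """Simulate one fraction's label-free intensity matrix.

    Returns values on the raw (2**log2) scale with ``NaN`` for missing cells,
    plus the ground truth of planted regulated features.
    """
    rng = rng_for(config.seed, f"proteomics-{dataset_tag}")
    n, m = config.n_features, 2 * config.n_per_group
    ids = config.feature_ids()
    regulated = _regulated_assignment(config)

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    sigma = rng.uniform(*config.sigma_range, size=n)
    log2_vals = rng.normal(mu[:, None], sigma[:, None], size=(n, m))

    effect = np.array([regulated.get(f, 0.0) for f in ids])
    log2_vals[:, :config.n_per_group] += effect[:, None]   # AF columns first

    if config.missing_rate > 0:
        if config.missing_mode == "random":
            mask = rng.random((n, m)) < config.missing_rate
        else:
            mask = _calibrated_censoring_mask(log2_vals, config.missing_rate, rng)
    else:
        mask = np.zeros((n, m), dtype=bool)

    raw = np.exp2(log2_vals)
    raw[mask] = np.nan
    values = pd.DataFrame(raw, index=ids, columns=config.sample_ids(dataset_tag))
    matrix = OmicsMatrix(values=values, groups=config.groups(dataset_tag),
                         dataset_tag=dataset_tag, value_kind="intensity")
    return matrix, GroundTruth(regulated_features=regulated)


def simulate_transcript_counts(
        config: SimStudyConfig,
        library_factors: Sequence[float] | None = None,
) -> tuple[OmicsMatrix, GroundTruth]:
    """Simulate an overdispersed transcript count matrix (tag ``RNA``).

    Counts are negative binomial with size ``config.dispersion``; variance is
    mu + mu^2/dispersion, so large dispersion approaches the Poisson limit.
    ``library_factors`` overrides the per-sample depth factors (default:
    log-normal with 15% CV).
    """
    rng = rng_for(config.seed, "transcripts")
    n, m = config.n_features, 2 * config.n_per_group
    ids = config.feature_ids()
    regulated = _regulated_assignment(config)

    if library_factors is None:
        lib = rng.lognormal(mean=0.0, sigma=0.15, size=m)
    else:
        lib = np.asarray(library_factors, dtype=float)
        if lib.shape != (m,):
            raise ValueError(f"library_factors must have length {m}")
        if np.any(lib <= 0):
            raise ValueError("library_factors must be positive")

    base_mean = np.exp2(rng.normal(7.0, 2.0, size=n))
    effect = np.array([regulated.get(f, 0.0) for f in ids])
    mu = np.tile(base_mean[:, None], (1, m)) * lib[None, :]
    mu[:, :config.n_per_group] *= np.exp2(effect)[:, None]

    size = config.dispersion
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p).astype(float)

    values = pd.DataFrame(counts, index=ids, columns=config.sample_ids(RNA_TAG))
    matrix = OmicsMatrix(values=values, groups=config.groups(RNA_TAG),
                         dataset_tag=RNA_TAG, value_kind="count")
    return matrix, GroundTruth(regulated_features=regulated)


def simulate_study(config: SimStudyConfig) -> tuple[dict[str, OmicsMatrix], GroundTruth]:
    """All matrices of one study, sharing the same regulated feature set."""
    matrices: dict[str, OmicsMatrix] = {}
    truth = GroundTruth(regulated_features=_regulated_assignment(config))
    for tag in config.datasets:
        if tag == RNA_TAG:
            matrices[tag], _ = simulate_transcript_counts(config)
        else:
            matrices[tag], _ = simulate_proteomics(config, dataset_tag=tag)
    return matrices, truth


def simulate_pathway_annotation(
        config: SimStudyConfig,
        n_pathways: int,
        size_range: tuple[int, int],
        n_planted: int = 1,
) -> tuple[PathwayAnnotation, GroundTruth]:
    """Random pathway membership over the study's feature universe.

    ``n_planted`` pathways are built entirely from regulated features sharing
    one effect sign, so a coordinated pathway-level shift exists by
    construction; the rest sample members uniformly without replacement.
    """
    lo, hi = size_range
    if not (1 <= lo <= hi):
        raise ValueError("size_range must satisfy 1 <= min <= max")
    universe = np.array(config.feature_ids())
    if hi > universe.size:
        raise ValueError(
            f"size_range max {hi} exceeds feature universe {universe.size}")
    if n_planted > n_pathways:
        raise ValueError("n_planted cannot exceed n_pathways")

    rng = rng_for(config.seed, "pathways")
    regulated = _regulated_assignment(config)
    members: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    truth = GroundTruth(regulated_features=regulated)

    for i in range(n_planted):
        pid = f"PW{i:04d}"
        sign = 1.0 if rng.random() < 0.5 else -1.0
        pool = [f for f, e in regulated.items() if np.sign(e) == sign]
        if len(pool) < lo:                      # fall back to the richer sign
            sign = -sign
            pool = [f for f, e in regulated.items() if np.sign(e) == sign]
        if len(pool) < lo:
            raise ValueError(
                "not enough regulated features of one sign to plant a pathway; "
                "raise frac_regulated or lower size_range")
        k = int(rng.integers(lo, min(hi, len(pool)) + 1))
        chosen = rng.choice(len(pool), size=k, replace=False)
        members[pid] = frozenset(np.array(pool)[chosen])
        names[pid] = f"planted pathway {i} ({'up' if sign > 0 else 'down'})"
        truth.regulated_pathways[pid] = sign * config.effect_log2

    for i in range(n_planted, n_pathways):
        pid = f"PW{i:04d}"
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(universe.size, size=k, replace=False)
        members[pid] = frozenset(universe[chosen])
        names[pid] = f"random pathway {i}"

    if not members:
        return PathwayAnnotation(members={}, names={}), truth
    return PathwayAnnotation(members=members, names=names), truth


# ---------------------------------------------------------------------------
# Electron micrographs
# ---------------------------------------------------------------------------

@dataclass
class GranuleImageSpec:
    """Geometry and intensity model of one synthetic micrograph.

    Intensities are in 16-bit grayscale units. Glycogen granules are dark
    anti-aliased disks on a textured cytosol; organelle blobs are larger
    bright ellipses (regions a manual analyst would exclude from boxes).
    """

    width: int = 512
    height: int = 512
    nm_per_px: float = 2.0
    n_granules: int = 50
    granule_radius_px: tuple[float, float] = (4.0, 0.5)   # mean, sd
    granule_darkness: float = 18000.0
    background_level: float = 42000.0
    background_texture_sd: float = 1500.0
    n_organelle_blobs: int = 3
    noise_sd: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("image too small")
        if self.n_granules < 0 or self.n_organelle_blobs < 0:
            raise ValueError("counts must be non-negative")
        if self.granule_radius_px[0] <= 0:
            raise ValueError("granule radius must be positive")
        if self.nm_per_px <= 0:
            raise ValueError("nm_per_px must be positive")


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sd: float, scale: float = 8.0) -> np.ndarray:
    from scipy.ndimage import gaussian_filter
    field_ = gaussian_filter(rng.normal(0.0, 1.0, size=shape), scale)
    s = field_.std()
    return field_ / s * sd if s > 0 else field_


def simulate_em_image(spec: GranuleImageSpec) -> tuple[EMImage, GroundTruth]:
    """Render one synthetic micrograph and the exact granule coordinates.

    Granules are placed fully inside the image, mutually non-overlapping and
    outside organelle blobs, by rejection sampling; an image too crowded to
    satisfy that raises ``ValueError``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.full((h, w), spec.background_level, dtype=float)
    if spec.background_texture_sd > 0:
        img += _smooth_noise(rng, (h, w), spec.background_texture_sd)

    yy, xx = np.mgrid[0:h, 0:w]
    blob_boxes: list[tuple[int, int, int, int]] = []
    for _ in range(spec.n_organelle_blobs):
        a = min(rng.uniform(20, 45), (w - 2) / 2.0)
        b = min(rng.uniform(15, 35), (h - 2) / 2.0)
        cx = rng.uniform(a, w - a)
        cy = rng.uniform(b, h - b)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        img[inside] += rng.uniform(6000, 10000)
        r = max(a, b)
        x0, y0 = int(max(0, cx - r)), int(max(0, cy - r))
        x1, y1 = int(min(w, cx + r + 1)), int(min(h, cy + r + 1))
        blob_boxes.append((x0, y0, x1 - x0, y1 - y0))

    def in_blob(x: float, y: float, margin: float) -> bool:
        for (bx, by, bw, bh) in blob_boxes:
            if bx - margin <= x <= bx + bw + margin and \
               by - margin <= y <= by + bh + margin:
                return True
        return False

    mean_r, sd_r = spec.granule_radius_px
    coords: list[tuple[float, float, float]] = []
    attempts = 0
    max_attempts = 400 * max(1, spec.n_granules)
    while len(coords) < spec.n_granules:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {spec.n_granules} non-overlapping granules "
                f"in a {w}x{h} image (placed {len(coords)})")
        r = max(1.5, rng.normal(mean_r, sd_r))
        if w - 2 * r - 2 <= 0 or h - 2 * r - 2 <= 0:
            raise ValueError(
                f"image too small for a radius-{r:.1f} granule; could not "
                f"place {spec.n_granules} non-overlapping granules")
        x = rng.uniform(r + 1, w - r - 1)
        y = rng.uniform(r + 1, h - r - 1)
        if in_blob(x, y, margin=r + 2):
            continue
        if any((x - x2) ** 2 + (y - y2) ** 2 < (r + r2 + 2.0) ** 2
               for x2, y2, r2 in coords):
            continue
        coords.append((x, y, r))

    for (x, y, r) in coords:
        x0, x1 = max(0, int(x - r - 2)), min(w, int(x + r + 3))
        y0, y1 = max(0, int(y - r - 2)), min(h, int(y + r + 3))
        sub_y, sub_x = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(sub_x - x, sub_y - y)
        coverage = np.clip(r + 0.5 - dist, 0.0, 1.0)   # anti-aliased disk
        img[y0:y1, x0:x1] -= spec.granule_darkness * coverage

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=(h, w))

    pixels = np.clip(img, 0, 65535).astype(np.uint16)
    image = EMImage(pixels=pixels, nm_per_px=spec.nm_per_px)
    truth = GroundTruth(granule_coordinates=coords, organelle_boxes=blob_boxes)
    return image, truth


def simulate_rois(image: EMImage, truth: GroundTruth, n_rois: int = 6,
                  roi_size: int = 128, seed: int = 0,
                  max_attempts: int = 2000) -> list[ROI]:
    """Rectangular boxes avoiding organelle blobs, like manual box selection."""
    rng = np.random.default_rng(seed)
    h, w = image.shape
    if roi_size > min(h, w):
        raise ValueError("roi_size exceeds image dimensions")
    rois: list[ROI] = []
    for _ in range(max_attempts):
        if len(rois) >= n_rois:
            break
        x0 = int(rng.integers(0, w - roi_size + 1))
        y0 = int(rng.integers(0, h - roi_size + 1))
        overlaps_blob = any(
            x0 < bx + bw and bx < x0 + roi_size and
            y0 < by + bh and by < y0 + roi_size
            for (bx, by, bw, bh) in truth.organelle_boxes)
        if not overlaps_blob:
            rois.append(ROI(x0=x0, y0=y0, width=roi_size, height=roi_size))
    if len(rois) < n_rois:
        raise ValueError("could not place the requested ROIs clear of blobs")
    return rois


# ---------------------------------------------------------------------------
# Fluorometric assay plates
# ---------------------------------------------------------------------------

@dataclass
class AssayPlate:
    """Simulated plate: standard wells plus unknown (sample) wells.

    Both tables carry the columns well, role, known_amount (nmol 4-MU;
    NaN for unknowns), response (fluorescence), time_min, protein_mg.
    """

    standards: pd.DataFrame
    unknowns: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.standards, self.unknowns], ignore_index=True)


def simulate_assay_plate(true_activities: Mapping[str, float],
                         curve_slope: float,
                         curve_intercept: float = 0.0,
                         noise_sd: float = 0.0,
                         seed: int = 0,
                         incubation_time_min: float = 60.0,
                         protein_mass_mg: float = 1.0,
                         standard_amounts: Sequence[float] | None = None,
                         ) -> AssayPlate:
    """Emulate a 4-MU fluorometric enzyme assay plate.

    Standards respond linearly to known free 4-MU amounts; unknown wells
    respond according to the 4-MU their sample's true activity (nmol/min/mg)
    would release over ``incubation_time_min`` with ``protein_mass_mg`` of
    protein. At ``noise_sd = 0`` back-calculation recovers the true
    activities exactly.
    """
    if curve_slope == 0:
        raise ValueError("curve_slope must be non-zero")
    if incubation_time_min <= 0 or protein_mass_mg <= 0:
        raise ValueError("incubation time and protein mass must be positive")
    rng = np.random.default_rng(seed)
    if standard_amounts is None:
        standard_amounts = [0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0]

    std_rows = []
    for i, amount in enumerate(standard_amounts):
        response = curve_slope * amount + curve_intercept
        if noise_sd > 0:
            response += rng.normal(0.0, noise_sd)
        std_rows.append({"well": f"STD{i+1}", "role": "standard",
                         "known_amount": float(amount),
                         "response": float(response),
                         "time_min": float(incubation_time_min),
                         "protein_mg": float(protein_mass_mg)})

    unk_rows = []
    for sample_id, activity in true_activities.items():
        released = activity * incubation_time_min * protein_mass_mg
        response = curve_slope * released + curve_intercept
        if noise_sd > 0:
            response += rng.normal(0.0, noise_sd)
        unk_rows.append({"well": sample_id, "role": "unknown",
                         "known_amount": np.nan,
                         "response": float(response),
                         "time_min": float(incubation_time_min),
                         "protein_mg": float(protein_mass_mg)})

    cols = ["well", "role", "known_amount", "response", "time_min", "protein_mg"]
    return AssayPlate(standards=pd.DataFrame(std_rows, columns=cols),
                      unknowns=pd.DataFrame(unk_rows, columns=cols))
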