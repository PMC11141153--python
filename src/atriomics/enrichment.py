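"""Integrated proteome-transcriptome pathway enrichment.

The integration follows the rank-based annotation-enrichment idea of
2D enrichment generalized to N datasets: per-gene two-sample t statistics
are computed within each dataset (three proteomics fractions plus one
transcriptomics dataset), genes are rank-transformed within each dataset,
and for every pathway the vector of standardized mean member ranks is tested
jointly with a Hotelling-type chi-square statistic whose cross-dataset
correlation is estimated from the rank columns themselves.

Missing-data policy during ranking:

* a gene quantified in at least one proteomics dataset but missing in
  another proteomics dataset is *ranked last* there (the whole bottom block
  shares one mid-rank, keeping rank sums exact);
* a gene observed only in the transcriptomics dataset is *excluded* from all
  proteomics rankings;
* the transcriptomics ranking covers exactly the genes with transcript
  statistics.

Pathway p-values are converted to q-values (Benjamini-Hochberg step-up by
default) and thresholded at 1% FDR, with confidence tiers mapped from q.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (GROUP_AF, GROUP_SHAM, PROTEOMICS_TAGS, RNA_TAG,
                         OmicsMatrix, PathwayAnnotation)

logger = logging.getLogger(__name__)

__all__ = [
    "RankProfile", "EnrichmentConfig", "vst_transform", "harmonize_ids",
    "detect_outlier_samples", "gene_t_stats", "rank_datasets",
    "category_scores", "manova_enrichment_test", "qvalues", "classify_tiers",
    "enrich_pathways",
]

RANKED = "ranked"
RANKED_LAST = "ranked_last"
EXCLUDED = "excluded"


@dataclass
class EnrichmentConfig:
    """Thresholds for the joint pathway test."""

    min_per_side: int = 2
    fdr_threshold: float = 0.01
    tier_confident_q: float = 0.01
    tier_high_q: float = 0.001
    qvalue_method: str = "bh"            # "bh" | "storey"
    ridge_epsilon: float = 1e-6


@dataclass
class RankProfile:
    """Per-dataset gene ranks with status annotations.

    ``ranks[tag]`` maps gene id -> mid-rank in 1..n_d over the ranked
    universe of dataset ``tag`` (ranked + ranked_last genes); ``status[tag]``
    maps gene id -> one of ``ranked``/``ranked_last``/``excluded``.
    """

    ranks: dict[str, dict[str, float]] = field(default_factory=dict)
    status: dict[str, dict[str, str]] = field(default_factory=dict)
    _corr_cache: dict = field(default_factory=dict, repr=False)

    @property
    def datasets(self) -> list[str]:
        return list(self.ranks)

    def n_ranked(self, tag: str) -> int:
        return len(self.ranks[tag])

    def rank_frame(self) -> pd.DataFrame:
        """Genes x datasets rank table (NaN where a gene carries no rank)."""
        return pd.DataFrame(self.ranks)


# ---------------------------------------------------------------------------
# Normalization and harmonization
# ---------------------------------------------------------------------------

def vst_transform(matrix: OmicsMatrix, c: float | None = None,
                  calibrate: bool = True) -> OmicsMatrix:
    """Variance-stabilizing generalized-log transform.

    Samples are first affinely calibrated (scaled so their medians agree
    with the across-sample mean median), then
    ``glog(x) = log2((x + sqrt(x^2 + c^2)) / 2)`` is applied. With ``c = 0``
    this reduces to plain log2 on positive data; ``glog(0) = log2(c/2)``.
    ``c`` defaults to the 5th percentile of the calibrated positive values —
    large enough to damp the variance of low-intensity rows, small enough to
    leave the bulk on the log2 scale.
    """
    values = matrix.values.copy()
    if (values < 0).any().any():
        raise ValueError("vst_transform requires non-negative values")
    if values.isna().all(axis=0).any():
        bad = values.columns[values.isna().all(axis=0)].tolist()
        raise ValueError(f"all-missing sample(s): {bad}")

    if calibrate:
        medians = values.median(axis=0, skipna=True)
        target = float(medians.mean())
        scale = medians / target
        scale = scale.replace(0.0, 1.0)
        values = values.div(scale, axis=1)

    if c is None:
        pos = values.to_numpy(float)
        pos = pos[np.isfinite(pos) & (pos > 0)]
        c = float(np.percentile(pos, 5)) if pos.size else 0.0
    if c < 0:
        raise ValueError("glog constant c must be non-negative")

    arr = values.to_numpy(float)
    with np.errstate(divide="ignore"):
        out = np.log2((arr + np.sqrt(arr ** 2 + c ** 2)) / 2.0)
    result = matrix.replace_values(
        pd.DataFrame(out, index=values.index, columns=values.columns))
    result.value_kind = "intensity"
    return result


def _collapse(block: pd.DataFrame, rule: str) -> pd.Series:
    if rule == "median":
        return block.median(axis=0, skipna=True)
    if rule == "max_abs":
        arr = block.to_numpy(float)
        filled = np.where(np.isnan(arr), -np.inf, np.abs(arr))
        idx = np.argmax(filled, axis=0)
        out = arr[idx, np.arange(arr.shape[1])]
        out[np.all(np.isnan(arr), axis=0)] = np.nan
        return pd.Series(out, index=block.columns)
    raise ValueError(f"unknown collapse rule {rule!r}")


def harmonize_ids(matrices: list[OmicsMatrix], idmap: dict[str, list[str]],
                  collapse: str = "median") -> list[OmicsMatrix]:
    """Rename features to human homolog ids and collapse collisions.

    ``idmap`` maps a source id to one or more target ids (one-to-many is
    expanded; many-to-one collisions are collapsed elementwise by ``median``
    or ``max_abs``). Unmapped features are dropped with the count logged.
    """
    out: list[OmicsMatrix] = []
    for matrix in matrices:
        rows: list[pd.Series] = []
        targets: list[str] = []
        n_unmapped = 0
        for fid in matrix.feature_ids:
            mapped = idmap.get(fid)
            if not mapped:
                n_unmapped += 1
                continue
            for target in mapped:
                rows.append(matrix.values.loc[fid])
                targets.append(target)
        if not rows:
            raise ValueError(
                f"no feature of dataset {matrix.dataset_tag!r} is covered by "
                "the id map")
        if n_unmapped:
            logger.info("harmonize_ids[%s]: dropped %d unmapped features",
                        matrix.dataset_tag, n_unmapped)
        stacked = pd.DataFrame(rows)
        stacked.index = pd.Index(targets, name="human_id")
        collapsed = stacked.groupby(level=0, sort=False).apply(
            lambda block: _collapse(block, collapse))
        out.append(matrix.replace_values(collapsed))
    return out


def detect_outlier_samples(matrices: list[OmicsMatrix],
                           threshold_mad: float = 5.0) -> list[str]:
    """Flag samples far from their group centroid in PC1/PC2.

    All matrices are row-standardized, stacked over shared complete
    features, and projected; a sample whose Euclidean distance to its
    group's component-wise median center exceeds ``threshold_mad`` times
    the MAD of within-group distances is flagged. Raises if removal would
    leave any group with fewer than two samples.
    """
    blocks = []
    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    for matrix in matrices:
        complete = matrix.values.dropna(axis=0)
        if complete.empty:
            continue
        arr = complete.to_numpy(float)
        sd = arr.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (arr - arr.mean(axis=1, keepdims=True)) / sd
        blocks.append(z)
        if not sample_ids:
            sample_ids = list(complete.columns)
        groups.update({s: matrix.groups[s] for s in complete.columns})
    if not blocks:
        raise ValueError("no complete features available")
    widths = {b.shape[1] for b in blocks}
    if len(widths) != 1:
        raise ValueError("matrices must share a common sample layout "
                         "(equal sample counts per dataset)")

    X = np.vstack(blocks).T                      # samples x features
    per_group = {}
    for i, s in enumerate(sample_ids):
        per_group.setdefault(groups[s], []).append(i)
    if any(len(ix) < 3 for ix in per_group.values()):
        raise ValueError("need at least 3 samples per group")

    Xc = X - X.mean(axis=0, keepdims=True)
    u, s_, _ = np.linalg.svd(Xc, full_matrices=False)
    pcs = (u * s_)[:, :2]

    dist = np.empty(len(sample_ids))
    for ix in per_group.values():
        # component-wise median center: an extreme sample cannot drag the
        # center toward itself (a mean would halve its apparent distance)
        center = np.median(pcs[ix], axis=0)
        dist[ix] = np.linalg.norm(pcs[ix] - center, axis=1)
    mad = float(np.median(np.abs(dist - np.median(dist))))
    if mad == 0.0:
        return []
    flagged = [sample_ids[i] for i in range(len(sample_ids))
               if dist[i] > threshold_mad * mad]

    for g, ix in per_group.items():
        remaining = sum(1 for i in ix if sample_ids[i] not in flagged)
        if remaining < 2:
            raise ValueError(
                f"outlier removal would leave group {g!r} with "
                f"{remaining} sample(s); removal aborted")
    return flagged


# ---------------------------------------------------------------------------
# Per-gene statistics and ranking
# ---------------------------------------------------------------------------

def gene_t_stats(matrix: OmicsMatrix) -> pd.Series:
    """Pooled two-sample t per gene (AF minus sham).

    Genes without two observed values in each group get NaN (missing in this
    dataset). A zero pooled SE with a non-zero mean difference yields a
    signed infinity sentinel, which ranks to the extreme.
    """
    from .proteome import _pooled_t_rows
    af, sham = matrix.group_columns()
    t_raw, _, _, valid = _pooled_t_rows(af.to_numpy(float),
                                        sham.to_numpy(float), s0=0.0)
    return pd.Series(np.where(valid, t_raw, np.nan),
                     index=matrix.feature_ids, name=matrix.dataset_tag)


def rank_datasets(tstats: dict[str, pd.Series]) -> RankProfile:
    """Rank genes within each dataset with the proteomics missing-value policy.

    Ascending mid-ranks of the t statistics (rank n_d = most AF-up). In a
    proteomics dataset, a gene missing there but quantified in at least one
    proteomics dataset enters a shared bottom block ("ranked last"); a gene
    carried only by the transcriptomics dataset is excluded from proteomics
    rankings entirely.
    """
    prot_tags = [t for t in tstats if t != RNA_TAG]
    observed_in_prot: set[str] = set()
    for tag in prot_tags:
        s = tstats[tag]
        observed_in_prot |= set(s.index[s.notna()])

    profile = RankProfile()
    for tag, s in tstats.items():
        have = s.dropna()
        if tag in prot_tags:
            last_ids = sorted(observed_in_prot - set(have.index))
        else:
            last_ids = []
        n_ranked = have.size
        n_total = n_ranked + len(last_ids)
        ranks: dict[str, float] = {}
        status: dict[str, str] = {}
        if n_ranked:
            r = stats.rankdata(have.to_numpy(float), method="average")
            for gid, rk in zip(have.index, r):
                ranks[gid] = float(rk)
                status[gid] = RANKED
        if last_ids:
            # the whole bottom block shares its mid-rank, keeping sums exact
            block_rank = (n_ranked + 1 + n_total) / 2.0
            for gid in last_ids:
                ranks[gid] = block_rank
                status[gid] = RANKED_LAST
        for gid in s.index:
            if gid not in status:
                status[gid] = EXCLUDED
        profile.ranks[tag] = ranks
        profile.status[tag] = status
    if all(len(r) < 2 for r in profile.ranks.values()):
        raise ValueError("no dataset has at least 2 ranked genes")
    return profile


def category_scores(profile: RankProfile, members) -> dict[str, float]:
    """Normalized mean-rank score per dataset, in (-1, 1).

    score_d = (2 / n_d) * (mean member rank - (n_d + 1)/2); positive means
    the category's genes sit toward the AF-up end. Datasets with no ranked
    member are omitted.
    """
    members = set(members)
    out: dict[str, float] = {}
    for tag, ranks in profile.ranks.items():
        n_d = len(ranks)
        got = [ranks[g] for g in members if g in ranks]
        if not got or n_d == 0:
            continue
        out[tag] = float((2.0 / n_d) * (np.mean(got) - (n_d + 1) / 2.0))
    return out


def _rank_correlation(profile: RankProfile, tags: list[str],
                      ridge_epsilon: float) -> np.ndarray:
    """Spearman correlation of the rank columns over jointly ranked genes.

    Depends only on the profile and the dataset subset, not on any category,
    so it is memoized on the profile.
    """
    key = (tuple(tags), ridge_epsilon)
    if key in profile._corr_cache:
        return profile._corr_cache[key]
    frame = profile.rank_frame()[tags]
    d = len(tags)
    C = np.eye(d)
    for i in range(d):
        for j in range(i + 1, d):
            pair = frame.iloc[:, [i, j]].dropna()
            if len(pair) >= 3:
                rho = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic
                if np.isfinite(rho):
                    C[i, j] = C[j, i] = rho
    # guard against singular estimates
    if np.linalg.matrix_rank(C) < d or np.linalg.cond(C) > 1e8:
        warnings.warn("singular rank-correlation matrix; ridge-regularized",
                      stacklevel=2)
        C = C + ridge_epsilon * np.eye(d)
    profile._corr_cache[key] = C
    return C


def manova_enrichment_test(profile: RankProfile, members,
                           min_per_side: int = 2,
                           ridge_epsilon: float = 1e-6,
                           ) -> tuple[float, float, dict[str, float]]:
    """Joint Hotelling-type chi-square test of a category's mean ranks.

    Per dataset d with n_d ranked genes and k_d ranked members,
    ``z_d = (mean member rank - (n_d+1)/2) / sqrt((n_d-k_d)(n_d+1)/(12 k_d))``
    (the exact mean-rank variance under sampling without replacement);
    T2 = z' C^-1 z with C the Spearman correlation of the rank columns; the
    p-value is chi-square with df = number of datasets entering.

    A pathway needs at least ``min_per_side`` ranked members in every
    dataset entering the test; otherwise ``(nan, nan, {})`` is returned and
    the caller logs the skip.
    """
    members = set(members)
    tags, zs, ks = [], [], {}
    for tag, ranks in profile.ranks.items():
        n_d = len(ranks)
        got = [ranks[g] for g in members if g in ranks]
        k_d = len(got)
        if n_d < 2:
            continue
        if k_d < min_per_side or (n_d - k_d) < min_per_side:
            return (float("nan"), float("nan"), {})
        var = (n_d - k_d) * (n_d + 1) / (12.0 * k_d)
        if var <= 0:
            return (float("nan"), float("nan"), {})
        zs.append((np.mean(got) - (n_d + 1) / 2.0) / np.sqrt(var))
        tags.append(tag)
        ks[tag] = k_d
    if not tags:
        return (float("nan"), float("nan"), {})

    z = np.array(zs)
    C = _rank_correlation(profile, tags, ridge_epsilon)
    try:
        t2 = float(z @ np.linalg.solve(C, z))
    except np.linalg.LinAlgError:
        t2 = float(z @ np.linalg.solve(C + ridge_epsilon * np.eye(len(z)), z))
    p = float(stats.chi2.sf(t2, df=len(tags)))
    return t2, p, ks


def qvalues(pvals, method: str = "bh") -> np.ndarray:
    """Convert p-values to q-values.

    ``"bh"`` is the Benjamini-Hochberg step-up (monotone, q >= p);
    ``"storey"`` additionally scales by a pi0 estimate from the upper half
    of the p distribution. NaN entries pass through as NaN.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) & np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if not ok.any():
        return out
    from statsmodels.stats.multitest import multipletests
    q = multipletests(p[ok], method="fdr_bh")[1]
    if method == "storey":
        pi0 = min(1.0, 2.0 * float(np.mean(p[ok] > 0.5)))
        pi0 = max(pi0, 1e-8)
        q = np.minimum(q * pi0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown q-value method {method!r}")
    out[ok] = q
    return out


def classify_tiers(q: np.ndarray, fdr_threshold: float = 0.01,
                   tier_high_q: float = 0.001) -> tuple[np.ndarray, np.ndarray]:
    """Significance at the FDR threshold plus gray/black/red confidence tiers.

    non_confident: q >= fdr_threshold; confident: tier_high_q <= q <
    fdr_threshold; highly_confident: q < tier_high_q.
    """
    q = np.asarray(q, dtype=float)
    significant = q < fdr_threshold
    tier = np.where(q < tier_high_q, "highly_confident",
                    np.where(q < fdr_threshold, "confident", "non_confident"))
    tier = np.where(np.isnan(q), "non_confident", tier)
    return significant & ~np.isnan(q), tier


def enrich_pathways(matrices: dict[str, OmicsMatrix],
                    annotation: PathwayAnnotation,
                    config: EnrichmentConfig | None = None) -> pd.DataFrame:
    """Full enrichment pass: t stats -> ranks -> joint test -> q -> tiers.

    Returns one row per pathway (skipped pathways carry NaN statistics and a
    ``skip_reason``), sorted by q.
    """
    config = config or EnrichmentConfig()
    tstats = {tag: gene_t_stats(m) for tag, m in matrices.items()}
    profile = rank_datasets(tstats)

    rows = []
    for pid in annotation:
        members = annotation.members[pid]
        scores = category_scores(profile, members)
        t2, p, ks = manova_enrichment_test(
            profile, members, min_per_side=config.min_per_side,
            ridge_epsilon=config.ridge_epsilon)
        row = {"pathway_id": pid, "name": annotation.display_name(pid),
               "T2": t2, "p": p,
               "skip_reason": "" if np.isfinite(p) else
               f"fewer than {config.min_per_side} ranked members on a side"}
        for tag in profile.datasets:
            row[f"k_{tag}"] = ks.get(tag, 0)
            row[f"score_{tag}"] = scores.get(tag, np.nan)
        rows.append(row)
    result = pd.DataFrame(rows).set_index("pathway_id")
    result["q"] = qvalues(result["p"].to_numpy(), method=config.qvalue_method)
    sig, tier = classify_tiers(result["q"].to_numpy(),
                               fdr_threshold=config.fdr_threshold,
                               tier_high_q=config.tier_high_q)
    result["significant"] = sig
    result["tier"] = tier
    return result.sort_values("q")
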