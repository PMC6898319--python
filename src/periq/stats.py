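"""Rank-based statistics and the three-tier study analysis.

Tier 1 compares single-number RMSE summaries of the per-subject difference
maps between the naked eye and each lens (Mann-Whitney-U).  Tier 2 pools
full difference maps and compares groups with Kruskal-Wallis followed by
simultaneous pairwise contrasts under Scheffe's criterion on rank means.
Tier 3 repeats tier 2 within each sector x annulus segment of the field.

The exact small-sample Mann-Whitney null is obtained by enumerating all
group assignments (valid under ties); larger samples use the normal
approximation with tie correction.  The Scheffe criterion flags the pair
(i, j) when |Rbar_i - Rbar_j| exceeds
sqrt(chi2[k-1, 1-alpha] * C * N(N+1)/12 * (1/n_i + 1/n_j)),
with C the tie-correction factor of the pooled ranking.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .config import PipelineConfig
from .imaging import CutoffSurface, ReferenceImage, make_reference
from .mapping import (
    DifferenceMap,
    QualityMap,
    difference_map,
    interpolate_map,
    map_rmse,
    neural_limit_samples,
    sample_quality,
)
from .optics import normalize_low_order
from .segmentation import SegmentKey, segment_map

__all__ = [
    "StatResult",
    "PairwiseResult",
    "StudyReport",
    "mann_whitney_u",
    "wilcoxon_paired",
    "kruskal_wallis",
    "scheffe_pairwise",
    "compute_cohort_maps",
    "build_report",
    "run_study",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class StatResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    group_labels: tuple[str, ...] = ()
    n_per_group: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("every group must be non-empty")

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_labels": list(self.group_labels),
            "n_per_group": list(self.n_per_group),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StatResult":
        return cls(
            test_name=d["test_name"],
            statistic=d["statistic"],
            p_value=d["p_value"],
            group_labels=tuple(d["group_labels"]),
            n_per_group=tuple(d["n_per_group"]),
        )


@dataclass
class PairwiseResult:
    """One pairwise contrast with raw and Scheffe-adjusted significance."""

    pair: tuple[str, str]
    rank_mean_diff: float
    criterion: float
    significant: bool  # Scheffe-adjusted at alpha
    raw_p: float
    raw_significant: bool

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "rank_mean_diff": self.rank_mean_diff,
            "criterion": self.criterion,
            "significant": self.significant,
            "raw_p": self.raw_p,
            "raw_significant": self.raw_significant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PairwiseResult":
        return cls(
            pair=tuple(d["pair"]),
            rank_mean_diff=d["rank_mean_diff"],
            criterion=d["criterion"],
            significant=d["significant"],
            raw_p=d["raw_p"],
            raw_significant=d["raw_significant"],
        )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of sample x: # of (x_i, y_j) pairs with x_i > y_j, ties count half."""
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p by enumerating all group assignments.

    The permutation distribution of U is symmetric about n_x n_y / 2 even
    under ties, so the two-sided p-value is P(|U - mu| >= |u_obs - mu|).
    """
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    mu = nx * (n - nx) / 2.0
    u_obs = _u_statistic(x, y)
    d_obs = abs(u_obs - mu)
    hits = total = 0
    indices = np.arange(n)
    for comb in itertools.combinations(range(n), nx):
        sel = np.zeros(n, dtype=bool)
        sel[list(comb)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        if abs(u - mu) >= d_obs - 1e-12:
            hits += 1
        total += 1
    del indices
    return u_obs, hits / total


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> StatResult:
    """Two-sided Mann-Whitney-U test.

    ``mode='auto'`` enumerates the exact null when n_x + n_y <= 16 and
    otherwise uses the tie-corrected normal approximation; ``'exact'`` and
    ``'approx'`` force either branch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    exact = mode == "exact" or (mode == "auto" and len(x) + len(y) <= 16)
    if exact:
        u, p = _exact_mwu_p(x, y)
        name = "mann_whitney_u_exact"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        name = "mann_whitney_u_approx"
    return StatResult(
        test_name=name,
        statistic=u,
        p_value=min(p, 1.0),
        group_labels=("x", "y"),
        n_per_group=(len(x), len(y)),
    )


def wilcoxon_paired(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Paired-samples alternative (Wilcoxon signed-rank, two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) == 0:
        raise ValueError("paired samples must be non-empty and equal-length")
    if np.allclose(x, y):
        return StatResult("wilcoxon_paired", 0.0, 1.0, ("x", "y"), (len(x), len(y)))
    res = sps.wilcoxon(x, y, alternative="two-sided")
    return StatResult(
        "wilcoxon_paired", float(res.statistic), float(res.pvalue), ("x", "y"), (len(x), len(y))
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Scheffe pairwise
# ---------------------------------------------------------------------------

def kruskal_wallis(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> StatResult:
    """Tie-corrected Kruskal-Wallis H test, p from chi-square (k-1 d.f.)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    labels = tuple(labels) if labels else tuple(f"g{i}" for i in range(len(arrays)))
    try:
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            h, p = sps.kruskal(*arrays)
        h, p = float(h), float(p)
    except ValueError:
        h, p = float("nan"), float("nan")
    if np.isnan(h) or np.isnan(p):
        # all pooled values identical: no evidence of any difference
        h, p = 0.0, 1.0
    return StatResult(
        test_name="kruskal_wallis",
        statistic=h,
        p_value=min(p, 1.0),
        group_labels=labels,
        n_per_group=tuple(len(a) for a in arrays),
    )


def scheffe_pairwise(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> list[PairwiseResult]:
    """Simultaneous pairwise rank contrasts under Scheffe's criterion.

    Rank means come from the pooled (mid-)ranking; the variance term
    carries the tie-correction factor C = 1 - sum(t^3 - t)/(N^3 - N).  The
    unadjusted ("raw") p-value is the normal test on the same rank-mean
    difference, which is never stricter than the Scheffe criterion.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    labels = list(labels) if labels else [f"g{i}" for i in range(len(arrays))]
    k = len(arrays)
    pooled = np.concatenate(arrays)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    rank_means = []
    start = 0
    for a in arrays:
        rank_means.append(float(ranks[start : start + len(a)].mean()))
        start += len(a)
    _, counts = np.unique(pooled, return_counts=True)
    tie_c = 1.0 - float(np.sum(counts**3 - counts)) / (N**3 - N) if N > 1 else 0.0
    var_base = tie_c * N * (N + 1) / 12.0
    chi2_crit = float(sps.chi2.ppf(1.0 - alpha, k - 1))
    out = []
    for i, j in itertools.combinations(range(k), 2):
        diff = abs(rank_means[i] - rank_means[j])
        se2 = var_base * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j]))
        criterion = float(np.sqrt(chi2_crit * se2))
        if se2 > 0:
            z = diff / np.sqrt(se2)
            raw_p = float(2.0 * sps.norm.sf(z))
        else:  # all values tied: no contrast possible
            raw_p = 1.0
        out.append(
            PairwiseResult(
                pair=(labels[i], labels[j]),
                rank_mean_diff=diff,
                criterion=criterion,
                significant=bool(diff > criterion),
                raw_p=min(raw_p, 1.0),
                raw_significant=bool(raw_p < alpha),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Serializable three-tier analysis report.

    ``fullfield_by_condition`` compares the three optical conditions within
    each refraction pattern (and pooled over all subjects under the key
    ``"all"``); ``fullfield_by_pattern`` compares the refraction patterns
    within each optical condition.  ``regional`` repeats both groupings per
    field segment.
    """

    rmse_rows: list = field(default_factory=list)
    pooled_rmse: dict = field(default_factory=dict)
    rmse_tests: dict = field(default_factory=dict)
    fullfield_by_condition: dict = field(default_factory=dict)
    fullfield_by_pattern: dict = field(default_factory=dict)
    regional: dict = field(default_factory=dict)
    alpha: float = 0.05
    alpha_strict: float = 0.01
    seed: int | None = None
    config_digest: str | None = None

    # -- serialisation -----------------------------------------------------
    @staticmethod
    def _tier_to_dict(tier: dict) -> dict:
        return {
            key: {
                "kruskal": entry["kruskal"].to_dict(),
                "pairwise": [p.to_dict() for p in entry["pairwise"]],
            }
            for key, entry in tier.items()
        }

    @staticmethod
    def _tier_from_dict(d: dict) -> dict:
        return {
            key: {
                "kruskal": StatResult.from_dict(entry["kruskal"]),
                "pairwise": [PairwiseResult.from_dict(p) for p in entry["pairwise"]],
            }
            for key, entry in d.items()
        }

    def to_dict(self) -> dict:
        return {
            "rmse_rows": self.rmse_rows,
            "pooled_rmse": self.pooled_rmse,
            "rmse_tests": {k: v.to_dict() for k, v in self.rmse_tests.items()},
            "fullfield_by_condition": self._tier_to_dict(self.fullfield_by_condition),
            "fullfield_by_pattern": self._tier_to_dict(self.fullfield_by_pattern),
            "regional": {
                grouping: self._tier_to_dict(tier)
                for grouping, tier in self.regional.items()
            },
            "alpha": self.alpha,
            "alpha_strict": self.alpha_strict,
            "seed": self.seed,
            "config_digest": self.config_digest,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyReport":
        return cls(
            rmse_rows=[dict(r) for r in d["rmse_rows"]],
            pooled_rmse=dict(d["pooled_rmse"]),
            rmse_tests={k: StatResult.from_dict(v) for k, v in d["rmse_tests"].items()},
            fullfield_by_condition=cls._tier_from_dict(d["fullfield_by_condition"]),
            fullfield_by_pattern=cls._tier_from_dict(d["fullfield_by_pattern"]),
            regional={
                grouping: cls._tier_from_dict(tier)
                for grouping, tier in d["regional"].items()
            },
            alpha=d["alpha"],
            alpha_strict=d["alpha_strict"],
            seed=d.get("seed"),
            config_digest=d.get("config_digest"),
        )

    def to_json(self) -> str:
        import json

        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "StudyReport":
        import json

        return cls.from_dict(json.loads(s))


def compute_cohort_maps(
    cohort,
    config: PipelineConfig | None = None,
    ref: ReferenceImage | None = None,
    surface: CutoffSurface | None = None,
) -> dict:
    """Quality, limit and difference maps for every subject and condition.

    Low-order aberrations of each field are re-referenced to the fovea
    before simulation; the neural/diffraction-limit map is shared by all
    subjects.
    """
    config = config or PipelineConfig()
    ref = ref or make_reference("builtin", seed=config.reference_seed)
    surface = surface or CutoffSurface()
    limit = interpolate_map(neural_limit_samples(ref, surface, config))
    optical: dict[tuple[str, str], QualityMap] = {}
    diffs: dict[tuple[str, str], DifferenceMap] = {}
    for subject in cohort.subjects:
        for condition, zfield in subject.fields.items():
            normed = normalize_low_order(zfield)
            qmap = interpolate_map(sample_quality(normed, ref, surface, config))
            optical[(subject.subject_id, condition)] = qmap
            diffs[(subject.subject_id, condition)] = difference_map(limit, qmap)
    return {"limit": limit, "optical": optical, "difference": diffs}


def _grouped_values(
    diffs: dict,
    subjects,
    pooling: str,
    segment: SegmentKey | None = None,
    seg_values: dict | None = None,
) -> dict:
    """Per-(subject, condition) value vectors: full maps or one segment."""
    out = {}
    for subject in subjects:
        for condition in subject.fields:
            key = (subject.subject_id, condition)
            if segment is None:
                vals = diffs[key].values.ravel()
            else:
                vals = seg_values[key][segment]
            out[key] = vals.mean(keepdims=True) if pooling == "subject_means" else vals
    return out


def _tier_tests(
    groups: dict[str, np.ndarray], alpha: float
) -> dict:
    labels = sorted(groups)
    arrays = [groups[g] for g in labels]
    return {
        "kruskal": kruskal_wallis(arrays, labels),
        "pairwise": scheffe_pairwise(arrays, alpha, labels),
    }


def build_report(cohort, maps: dict, config: PipelineConfig | None = None) -> StudyReport:
    """Assemble the three analysis tiers from precomputed maps."""
    config = config or PipelineConfig()
    alpha = config.stats.alpha
    diffs = maps["difference"]
    conditions = list(cohort.subjects[0].fields)
    patterns = sorted({s.pattern for s in cohort.subjects})

    # tier 1: RMSE summaries -------------------------------------------------
    rmse_rows = []
    for subject in cohort.subjects:
        for condition in conditions:
            rmse_rows.append(
                {
                    "subject_id": subject.subject_id,
                    "pattern": subject.pattern,
                    "condition": condition,
                    "rmse": map_rmse(diffs[(subject.subject_id, condition)]),
                }
            )
    pooled_rmse = {
        condition: float(
            np.sqrt(
                np.mean(
                    np.concatenate(
                        [
                            np.square(diffs[(s.subject_id, condition)].values.ravel())
                            for s in cohort.subjects
                        ]
                    )
                )
            )
        )
        for condition in conditions
    }
    by_cond_rmse = {
        c: [r["rmse"] for r in rmse_rows if r["condition"] == c] for c in conditions
    }
    rmse_tests = {}
    baseline = "naked_eye"
    for condition in conditions:
        if condition == baseline or baseline not in by_cond_rmse:
            continue
        if config.stats.paired_rmse_test:
            res = wilcoxon_paired(by_cond_rmse[baseline], by_cond_rmse[condition])
        else:
            res = mann_whitney_u(
                by_cond_rmse[baseline], by_cond_rmse[condition], config.stats.mwu_mode
            )
        rmse_tests[f"{baseline}_vs_{condition}"] = res

    # tier 2: full-field grouped tests ---------------------------------------
    pooling = config.stats.fullfield_pooling
    values = _grouped_values(diffs, cohort.subjects, pooling)

    fullfield_by_condition = {}
    for pattern in patterns + ["all"]:
        members = [
            s for s in cohort.subjects if pattern == "all" or s.pattern == pattern
        ]
        groups = {
            c: np.concatenate([values[(s.subject_id, c)] for s in members])
            for c in conditions
        }
        fullfield_by_condition[pattern] = _tier_tests(groups, alpha)

    fullfield_by_pattern = {}
    for condition in conditions:
        groups = {
            p: np.concatenate(
                [values[(s.subject_id, condition)] for s in cohort.subjects if s.pattern == p]
            )
            for p in patterns
        }
        if len(groups) >= 2:
            fullfield_by_pattern[condition] = _tier_tests(groups, alpha)

    # tier 3: regional tests --------------------------------------------------
    seg_values = {
        key: segment_map(dmap) for key, dmap in diffs.items()
    }
    segments = sorted(
        next(iter(seg_values.values())), key=lambda k: (k.sector, k.annulus_deg)
    )
    regional = {"by_condition": {}, "by_pattern": {}}
    for seg in segments:
        seg_name = f"{seg.sector}_{seg.annulus_deg}_{seg.annulus_deg + 5}"
        vals = _grouped_values(diffs, cohort.subjects, pooling, seg, seg_values)
        groups_c = {
            c: np.concatenate([vals[(s.subject_id, c)] for s in cohort.subjects])
            for c in conditions
        }
        regional["by_condition"][seg_name] = _tier_tests(groups_c, alpha)
        groups_p = {
            p: np.concatenate(
                [
                    vals[(s.subject_id, c)]
                    for s in cohort.subjects
                    if s.pattern == p
                    for c in s.fields
                ]
            )
            for p in patterns
            if any(s.pattern == p for s in cohort.subjects)
        }
        if len(groups_p) >= 2:
            regional["by_pattern"][seg_name] = _tier_tests(groups_p, alpha)

    return StudyReport(
        rmse_rows=rmse_rows,
        pooled_rmse=pooled_rmse,
        rmse_tests=rmse_tests,
        fullfield_by_condition=fullfield_by_condition,
        fullfield_by_pattern=fullfield_by_pattern,
        regional=regional,
        alpha=alpha,
        alpha_strict=config.stats.alpha_strict,
        seed=config.seed,
        config_digest=config.digest(),
    )


def run_study(
    cohort,
    config: PipelineConfig | None = None,
    ref: ReferenceImage | None = None,
    surface: CutoffSurface | None = None,
) -> StudyReport:
    """End-to-end three-tier analysis of a cohort (maps recomputed)."""
    config = config or PipelineConfig()
    if not cohort.subjects:
        raise ValueError("cohort has no subjects")
    maps = compute_cohort_maps(cohort, config, ref, surface)
    return build_report(cohort, maps, config)
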