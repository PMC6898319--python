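"""Model/Results interface over the analysis pipeline.

``ImageQualityStudy`` is constructed from a cohort of Zernike fields (or
directly from the synthetic generator / a CSV file); ``fit()`` runs the
whole chain -- foveal normalisation, PSF simulation, quality sampling,
map interpolation, segmentation, three statistical tiers -- and returns a
``StudyResults`` carrying the maps, the RMSE table, the test results and
a printable ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .imaging import CutoffSurface, ReferenceImage, make_reference
from .mapping import QualityMap
from .segmentation import classify_pattern
from .stats import StudyReport, build_report, compute_cohort_maps
from .synthetic import (
    CONDITIONS,
    CohortDataset,
    SubjectRecord,
    extract_refraction_profile,
    generate_cohort,
)

__all__ = ["ImageQualityStudy", "StudyResults"]


class ImageQualityStudy:
    """Peripheral image-quality study model.

    Parameters
    ----------
    cohort : CohortDataset
        Subjects with Zernike fields for the three optical conditions.
    config : PipelineConfig, optional
        Full pipeline configuration (optics, imaging, mapping,
        segmentation, statistics, seeds).
    reference : ReferenceImage, optional
        Reference scene; defaults to the built-in seeded 1/f texture.
    cutoff_surface : CutoffSurface, optional
        Neural cutoff-frequency surface; defaults to the 20-anchor fixture.
    """

    def __init__(
        self,
        cohort: CohortDataset,
        config: PipelineConfig | None = None,
        reference: ReferenceImage | None = None,
        cutoff_surface: CutoffSurface | None = None,
    ):
        if not cohort.subjects:
            raise ValueError("cohort has no subjects")
        self.cohort = cohort
        self.config = config or PipelineConfig()
        self.reference = reference or make_reference(
            "builtin", seed=self.config.reference_seed
        )
        self.cutoff_surface = cutoff_surface or CutoffSurface()

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_synthetic(
        cls,
        n_per_pattern: dict[str, int] | None = None,
        config: PipelineConfig | None = None,
        **cohort_kwargs,
    ) -> "ImageQualityStudy":
        """Build the model on a freshly generated synthetic cohort."""
        config = config or PipelineConfig()
        cohort = generate_cohort(n_per_pattern, seed=config.seed, **cohort_kwargs)
        return cls(cohort, config)

    @classmethod
    def from_zernike_csv(
        cls,
        path: str | Path,
        patterns: dict[str, str] | None = None,
        config: PipelineConfig | None = None,
    ) -> "ImageQualityStudy":
        """Build the model from a Zernike-field CSV file.

        Subjects missing any of the three conditions are rejected.  Unless
        ``patterns`` supplies subject_id -> archetype labels, each subject
        is classified from the naked-eye horizontal refraction profile.
        """
        from .io import read_zernike_csv

        config = config or PipelineConfig()
        fields = read_zernike_csv(path)
        by_subject: dict[str, dict] = {}
        for f in fields:
            by_subject.setdefault(f.subject_id, {})[f.condition] = f
        subjects = []
        for sid in sorted(by_subject):
            conds = by_subject[sid]
            missing = set(CONDITIONS) - set(conds)
            if missing:
                raise ValueError(f"subject {sid} is missing condition(s): {sorted(missing)}")
            if patterns and sid in patterns:
                label = patterns[sid]
            else:
                profile = extract_refraction_profile(conds["naked_eye"])
                label = classify_pattern(profile, config.segmentation)
            subjects.append(SubjectRecord(subject_id=sid, pattern=label, fields=conds))
        return cls(CohortDataset(subjects=subjects, seed=config.seed), config)

    # -- estimation --------------------------------------------------------
    def fit(self) -> "StudyResults":
        """Run the full analysis and return the results object."""
        maps = compute_cohort_maps(
            self.cohort, self.config, self.reference, self.cutoff_surface
        )
        report = build_report(self.cohort, maps, self.config)
        return StudyResults(
            model=self,
            report=report,
            limit_map=maps["limit"],
            quality_maps=maps["optical"],
            difference_maps=maps["difference"],
        )


@dataclass
class StudyResults:
    """Fitted study: maps, RMSE table, statistical tiers, summary."""

    model: ImageQualityStudy
    report: StudyReport
    limit_map: QualityMap
    quality_maps: dict = dc_field(default_factory=dict)
    difference_maps: dict = dc_field(default_factory=dict)

    # -- tabular views -----------------------------------------------------
    @property
    def rmse_table(self) -> pd.DataFrame:
        """Per-subject, per-condition RMSE versus the neural limit."""
        return pd.DataFrame(self.report.rmse_rows)

    @property
    def pooled_rmse(self) -> dict:
        return dict(self.report.pooled_rmse)

    # -- summary -----------------------------------------------------------
    def summary(self) -> str:
        rep = self.report
        n_subjects = len({r["subject_id"] for r in rep.rmse_rows})
        lines = []
        bar = "=" * 64
        lines.append(bar)
        lines.append("Peripheral Image Quality Study".center(64))
        lines.append(bar)
        lines.append(
            f"Subjects: {n_subjects:<6d} Conditions: {len(rep.pooled_rmse):<4d} "
            f"alpha: {rep.alpha:g} / {rep.alpha_strict:g}"
        )
        if rep.seed is not None:
            lines.append(f"Seed: {rep.seed}   Config: {rep.config_digest}")
        lines.append("-" * 64)
        lines.append("Pooled RMSE vs neural/diffraction limit")
        for cond, rmse in sorted(rep.pooled_rmse.items(), key=lambda kv: kv[1]):
            test = rep.rmse_tests.get(f"naked_eye_vs_{cond}")
            note = f"   MWU vs naked eye p = {test.p_value:.4f}" if test else ""
            lines.append(f"  {cond:<16s} {rmse:.4f}{note}")
        lines.append("-" * 64)
        lines.append("Full-field Kruskal-Wallis (conditions within pattern)")
        for pattern, entry in sorted(rep.fullfield_by_condition.items()):
            kw = entry["kruskal"]
            sig = sum(p.significant for p in entry["pairwise"])
            lines.append(
                f"  {pattern:<6s} H = {kw.statistic:8.2f}  p = {kw.p_value:.4g}  "
                f"significant pairs (Scheffe): {sig}/{len(entry['pairwise'])}"
            )
        lines.append("Full-field Kruskal-Wallis (patterns within condition)")
        for cond, entry in sorted(rep.fullfield_by_pattern.items()):
            kw = entry["kruskal"]
            sig = sum(p.significant for p in entry["pairwise"])
            lines.append(
                f"  {cond:<16s} H = {kw.statistic:8.2f}  p = {kw.p_value:.4g}  "
                f"significant pairs (Scheffe): {sig}/{len(entry['pairwise'])}"
            )
        lines.append("-" * 64)
        for grouping, title in (
            ("by_condition", "Regional segments with all condition pairs significant"),
            ("by_pattern", "Regional segments with all pattern pairs significant"),
        ):
            tier = rep.regional.get(grouping, {})
            full = [
                name
                for name, entry in sorted(tier.items())
                if entry["pairwise"] and all(p.significant for p in entry["pairwise"])
            ]
            lines.append(f"{title}: {len(full)}/{len(tier)}")
        lines.append(bar)
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------
    def plot_maps(self, subject_id: str):
        """Quality and difference maps of one subject (one row per kind)."""
        import matplotlib.pyplot as plt

        conds = [c for c in CONDITIONS if (subject_id, c) in self.quality_maps]
        if not conds:
            raise KeyError(f"no maps for subject {subject_id!r}")
        grid = self.limit_map.grid_deg
        extent = (grid[0] - 0.5, grid[-1] + 0.5, grid[0] - 0.5, grid[-1] + 0.5)
        fig, axes = plt.subplots(2, len(conds), figsize=(4 * len(conds), 7.5))
        axes = np.atleast_2d(axes)
        for j, cond in enumerate(conds):
            q = self.quality_maps[(subject_id, cond)]
            d = self.difference_maps[(subject_id, cond)]
            im0 = axes[0, j].imshow(
                q.values, origin="lower", extent=extent, vmin=0, vmax=1, cmap="viridis"
            )
            axes[0, j].set_title(f"{cond}\ncross-correlation")
            im1 = axes[1, j].imshow(
                d.values, origin="lower", extent=extent, cmap="magma"
            )
            axes[1, j].set_title("deficit vs limit")
            for ax in (axes[0, j], axes[1, j]):
                ax.set_xlabel("x (deg, nasal +)")
                ax.set_ylabel("y (deg, superior +)")
            fig.colorbar(im0, ax=axes[0, j], shrink=0.8)
            fig.colorbar(im1, ax=axes[1, j], shrink=0.8)
        fig.suptitle(f"Subject {subject_id}")
        fig.tight_layout()
        return fig

    def plot_rmse(self):
        """Per-condition RMSE distribution across subjects."""
        import matplotlib.pyplot as plt

        df = self.rmse_table
        fig, ax = plt.subplots(figsize=(5, 4))
        conds = list(dict.fromkeys(df["condition"]))
        data = [df.loc[df["condition"] == c, "rmse"] for c in conds]
        ax.boxplot(data, tick_labels=conds)
        ax.set_ylabel("RMSE vs neural limit")
        fig.tight_layout()
        return fig
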