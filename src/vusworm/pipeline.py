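"""End-to-end workflow: simulate -> summarize -> test -> score -> report.

One :class:`RunConfig` fixes the panel, seed, per-assay sample sizes and
decision parameters; :func:`run_pipeline` is deterministic for a fixed
config and seed.  Default sample sizes follow the experimental protocol
(135 worms per strain for dye filling, 30 for roaming, 20 chemotaxis
plates).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import ValidationError
from . import assay_metrics, rank_stats, scoring, synthetic_data
from .synthetic_data import StrainPanel, WILDTYPE_STRAIN

__all__ = ["RunConfig", "InterpretationReport", "run_pipeline", "write_report", "load_report"]

logger = logging.getLogger("vusworm")


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one pipeline run."""

    panel_path: str | None = None   # None = built-in default panel
    seed: int = 0
    n_dyefill: int = 135
    n_roaming: int = 30
    n_chemotaxis_plates: int = 20
    worms_per_plate: tuple[int, int] = (50, 300)
    threshold: float = scoring.DEFAULT_THRESHOLD
    alpha: float = 0.05
    dunn_adjustment: str = "bonferroni"

    def __post_init__(self) -> None:
        if min(self.n_dyefill, self.n_roaming, self.n_chemotaxis_plates) < 1:
            raise ValidationError("all sample sizes must be >= 1")
        if not 0 < self.threshold < 3:
            raise ValidationError("threshold must lie in (0, 3)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")

    def load_panel(self) -> StrainPanel:
        if self.panel_path is None:
            return synthetic_data.default_panel()
        path = Path(self.panel_path)
        if not path.exists():
            raise ValidationError(f"panel file not found: {path}")
        return StrainPanel.from_json(path)


@dataclass
class InterpretationReport:
    """Full pipeline output: summaries, statistics, scores and provenance."""

    summaries: pd.DataFrame      # strain, assay, mean, dispersion, n, median, q1, q3
    scores: pd.DataFrame         # strain, dyefill/roaming/chemotaxis components, score, classification
    stats: dict[str, dict]       # assay -> {method, statistic, df, p_value, posthoc: DataFrame}
    ranked: list[str]            # strain ids, highest (benign) to lowest (pathogenic)
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "summaries": self.summaries.to_dict(orient="records"),
            "scores": self.scores.to_dict(orient="records"),
            "stats": {
                assay: {**{k: v for k, v in block.items() if k != "posthoc"},
                        "posthoc": block["posthoc"].to_dict(orient="records")}
                for assay, block in self.stats.items()
            },
            "ranked": list(self.ranked),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "InterpretationReport":
        stats = {
            assay: {**{k: v for k, v in block.items() if k != "posthoc"},
                    "posthoc": pd.DataFrame(block["posthoc"])}
            for assay, block in payload["stats"].items()
        }
        return cls(
            summaries=pd.DataFrame(payload["summaries"]),
            scores=pd.DataFrame(payload["scores"]),
            stats=stats,
            ranked=list(payload["ranked"]),
            provenance=payload["provenance"],
        )


def _summary_row(summary: assay_metrics.AssaySummary) -> dict:
    return {
        "strain": summary.strain_id,
        "assay": summary.assay,
        "mean": summary.mean,
        "dispersion": summary.dispersion,
        "n": summary.n,
        "median": summary.median,
        "q1": summary.q1,
        "q3": summary.q3,
    }


def run_pipeline(config: RunConfig) -> InterpretationReport:
    """Simulate the panel, summarize and test each assay, and score strains."""
    panel = config.load_panel()
    seed = config.seed
    logger.info("simulating %d strains (seed=%d)", len(panel.profiles), seed)

    # -- simulate ---------------------------------------------------------
    dyefill = {p.strain_id: synthetic_data.generate_dyefill(p, config.n_dyefill, seed)
               for p in panel.profiles}
    roaming_raw = {p.strain_id: synthetic_data.generate_roaming(p, config.n_roaming, seed)
                   for p in panel.profiles}
    chemotaxis = {
        p.strain_id: synthetic_data.generate_chemotaxis(
            p, config.n_chemotaxis_plates, config.worms_per_plate, seed
        )
        for p in panel.profiles
    }

    # -- per-replicate roaming normalization to wild-type (N2) ------------
    # panels without N2 fall back to the reference strain as the roaming
    # normalizer, keeping reduced panels (e.g. control-only) runnable
    wt_strain = WILDTYPE_STRAIN if WILDTYPE_STRAIN in roaming_raw else panel.reference_strain
    wt_roaming = roaming_raw[wt_strain]
    roaming = {
        strain: assay_metrics.normalize_roaming(frame, wt_roaming)
        for strain, frame in roaming_raw.items()
    }

    # -- summarize --------------------------------------------------------
    rows, dye_props = [], {}
    for strain in panel.strain_ids:
        dye_summary, props = assay_metrics.summarize_dyefill(
            dyefill[strain]["value"], strain_id=strain
        )
        dye_props[strain] = props.tolist()
        rows.append(_summary_row(dye_summary))
        rows.append(_summary_row(assay_metrics.summarize_roaming(roaming[strain], strain)))
        rows.append(_summary_row(assay_metrics.summarize_chemotaxis(chemotaxis[strain], strain)))
    summaries = pd.DataFrame(rows)
    logger.info("summarized %d strain x assay cells", len(summaries))

    # -- statistics -------------------------------------------------------
    stats_report: dict[str, dict] = {}
    grouped_by_assay = {} if len(panel.profiles) < 2 else {
        "dyefill": rank_stats.GroupedSamples.from_dict(
            {s: dyefill[s]["value"].to_numpy(float) for s in panel.strain_ids}
        ),
        "roaming": rank_stats.GroupedSamples.from_dict(
            {s: roaming[s]["normalized"].to_numpy(float) for s in panel.strain_ids}
        ),
        "chemotaxis": rank_stats.GroupedSamples.from_dict(
            {s: np.array([assay_metrics.chemotaxis_index(p) for p in chemotaxis[s]])
             for s in panel.strain_ids}
        ),
    }
    if not grouped_by_assay:
        logger.warning("fewer than 2 strains; skipping between-strain statistics")
    for assay, grouped in grouped_by_assay.items():
        result = rank_stats.run_test_battery(
            grouped, assay, alpha=config.alpha, dunn_adjustment=config.dunn_adjustment
        )
        stats_report[assay] = {
            "method": result.method,
            "statistic": result.statistic,
            "df": result.df,
            "p_value": result.p_value,
            "posthoc": rank_stats.posthoc_table(result),
        }
        logger.info("%s: %s statistic=%.3f p=%.3g", assay, result.method,
                    result.statistic, result.p_value)

    # -- scoring ----------------------------------------------------------
    mean_of = {
        (row["strain"], row["assay"]): row["mean"] for _, row in summaries.iterrows()
    }
    control = panel.reference_strain
    control_means = {a: mean_of[(control, a)] for a in scoring.ASSAY_ORDER}
    score_rows, score_objects = [], []
    for strain in panel.strain_ids:
        strain_means = {a: mean_of[(strain, a)] for a in scoring.ASSAY_ORDER}
        components = scoring.assay_components(strain_means, control_means)
        for assay, value in zip(scoring.ASSAY_ORDER, components):
            if value in (0.0, 1.0) and strain != control:
                logger.warning("%s %s component hit the %s", strain, assay,
                               "1.0 cap" if value == 1.0 else "0 floor")
        result = scoring.integrated_score(components, strain, config.threshold)
        score_objects.append(result)
        score_rows.append(
            {
                "strain": strain,
                "dyefill": result.normalized[0],
                "roaming": result.normalized[1],
                "chemotaxis": result.normalized[2],
                "score": result.score,
                "classification": result.classification,
            }
        )
    ranked = [s.strain_id for s in scoring.rank_strains(score_objects)]
    scores = pd.DataFrame(score_rows)
    logger.info("scored %d strains; top=%s bottom=%s", len(ranked), ranked[0], ranked[-1])

    provenance = {
        "config": {**asdict(config), "worms_per_plate": list(config.worms_per_plate)},
        "seed": seed,
        "software_version": __version__,
        "reference_strain": control,
        "dyefill_proportions": dye_props,
    }
    return InterpretationReport(summaries, scores, stats_report, ranked, provenance)


def write_report(report: InterpretationReport, output_dir: str | Path,
                 formats: tuple[str, ...] = ("tsv", "json")) -> list[Path]:
    """Write the report to disk; returns the files written.

    TSV output: score table, assay summaries and one pairwise-statistics
    table per assay.  JSON output: the full report, losslessly re-loadable
    with :func:`load_report`.
    """
    out = Path(output_dir)
    if not out.exists():
        logger.info("creating output directory %s", out)
    try:
        out.mkdir(parents=True, exist_ok=True)
        written = []
        if "tsv" in formats:
            for name, frame in (
                ("scores.tsv", report.scores),
                ("summaries.tsv", report.summaries),
                *((f"stats_{assay}.tsv", block["posthoc"])
                  for assay, block in report.stats.items()),
            ):
                path = out / name
                frame.to_csv(path, sep="\t", index=False)
                written.append(path)
        if "json" in formats:
            path = out / "report.json"
            path.write_text(json.dumps(report.to_dict(), indent=2, default=float) + "\n")
            written.append(path)
        return written
    except OSError as exc:
        raise OSError(f"failed writing report to {out}: {exc}") from exc


def load_report(path: str | Path) -> InterpretationReport:
    """Load a report previously written as JSON."""
    return InterpretationReport.from_dict(json.loads(Path(path).read_text()))
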