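"""Integration of the three assay averages into the 0–3 interpretation score.

Each strain's per-assay average is normalized to the positive-control strain
(``mks-3(+); nphp-4(delta)``) and capped at 1.0; the three normalized values
are summed with equal weighting into a score on [0, 3].  The control scored
against itself is exactly 3.0; strains scoring below the 2.5 cutoff are
interpreted as carrying a pathogenic variant.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import ValidationError

__all__ = [
    "IntegratedScore",
    "normalize_assay_mean",
    "integrated_score",
    "classify",
    "rank_strains",
    "assay_components",
    "vus_percentage",
    "DEFAULT_THRESHOLD",
    "ASSAY_ORDER",
]

DEFAULT_THRESHOLD = 2.5
ASSAY_ORDER = ("dyefill", "roaming", "chemotaxis")


@dataclass(frozen=True)
class IntegratedScore:
    """Normalized per-assay triplet, their sum, and the binary interpretation."""

    strain_id: str
    normalized: tuple[float, float, float]  # (dyefill, roaming, chemotaxis)
    score: float
    classification: str  # "pathogenic" | "benign"
    threshold: float = DEFAULT_THRESHOLD


def normalize_assay_mean(strain_mean: float, control_mean: float) -> float:
    """Normalize a strain's assay average to the control average, capping at 1.0.

    Negative ratios (possible for a worse-than-random chemotaxis index) are
    floored at 0 so no assay contributes a negative score component.
    """
    if control_mean <= 0:
        raise ValidationError(f"control mean must be > 0, got {control_mean}")
    return min(max(strain_mean / control_mean, 0.0), 1.0)


def assay_components(
    strain_means: dict[str, float], control_means: dict[str, float]
) -> tuple[float, float, float]:
    """Normalized (dyefill, roaming, chemotaxis) triplet for one strain.

    ``strain_means`` and ``control_means`` map assay name to the assay
    average (mean neurons filled; mean normalized roaming; mean chemotaxis
    index).  A negative chemotaxis mean is clamped to 0 before normalization.
    """
    components = []
    for assay in ASSAY_ORDER:
        if assay not in strain_means or assay not in control_means:
            raise ValidationError(f"missing {assay!r} mean")
        strain_mean = strain_means[assay]
        if assay == "chemotaxis":
            strain_mean = max(strain_mean, 0.0)
        components.append(normalize_assay_mean(strain_mean, control_means[assay]))
    return tuple(components)


def integrated_score(
    normalized: tuple[float, float, float],
    strain_id: str = "",
    threshold: float = DEFAULT_THRESHOLD,
) -> IntegratedScore:
    """Sum the normalized triplet (equal weighting) into the 0–3 score."""
    if len(normalized) != 3:
        raise ValidationError("expected exactly three normalized assay components")
    for value in normalized:
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"normalized component {value} outside [0, 1]")
    score = float(sum(normalized))
    return IntegratedScore(
        strain_id=strain_id,
        normalized=tuple(float(v) for v in normalized),
        score=score,
        classification=classify(score, threshold),
        threshold=threshold,
    )


def classify(score: float | IntegratedScore, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Binary interpretation: pathogenic iff score < threshold (strict).

    A score exactly at the threshold is benign.
    """
    value = score.score if isinstance(score, IntegratedScore) else float(score)
    return "pathogenic" if value < threshold else "benign"


def rank_strains(scores: list[IntegratedScore]) -> list[IntegratedScore]:
    """Order strains from highest (benign) to lowest (pathogenic) score;
    ties break alphabetically by strain label."""
    if not scores:
        raise ValidationError("no scores to rank")
    return sorted(scores, key=lambda s: (-s.score, s.strain_id))


def vus_percentage(n_vus: int, n_total: int) -> float:
    """Percentage of variants classified as VUS, e.g. among ClinVar missense
    entries for a gene."""
    if n_total <= 0 or n_vus < 0 or n_vus > n_total:
        raise ValidationError("need 0 <= n_vus <= n_total with n_total > 0")
    return 100.0 * n_vus / n_total
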