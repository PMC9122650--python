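"""Per-assay quantitative metrics for the three ciliary phenotyping assays.

The three readouts of sensory-cilium integrity and function in the worm are:

* **dye filling** — lipophilic dye uptake by the four phasmid (tail) neurons,
  scored per worm as the number of filled neuron cell bodies (0–4);
* **roaming** — grid squares a single worm enters on a food lawn over 20 h,
  normalized per biological replicate to the wild-type (N2) mean;
* **chemotaxis** — population assay scored per plate by the chemotaxis index
  ``(b − c) / n`` where ``b`` worms ended near the benzaldehyde (attractant)
  spot, ``c`` near the ethanol (solvent control) spot, and ``n`` is the total
  on the plate.

Electron-micrograph summaries (cilia per amphid pore, transition-zone
phenotype categories) are summarized here too; their raw tallies are inputs,
not computed from images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import ValidationError

__all__ = [
    "ChemotaxisPlate",
    "AssaySummary",
    "UltrastructureSummary",
    "TZ_CATEGORIES",
    "chemotaxis_index",
    "summarize_dyefill",
    "normalize_roaming",
    "summarize_chemotaxis",
    "summarize_ultrastructure",
]

#: Transition-zone ultrastructure phenotype classes, ordered by severity of
#: microtubule–membrane detachment seen in cross-section TEM.
TZ_CATEGORIES = ("wild-type", "mild", "moderate", "severe")


@dataclass(frozen=True)
class ChemotaxisPlate:
    """Counts for one chemotaxis plate: ``b`` worms in the benzaldehyde zone,
    ``c`` in the ethanol control zone, ``n`` total worms on the plate."""

    b: int
    c: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"plate must have n >= 1 worms, got n={self.n}")
        if self.b < 0 or self.c < 0:
            raise ValidationError(f"zone counts must be >= 0, got b={self.b}, c={self.c}")
        if self.b + self.c > self.n:
            raise ValidationError(
                f"zone counts exceed plate total: b={self.b} + c={self.c} > n={self.n}"
            )


@dataclass
class AssaySummary:
    """Mean and dispersion of one assay for one strain.

    ``mean`` carries assay-specific units: mean neurons filled (0–4) for dye
    filling, mean normalized roaming activity (unitless) for roaming, and the
    mean chemotaxis index (in [−1, 1]) for chemotaxis.  ``dispersion`` is the
    sample standard deviation; the quartiles back box-plot style reporting and
    feed nothing downstream.
    """

    strain_id: str
    assay: str
    mean: float
    dispersion: float
    n: int
    median: float | None = None
    q1: float | None = None
    q3: float | None = None


@dataclass
class UltrastructureSummary:
    strain_id: str
    mean_cilia_per_pore: float
    tz_category_proportions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.tz_category_proportions, dtype=float)
        if p.shape != (len(TZ_CATEGORIES),) or not np.isclose(p.sum(), 1.0):
            raise ValidationError("tz_category_proportions must be a 4-vector summing to 1")
        if not 0.0 <= self.mean_cilia_per_pore <= 10.0:
            raise ValidationError("mean cilia per pore must lie in [0, 10]")
        self.tz_category_proportions = p


def chemotaxis_index(plate: ChemotaxisPlate) -> float:
    """Chemotaxis index ``(b − c) / n`` for one plate; lies in [−1, 1]."""
    return (plate.b - plate.c) / plate.n


def _summary_stats(values: np.ndarray) -> tuple[float, float, float, float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd, float(med), float(q1), float(q3)


def summarize_dyefill(
    records: Iterable[int], strain_id: str = ""
) -> tuple[AssaySummary, np.ndarray]:
    """Summarize per-worm filled-neuron counts.

    Returns the assay summary (mean neurons filled) together with the
    proportion of worms with 0..4 filled phasmid neurons — the stacked-bar
    representation of the population.
    """
    values = np.asarray(list(records))
    if values.size == 0:
        raise ValidationError("no dye-fill records")
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(values == np.floor(values)):
            raise ValidationError("dye-fill counts must be integers in 0..4")
        values = values.astype(int)
    if values.min() < 0 or values.max() > 4:
        raise ValidationError("dye-fill counts must lie in 0..4")
    mean, sd, med, q1, q3 = _summary_stats(values.astype(float))
    proportions = np.bincount(values, minlength=5) / values.size
    summary = AssaySummary(strain_id, "dyefill", mean, sd, int(values.size), med, q1, q3)
    return summary, proportions


def normalize_roaming(records: pd.DataFrame, wildtype_records: pd.DataFrame) -> pd.DataFrame:
    """Normalize per-worm roaming counts to the wild-type mean of the same
    biological replicate.

    Both frames need ``replicate`` and ``value`` columns.  Every replicate
    present in ``records`` must have wild-type worms in the same replicate
    with a nonzero mean.  Returns a copy of ``records`` with a
    ``normalized`` column; by construction the wild-type strain normalized
    against itself has mean 1.0 in every replicate.
    """
    for frame, name in ((records, "records"), (wildtype_records, "wildtype_records")):
        missing = {"replicate", "value"} - set(frame.columns)
        if missing:
            raise ValidationError(f"{name} missing columns: {sorted(missing)}")
    wt_means = wildtype_records.groupby("replicate")["value"].mean()
    out = records.copy()
    unmatched = set(out["replicate"]) - set(wt_means.index)
    if unmatched:
        raise ValidationError(f"no wild-type records for replicates: {sorted(unmatched)}")
    denom = out["replicate"].map(wt_means)
    if (denom <= 0).any():
        bad = sorted(set(out.loc[denom <= 0, "replicate"]))
        raise ValidationError(f"wild-type replicate mean is zero for replicates: {bad}")
    out["normalized"] = out["value"] / denom
    return out


def summarize_roaming(normalized: pd.DataFrame, strain_id: str = "") -> AssaySummary:
    """Summarize normalized roaming values (``normalized`` column)."""
    if "normalized" not in normalized.columns:
        raise ValidationError("expected a 'normalized' column; run normalize_roaming first")
    values = normalized["normalized"].to_numpy(dtype=float)
    if values.size == 0:
        raise ValidationError("no roaming records")
    mean, sd, med, q1, q3 = _summary_stats(values)
    return AssaySummary(strain_id, "roaming", mean, sd, int(values.size), med, q1, q3)


def summarize_chemotaxis(plates: Sequence[ChemotaxisPlate], strain_id: str = "") -> AssaySummary:
    """Mean and dispersion of per-plate chemotaxis indices (plates are the
    statistical unit; each plate carries a 50–300 worm population)."""
    if len(plates) == 0:
        raise ValidationError("no chemotaxis plates")
    indices = np.array([chemotaxis_index(p) for p in plates])
    mean, sd, med, q1, q3 = _summary_stats(indices)
    return AssaySummary(strain_id, "chemotaxis", mean, sd, len(plates), med, q1, q3)


def summarize_ultrastructure(
    per_pore_cilia_counts: Iterable[float],
    per_tz_category_calls: Iterable[str],
    strain_id: str = "",
) -> UltrastructureSummary:
    """Summarize TEM cross-section tallies: mean ciliary axonemes per amphid
    pore (wild-type complement 10) and proportions of transition-zone
    phenotype categories."""
    counts = np.asarray(list(per_pore_cilia_counts), dtype=float)
    calls = list(per_tz_category_calls)
    if counts.size == 0 or len(calls) == 0:
        raise ValidationError("need at least one pore count and one TZ call")
    unknown = set(calls) - set(TZ_CATEGORIES)
    if unknown:
        raise ValidationError(f"unknown TZ category labels: {sorted(unknown)}")
    proportions = np.array([calls.count(cat) for cat in TZ_CATEGORIES]) / len(calls)
    return UltrastructureSummary(strain_id, float(counts.mean()), proportions)
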