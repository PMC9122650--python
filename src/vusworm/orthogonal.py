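"""Orthogonal validation arithmetic: ROR2 phospho-induction and GDT scores.

Two quantifications independent of the worm assays support the variant
interpretations:

* **ROR2 induction** — in a genetic complementation assay, non-canonical
  Wnt5a signalling through a functional TMEM67 construct increases the ratio
  of phosphorylated to unphosphorylated ROR2 co-receptor.  From densitometry
  band intensities, the per-replicate induction is the Wnt5a-treatment
  phospho:unphospho ratio over the control-treatment ratio, as a percentage
  (100% = no induction).  The loading-control (beta-actin) normalization
  cancels in the ratio and is retained only for QC.

* **GDT** — the Global Distance Test summarizes predicted-structure quality
  from per-residue estimated modelling errors.  The weighted count
  1*N(1) + 0.75*N(2) + 0.5*N(4) + 0.25*N(8), divided by protein length and
  multiplied by 100, where N(x) counts residues with error < x Angstrom.
  With cumulative counts (the formula as written) a perfect model scores
  250; the conventional shell reading weights each residue once by its
  finest satisfied threshold, with maximum 100.  Both are implemented;
  cumulative is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import ValidationError

__all__ = [
    "DensitometryRecord",
    "GDTInput",
    "InductionResult",
    "ror2_induction",
    "normalize_to_wildtype_construct",
    "gdt_score",
    "GDT_THRESHOLDS",
    "GDT_WEIGHTS",
]

GDT_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)
GDT_WEIGHTS = (1.0, 0.75, 0.5, 0.25)


@dataclass(frozen=True)
class DensitometryRecord:
    """One western-blot band-intensity measurement."""

    construct: str
    treatment: str  # "control" | "Wnt5a"
    phospho_intensity: float
    unphospho_intensity: float
    loading_intensity: float
    replicate: int

    def __post_init__(self) -> None:
        if self.treatment not in ("control", "Wnt5a"):
            raise ValidationError(f"unknown treatment {self.treatment!r}")
        if min(self.phospho_intensity, self.loading_intensity) < 0:
            raise ValidationError("band intensities must be >= 0")
        if self.unphospho_intensity <= 0:
            raise ValidationError("unphosphorylated band intensity must be > 0")


@dataclass(frozen=True)
class GDTInput:
    """Per-residue estimated modelling errors (Angstrom) and protein length."""

    residue_errors: tuple[float, ...]
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError("protein length must be > 0")
        errors = np.asarray(self.residue_errors, dtype=float)
        if (errors < 0).any():
            raise ValidationError("residue errors must be >= 0")
        if errors.size > self.length:
            raise ValidationError("more residue errors than residues")


@dataclass
class InductionResult:
    construct: str
    per_replicate: np.ndarray
    mean: float
    sem: float


def _ratio(phospho: float, unphospho: float, loading: float) -> float:
    # beta-actin loading normalization cancels in phospho:unphospho, applied
    # anyway so QC on the individual normalized bands stays meaningful
    if loading <= 0:
        raise ValidationError("loading-control intensity must be > 0")
    return (phospho / loading) / (unphospho / loading)


def ror2_induction(records: pd.DataFrame) -> InductionResult:
    """Percent induction of the phospho:unphospho ROR2 ratio by Wnt5a.

    ``records`` holds one construct's densitometry table (columns construct,
    treatment, replicate, phospho_intensity, unphospho_intensity,
    loading_intensity).  Every replicate needs both treatment arms; per
    replicate the induction is 100 x (Wnt5a ratio / control ratio), and the
    replicate mean and SEM are reported.
    """
    required = {
        "construct",
        "treatment",
        "replicate",
        "phospho_intensity",
        "unphospho_intensity",
        "loading_intensity",
    }
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"densitometry table missing columns: {sorted(missing)}")
    constructs = records["construct"].unique()
    if len(constructs) != 1:
        raise ValidationError(f"expected one construct, got {list(constructs)}")
    inductions = []
    for rep, sub in records.groupby("replicate"):
        arms = {}
        for treatment in ("control", "Wnt5a"):
            arm = sub[sub["treatment"] == treatment]
            if len(arm) != 1:
                raise ValidationError(
                    f"replicate {rep}: need exactly one {treatment} record, got {len(arm)}"
                )
            row = arm.iloc[0]
            arms[treatment] = _ratio(
                row["phospho_intensity"], row["unphospho_intensity"], row["loading_intensity"]
            )
        if arms["control"] <= 0:
            raise ValidationError(f"replicate {rep}: control ratio must be > 0")
        inductions.append(100.0 * arms["Wnt5a"] / arms["control"])
    per_rep = np.asarray(inductions)
    sem = float(per_rep.std(ddof=1) / np.sqrt(per_rep.size)) if per_rep.size > 1 else 0.0
    return InductionResult(str(constructs[0]), per_rep, float(per_rep.mean()), sem)


def normalize_to_wildtype_construct(
    inductions: dict[str, float], wildtype_induction: float
) -> dict[str, float]:
    """Express each construct's percent induction as a percentage of the
    wild-type construct's induction."""
    if wildtype_induction <= 0:
        raise ValidationError("wild-type induction must be > 0")
    return {k: 100.0 * v / wildtype_induction for k, v in inductions.items()}


def gdt_score(gdt_input: GDTInput, counting: str = "cumulative") -> float:
    """Weighted model-quality score from per-residue errors.

    ``counting="cumulative"`` evaluates 1*N(1) + 0.75*N(2) + 0.5*N(4) +
    0.25*N(8) with cumulative counts N(x) = #{errors < x}, divided by length
    and multiplied by 100 (maximum 250).  ``counting="shell"`` weights each
    residue once by its finest satisfied threshold (maximum 100).
    """
    errors = np.asarray(gdt_input.residue_errors, dtype=float)
    if counting == "cumulative":
        weighted = sum(
            w * float((errors < t).sum()) for w, t in zip(GDT_WEIGHTS, GDT_THRESHOLDS)
        )
    elif counting == "shell":
        bins = np.digitize(errors, GDT_THRESHOLDS, right=False)  # 0 => e < 1, 4 => e >= 8
        shell_weights = np.array(GDT_WEIGHTS + (0.0,))
        weighted = float(shell_weights[bins].sum())
    else:
        raise ValidationError(f"counting must be 'cumulative' or 'shell', got {counting!r}")
    return 100.0 * weighted / gdt_input.length
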