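"""The Corticalization Index and its risk scale.

The index combines the three texture primitives of one peri-implant ROI:

    CI = LngREmph · MOD / DifEntr

where LngREmph is long-run emphasis, MOD is mean optical density, and
DifEntr is difference entropy.  Corticalized bone (long uniform dense runs,
little grey-level scatter) drives CI up; healthy trabecular bone keeps it
low.  The 3-month CI stratifies the 5-year marginal-bone-loss risk:

* CI < 300 — low risk;
* 300 ≤ CI < 500 — borderline (a gap the published scale leaves unlabeled;
  made explicit here so the classifier is total);
* 500 ≤ CI ≤ 1200 — medium risk;
* CI > 1200 — critical risk of marginal bone loss.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import pandas as pd

from .texture import TextureFeatures

__all__ = [
    "RiskClass",
    "ScaleConfig",
    "CIRecord",
    "UndefinedCIError",
    "corticalization_index",
    "classify_risk",
    "per_implant_summary",
]


class UndefinedCIError(ValueError):
    """Raised when CI is requested for a degenerate (constant) ROI.

    A constant patch has zero difference entropy, so the ratio is undefined.
    """

    def __init__(self, message: str = "CI undefined: difference entropy is 0 (degenerate ROI)"):
        super().__init__(message)
        self.degenerate = True


class RiskClass(enum.IntEnum):
    """Ordered risk bands of the Corticalization Scale."""

    LOW = 0
    BORDERLINE = 1
    MEDIUM = 2
    CRITICAL = 3

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class ScaleConfig:
    """Corticalization Scale thresholds on the 3-month CI.

    Defaults are the published band edges (300 / 500 / 1200).  They are
    configuration, not constants, because absolute CI magnitudes depend on
    the texture conventions (grey-level depth, offset direction, log base):
    recalibration must not require code changes.
    """

    low_threshold: float = 300.0
    medium_threshold: float = 500.0
    critical_threshold: float = 1200.0

    def __post_init__(self) -> None:
        if not 0 < self.low_threshold < self.medium_threshold < self.critical_threshold:
            raise ValueError("thresholds must satisfy 0 < low < medium < critical")


@dataclass
class CIRecord:
    """Per-ROI feature vector with its CI value and risk class."""

    implant_id: str
    visit: int  # months since functional loading
    roi_label: str
    dif_entr: float
    lng_r_emph: float
    mean_optical_density: float
    ci: float | None = None
    risk: RiskClass | None = None


def corticalization_index(features: TextureFeatures | CIRecord) -> float:
    """CI = LngREmph · MOD / DifEntr.

    Raises :class:`UndefinedCIError` when DifEntr is 0 (constant ROI).
    """
    de = features.dif_entr
    lre = features.lng_r_emph
    mod = features.mean_optical_density
    if de <= 0:
        raise UndefinedCIError()
    return lre * mod / de


def classify_risk(ci: float, config: ScaleConfig | None = None) -> RiskClass:
    """Place a finite positive CI value on the Corticalization Scale.

    Band edges: low iff ``ci < low``; borderline iff ``low <= ci < medium``;
    medium iff ``medium <= ci <= critical``; critical iff ``ci > critical``.
    The classifier is total and monotone over (0, inf).
    """
    config = config or ScaleConfig()
    if not math.isfinite(ci) or ci <= 0:
        raise ValueError(f"CI must be finite and positive, got {ci!r}")
    if ci < config.low_threshold:
        return RiskClass.LOW
    if ci < config.medium_threshold:
        return RiskClass.BORDERLINE
    if ci <= config.critical_threshold:
        return RiskClass.MEDIUM
    return RiskClass.CRITICAL


def per_implant_summary(
    records: list[CIRecord],
    config: ScaleConfig | None = None,
) -> pd.DataFrame:
    """Aggregate per-ROI CI records to one row per (implant, visit).

    Mesial and distal CI values are retained and their arithmetic mean is
    reported as the implant-level CI (the two ROIs are samples of the same
    peri-implant bone).  An implant with a single ROI gets that ROI's CI and
    a ``single_roi`` flag.  Conflicting duplicates (same implant, visit and
    ROI label with different CI) are an error.
    """
    config = config or ScaleConfig()
    rows: dict[tuple[str, int], dict] = {}
    for rec in records:
        ci = rec.ci
        if ci is None:
            ci = corticalization_index(rec)
        key = (rec.implant_id, rec.visit)
        entry = rows.setdefault(key, {})
        if rec.roi_label in entry and not math.isclose(entry[rec.roi_label], ci, rel_tol=1e-12):
            raise ValueError(
                f"conflicting duplicate record for implant {rec.implant_id!r}, "
                f"visit {rec.visit}, ROI {rec.roi_label!r}"
            )
        entry[rec.roi_label] = ci

    out = []
    for (implant_id, visit), entry in sorted(rows.items()):
        mesial = entry.get("mesial")
        distal = entry.get("distal")
        present = [v for v in (mesial, distal) if v is not None]
        ci_mean = sum(present) / len(present)
        out.append(
            {
                "implant_id": implant_id,
                "visit": visit,
                "ci_mesial": mesial,
                "ci_distal": distal,
                "ci_mean": ci_mean,
                "single_roi": len(present) == 1,
                "risk": classify_risk(ci_mean, config).label,
            }
        )
    return pd.DataFrame(out)
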