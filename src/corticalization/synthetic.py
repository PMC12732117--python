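"""Synthetic bone-texture phantoms and a longitudinal implant cohort.

No clinical radiographs ship with the package, so two generators stand in:

**Phantoms** — Gaussian random fields whose correlation length and mean
intensity interpolate, under a single parameter ``c`` in [0, 1], between a
trabecular-like regime (c = 0: short correlation length, mid grey level)
and a corticalized regime (c = 1: long correlation length, brighter, more
uniform).  They exercise the texture pipeline: difference entropy falls and
long-run emphasis / mean density rise as ``c`` grows, so the
Corticalization Index is increasing in ``c``.

**Cohort** — per-implant Corticalization Index at 0, 3 and 60 months of
functional loading plus marginal bone loss, with the dependence structure a
5-year implant follow-up reports: right-skewed CI, positive CI3-CI60
dependence, and 60-month MBL rising once the 3-month CI exceeds a
changepoint.  Defaults reproduce the published CI moments (CI3 ≈ 210 ±
150, CI60 ≈ 278) and the low-CI-stratum 60-month MBL mean (≈ 0.73 mm);
the latent MBL noise (0.30 mm) is set by the module's own identifiability
requirement — the changepoint model must be recoverable from a
1000-implant cohort — and is therefore tighter than a clinical cohort's
marginal MBL spread, which also carries measurement and between-patient
components this generator does not model.

Neither generator claims histological or projection-physics realism.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import GreyImage

__all__ = ["PhantomParams", "CohortParams", "generate_phantom", "generate_cohort"]


@dataclass(frozen=True)
class PhantomParams:
    """Controls for the bone-texture phantom.

    ``corticalization`` (c) is the single dial: correlation length grows
    linearly from ``corr_length_trabecular_px`` to ``corr_length_cortical_px``
    and the mean grey value from ``base_density`` to
    ``base_density + density_gain`` as c goes 0 → 1.  ``texture_sd`` is the
    grey-level standard deviation of the structured field, ``noise_sd`` that
    of the uncorrelated acquisition noise added on top.
    """

    size: tuple[int, int] = (64, 64)
    corticalization: float = 0.0
    corr_length_trabecular_px: float = 1.0
    corr_length_cortical_px: float = 5.0
    base_density: float = 90.0
    density_gain: float = 120.0
    texture_sd: float = 30.0
    noise_sd: float = 2.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.size) < 32:
            raise ValueError("phantom size must be at least 32x32")
        if not 0.0 <= self.corticalization <= 1.0:
            raise ValueError("corticalization must lie in [0, 1]")
        if self.noise_sd < 0 or self.texture_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def generate_phantom(params: PhantomParams | None = None, **overrides) -> GreyImage:
    """Generate one reproducible bone-texture phantom patch.

    White Gaussian noise is smoothed with an isotropic Gaussian kernel whose
    width is the c-interpolated correlation length, re-standardized to
    ``texture_sd``, shifted to the c-dependent mean density, degraded with
    acquisition noise, and clipped/rounded to the integer grey range.
    Identical parameters and seed give identical patches.
    """
    params = params or PhantomParams()
    if overrides:
        params = replace(params, **overrides)
    rng = np.random.default_rng(params.seed)
    c = params.corticalization
    rows, cols = params.size

    sigma = (1 - c) * params.corr_length_trabecular_px + c * params.corr_length_cortical_px
    # pad so the border statistics match the interior after smoothing
    pad = int(np.ceil(4 * sigma))
    field = rng.standard_normal((rows + 2 * pad, cols + 2 * pad))
    field = ndimage.gaussian_filter(field, sigma=sigma, mode="reflect")
    field = field[pad:pad + rows, pad:pad + cols]
    sd = field.std()
    if sd > 0:
        field = field / sd * params.texture_sd
    # corticalized bone is more uniform: damp structured contrast with c
    field *= (1.0 - 0.5 * c)

    mean = params.base_density + c * params.density_gain
    img = mean + field
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    vmax = (1 << params.bit_depth) - 1
    pixels = np.clip(np.rint(img), 0, vmax).astype(np.int64)
    return GreyImage(pixels, bit_depth=params.bit_depth)


@dataclass(frozen=True)
class CohortParams:
    """Generative model for the longitudinal cohort table.

    3-month CI is Gamma(``ci3_shape``, ``ci3_scale``) — right-skewed with
    mean shape·scale.  60-month CI multiplies CI3 by a lognormal drift with
    median ``ci60_drift`` (positive CI3-CI60 dependence).  Latent 60-month
    MBL is ``mbl_intercept + mbl_slope·max(0, CI3 − changepoint) + N(0,
    noise_sd)`` clamped at zero; 3-month MBL is a small CI-independent
    clamped Gaussian.  Mesial/distal ROI values scatter around the implant
    CI with SD ``roi_sd``.  ``dropout_rate`` removes implants from the
    60-month visit at random.
    """

    n_implants: int = 1026
    ci3_shape: float = 2.0
    ci3_scale: float = 105.0
    ci60_drift: float = 1.30
    ci60_sd_log: float = 0.30
    ci0_scale_factor: float = 0.83  # 0-month CI relative to 3-month
    mbl_intercept: float = 0.73
    mbl_slope: float = 0.0025
    changepoint: float = 300.0
    noise_sd: float = 0.30
    mbl3_latent_mean: float = -0.30
    mbl3_latent_sd: float = 0.80
    roi_sd: float = 20.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_implants < 10:
            raise ValueError("cohort needs at least 10 implants")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.noise_sd == 0 and self.dropout_rate > 0:
            raise ValueError("zero-variance cohort with dropout is degenerate")


def generate_cohort(params: CohortParams | None = None, **overrides) -> pd.DataFrame:
    """Simulate the longitudinal cohort.

    Returns a tidy table with one row per (implant, visit) and columns
    ``implant_id, visit_months, ci_mesial, ci_distal, ci, mbl_mm``.
    ``ci`` is the implant-level value (mean of the two ROIs).  Reproducible
    under ``seed``.
    """
    params = params or CohortParams()
    if overrides:
        params = replace(params, **overrides)
    rng = np.random.default_rng(params.seed)
    n = params.n_implants

    ci3 = rng.gamma(params.ci3_shape, params.ci3_scale, size=n)
    ci3 = np.maximum(ci3, 1.0)
    mu_log = np.log(params.ci60_drift)
    ci60 = ci3 * rng.lognormal(mu_log, params.ci60_sd_log, size=n)
    ci0 = np.maximum(ci3 * params.ci0_scale_factor
                     * rng.lognormal(0.0, 0.25, size=n), 1.0)

    excess = np.maximum(0.0, ci3 - params.changepoint)
    latent60 = (
        params.mbl_intercept
        + params.mbl_slope * excess
        + rng.normal(0.0, params.noise_sd, size=n)
    )
    mbl60 = np.maximum(0.0, latent60)
    mbl3 = np.maximum(0.0, rng.normal(params.mbl3_latent_mean,
                                      params.mbl3_latent_sd, size=n))
    mbl0 = np.zeros(n)

    keep60 = rng.random(n) >= params.dropout_rate

    rows = []
    visits = [(0, ci0, mbl0, None), (3, ci3, mbl3, None), (60, ci60, mbl60, keep60)]
    for months, ci, mbl, keep in visits:
        # mesial/distal scatter around the implant value, floored at 1
        jitter = rng.normal(0.0, params.roi_sd, size=(n, 2))
        mesial = np.maximum(ci + jitter[:, 0], 1.0)
        distal = np.maximum(ci + jitter[:, 1], 1.0)
        for i in range(n):
            if keep is not None and not keep[i]:
                continue
            rows.append(
                {
                    "implant_id": f"imp{i:04d}",
                    "visit_months": months,
                    "ci_mesial": mesial[i],
                    "ci_distal": distal[i],
                    "ci": (mesial[i] + distal[i]) / 2.0,
                    "mbl_mm": mbl[i],
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["seed"] = params.seed
    return df
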