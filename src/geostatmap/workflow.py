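"""Single-scale analysis pipeline shared by the experiment drivers and CLI.

One call rasterizes the observations at a given smoothing diameter, fits
the mass-univariate GLM, estimates residual smoothness, derives the
voxel-level FWE threshold and returns thresholded significance maps for a
set of contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_grid import GridSpec, ObservationTable, build_response_stack
from .glm_engine import (
    DesignMatrix,
    DesignSpec,
    build_design,
    contrast_t_map,
    fit_mass_univariate,
    MassUnivariateFit,
)
from .rft_inference import (
    SignificanceMap,
    SmoothnessEstimate,
    estimate_fwhm_from_responses,
    fwe_threshold,
    resel_counts,
    threshold_map,
)

__all__ = ["ScaleAnalysis", "analyze_scale"]


@dataclass
class ScaleAnalysis:
    """Everything produced for one smoothing scale."""

    diameter: float
    design: DesignMatrix
    fit: MassUnivariateFit
    t_maps: dict[str, np.ndarray]
    significance: dict[str, SignificanceMap]
    smoothness: SmoothnessEstimate
    threshold_t: float
    alpha: float
    tails: str


def analyze_scale(
    obs: ObservationTable,
    design: DesignSpec | DesignMatrix,
    contrasts: dict[str, np.ndarray],
    diameter: float,
    grid: GridSpec,
    alpha: float = 0.05,
    tails: str = "one",
    mask: np.ndarray | None = None,
    dtype=np.float64,
) -> ScaleAnalysis:
    """Run the full rasterize -> GLM -> RFT chain at one smoothing scale."""
    if isinstance(design, DesignSpec):
        design = build_design(obs, design)
    stack = build_response_stack(obs, [diameter], grid, dtype=dtype)
    fit = fit_mass_univariate(stack.data[0], design, mask=mask, grid=grid,
                              keep_residuals=False)

    analysis_mask = fit.mask & ~fit.degenerate
    smooth = estimate_fwhm_from_responses(stack.data[0], design.X,
                                          mask=analysis_mask)
    resels = resel_counts(analysis_mask, smooth.fwhm_x, smooth.fwhm_y)
    smooth = SmoothnessEstimate(smooth.fwhm_x, smooth.fwhm_y, resels)
    thr = fwe_threshold(alpha, fit.nu, resels, int(analysis_mask.sum()), tails)

    t_maps: dict[str, np.ndarray] = {}
    sig: dict[str, SignificanceMap] = {}
    for name, c in contrasts.items():
        t = contrast_t_map(fit, np.asarray(c, dtype=float))
        t_maps[name] = t
        sig[name] = threshold_map(t, thr, tails=tails, mask=analysis_mask,
                                  alpha=alpha)
    return ScaleAnalysis(
        diameter=float(diameter), design=design, fit=fit, t_maps=t_maps,
        significance=sig, smoothness=smooth, threshold_t=thr, alpha=alpha,
        tails=tails,
    )
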