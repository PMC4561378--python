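"""End-to-end composition: smoothing -> search band -> init -> evolution."""

from __future__ import annotations

import numpy as np

from .evolve import (
    ChanVeseParams,
    RegionStats,
    SPFParams,
    evolve_chan_vese,
    evolve_sbgfrls,
    init_levelset,
    mask_from_levelset,
)
from .initcontour import Contour, clip_profile, profile_to_contour, radial_profile
from .isolevel import compute_thresholds, extract_search_band, iso_level_map
from .phantoms import Phantom, make_manual_init
from .preprocess import TVParams, gradient_magnitude, weighted_tv_flow

__all__ = ["proposed_initial_contour", "segment", "segment_phantom",
           "run_pipeline"]


def proposed_initial_contour(
    image,
    lam: float = 0.05,
    n_levels: int = 24,
    n_sigma: int = 1,
    m: int = 360,
    min_run: int = 5,
    max_gap: float = 3.0,
    tv_params: TVParams | None = None,
    return_intermediates: bool = False,
):
    """Derive the radial max-gradient initial contour from a raw image.

    Steps: weighted-TV smoothing at fidelity weight ``lam``; iso-level
    thresholding into ``n_levels`` levels; extraction of the dense nested
    search band; ``m`` radial rays from the innermost-contour centroid kept
    at their maximum-gradient crossings; statistical clipping at
    ``n_sigma`` sample standard deviations.
    """
    if tv_params is None:
        tv_params = TVParams(lam=lam)
    smoothed = weighted_tv_flow(image, tv_params)
    grad = gradient_magnitude(smoothed)
    thresholds = compute_thresholds(smoothed, n_levels)
    iso = iso_level_map(smoothed, thresholds)
    band = extract_search_band(iso, min_run=min_run, max_gap=max_gap)
    profile = clip_profile(radial_profile(band, grad, m=m), n=n_sigma)
    contour = profile_to_contour(profile)
    if return_intermediates:
        return contour, dict(smoothed=smoothed, grad=grad, thresholds=thresholds,
                             iso=iso, band=band, profile=profile)
    return contour


def segment(image, init: Contour, model: str = "chanvese", params=None,
            fill_holes: bool = False):
    """Propagate an initial contour to a final mask with the chosen model.

    Returns ``(mask, phi, stats, log)`` where ``stats`` holds the plain
    region means of the final binary partition (the recovered c1 and c2).
    """
    a = np.asarray(image, dtype=float)
    phi0 = init_levelset(init, a.shape)
    if model == "chanvese":
        phi, _, log = evolve_chan_vese(a, phi0, params or ChanVeseParams())
    elif model == "spf":
        phi, _, log = evolve_sbgfrls(a, phi0, params or SPFParams())
    else:
        raise ValueError("model must be 'chanvese' or 'spf'")
    mask = mask_from_levelset(phi, fill_holes=fill_holes)
    stats = RegionStats(c1=float(a[mask].mean()), c2=float(a[~mask].mean()))
    return mask, phi, stats, log


def run_pipeline(image_path, config=None, out_dir=None, manual_csv=None):
    """Run the whole pipeline on an image file and write every artifact.

    Writes, under ``out_dir`` (default: the config's ``out_dir``):
    ``smoothed.tif``, ``band_overlay.png``, ``init.csv``, ``mask.png``,
    ``descriptors.csv`` and — when ``manual_csv`` names a second (manual)
    initial contour — ``pair.json`` comparing the two final segmentations.
    Every parameter, defaults included, is logged.  Returns a dict of
    artifact paths.
    """
    import json
    import logging
    from pathlib import Path

    from . import io as mio
    from .metrics import compare_pair
    from .shapedesc import describe

    log = logging.getLogger("mamseg.pipeline")
    if config is None:
        config = mio.RunConfig()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run_pipeline config: %s", config)

    img = mio.read_image(image_path)
    contour, inter = proposed_initial_contour(
        img, lam=config.lam, n_levels=config.n_levels, n_sigma=config.n_sigma,
        m=config.rays, return_intermediates=True)

    artifacts = {}
    mio.write_image(inter["smoothed"], out / "smoothed.tif")
    artifacts["smoothed"] = out / "smoothed.tif"
    overlay = np.clip(0.6 * img + 0.4 * inter["band"].mask, 0, 1)
    mio.write_image(overlay, out / "band_overlay.png")
    artifacts["band_overlay"] = out / "band_overlay.png"
    mio.write_contour_csv(contour, out / "init.csv")
    artifacts["init"] = out / "init.csv"

    params = (ChanVeseParams(mu=config.mu, nu=config.nu, lam1=config.lam1,
                             lam2=config.lam2) if config.model == "chanvese"
              else SPFParams(alpha=config.alpha))
    mask, _, stats, _ = segment(img, contour, model=config.model,
                                params=params, fill_holes=config.fill_holes)
    mio.write_mask_png(mask, out / "mask.png")
    artifacts["mask"] = out / "mask.png"
    desc = describe(mask)
    mio.write_descriptors_csv(desc, out / "descriptors.csv")
    artifacts["descriptors"] = out / "descriptors.csv"
    log.info("model=%s c1=%.4f c2=%.4f", config.model, stats.c1, stats.c2)

    if manual_csv is not None:
        manual = mio.read_contour_csv(manual_csv)
        mask_m, _, _, _ = segment(img, manual, model=config.model,
                                  params=params, fill_holes=config.fill_holes)
        pair = compare_pair(mask_m, mask, describe(mask_m), desc)
        with open(out / "pair.json", "w") as fh:
            json.dump(pair.__dict__, fh, indent=2)
        artifacts["pair"] = out / "pair.json"
    return artifacts


def segment_phantom(phantom: Phantom, model: str = "chanvese", params=None,
                    init: str = "proposed", dilation: float = 12.0,
                    **init_kw) -> np.ndarray:
    """Segment a phantom image from either initialization; returns the mask."""
    if init == "proposed":
        c = proposed_initial_contour(phantom.image, **init_kw)
    elif init == "manual":
        c = make_manual_init(phantom.truth_contour, dilation,
                             shape=phantom.image.shape)
    else:
        raise ValueError("init must be 'proposed' or 'manual'")
    mask, _, _, _ = segment(phantom.image, c, model=model, params=params)
    return mask
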