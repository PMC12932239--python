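"""Seed localization in CT-like volumes: thresholding followed by Gaussian
mixture regression (intensity-weighted EM) of the seed centers.

Above-threshold voxels become sample points weighted by their intensity; an
isotropic shared-variance Gaussian mixture with one component per expected
seed is fitted by expectation-maximization, initialized at the strongest
mutually non-adjacent local intensity maxima (deterministic — no random
restarts)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dose import DoseGrid

__all__ = ["LocalizationResult", "localize_seeds"]


@dataclass
class LocalizationResult:
    centers: np.ndarray          # (n, 3) world coordinates, lexicographically sorted
    weights: np.ndarray          # mixing proportions, same order as centers
    sigma_mm: float              # shared isotropic component std
    converged: bool
    iterations: int


def _otsu_threshold(values: np.ndarray) -> float:
    """Otsu's method on a 256-bin histogram (maximal between-class variance)."""
    hist, edges = np.histogram(values, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    between[~np.isfinite(between)] = -1.0
    return float(centers[int(np.argmax(between))])


def _init_centers(volume: DoseGrid, above: np.ndarray, n: int,
                  min_sep_vox: int = 2) -> np.ndarray:
    """Strongest mutually non-adjacent local maxima of the masked volume."""
    v = np.where(above, volume.values, -np.inf)
    footprint = np.ones((3, 3, 3), dtype=bool)
    is_max = (ndimage.maximum_filter(v, footprint=footprint) == v) & above
    idx = np.argwhere(is_max)
    order = np.argsort(-v[tuple(idx.T)], kind="stable")
    idx = idx[order]
    chosen: list[np.ndarray] = []
    for i in idx:
        if all(np.max(np.abs(i - c)) > min_sep_vox for c in chosen):
            chosen.append(i)
        if len(chosen) == n:
            break
    if len(chosen) < n:  # pad with remaining strongest maxima
        for i in idx:
            if not any(np.array_equal(i, c) for c in chosen):
                chosen.append(i)
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise ValueError("fewer local maxima than requested components")
    ijk = np.array(chosen, dtype=float)
    return volume.origin + ijk * volume.spacing


def localize_seeds(volume: DoseGrid, n_seeds: int, threshold_mode="otsu",
                   rng_seed: int = 0, max_iter: int = 200,
                   tol: float = 1e-6) -> LocalizationResult:
    """Estimate ``n_seeds`` seed centers from an intensity volume.

    ``threshold_mode`` is ``"otsu"`` or a fixed intensity value.  The EM fit
    is fully deterministic; ``rng_seed`` is accepted for interface stability
    and reserved for tie-breaking.
    """
    del rng_seed
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    vals = volume.values
    if float(vals.max()) <= float(vals.min()):
        raise ValueError("constant volume: nothing to localize")
    thr = _otsu_threshold(vals.ravel()) if threshold_mode == "otsu" else float(threshold_mode)
    above = vals > thr
    if int(above.sum()) < n_seeds:
        raise ValueError("fewer above-threshold voxels than components")

    idx = np.argwhere(above)
    x = volume.origin + idx * volume.spacing     # (m, 3) sample points
    w = vals[above].astype(float)                # intensity weights
    w = w / w.sum()
    mu = _init_centers(volume, above, n_seeds)
    pi = np.full(n_seeds, 1.0 / n_seeds)
    sigma2 = float(np.mean(volume.spacing) ** 2)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = np.sum((x[:, None, :] - mu[None, :, :]) ** 2, axis=2)  # (m, k)
        log_r = np.log(pi)[None, :] - d2 / (2.0 * sigma2)
        log_r -= log_r.max(axis=1, keepdims=True)
        r = np.exp(log_r)
        r /= r.sum(axis=1, keepdims=True)
        wr = w[:, None] * r                                          # (m, k)
        nk = wr.sum(axis=0)
        mu_new = (wr.T @ x) / nk[:, None]
        sigma2_new = float(np.sum(wr * np.sum((x[:, None, :] - mu_new[None, :, :]) ** 2, axis=2))
                           / (3.0 * wr.sum()))
        sigma2_new = max(sigma2_new, 1e-6)
        pi = nk / nk.sum()
        shift = float(np.max(np.linalg.norm(mu_new - mu, axis=1)))
        mu, sigma2 = mu_new, sigma2_new
        if shift < tol:
            converged = True
            break

    order = np.lexsort((mu[:, 2], mu[:, 1], mu[:, 0]))
    return LocalizationResult(centers=mu[order], weights=pi[order],
                              sigma_mm=float(np.sqrt(sigma2)),
                              converged=converged, iterations=it)
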