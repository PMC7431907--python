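"""T1 intensity-based tissue segmentation via localized Gaussian mixtures.

Scanner inhomogeneity makes a single global intensity model unreliable,
so the classifier fits a three-component 1D Gaussian mixture (CSF, GM,
WM, ordered by mean) to the masked intensity histogram of overlapping
local blocks, and classifies each voxel under parameters interpolated
from the surrounding block centres.  A global mixture — initialized from
intensity tertiles — seeds every block fit, and a block whose data
cannot support a component keeps the global parameters for it, so the
CSF/GM/WM correspondence never drifts inside blocks that lack a class.

Ventricular CSF is then separated from sulcal CSF by seeded connected
components, honouring the manual-relabelling convention: only CSF
components that contain a seed become vCSF, and non-CSF voxels inside
the ventricular compartment (e.g. choroid plexus) are never smoothed
into it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import SegmentationConfig
from .core_io import LabelVolume, Volume3D, raw_tissue_scheme
from .parcellation import SupratentorialMask

_STRUCT26 = np.ones((3, 3, 3), bool)


# ---------------------------------------------------------------------------
# 1D weighted EM
# ---------------------------------------------------------------------------

def _em_1d(centers: np.ndarray, weights: np.ndarray, init: np.ndarray,
           max_iter: int, tol: float, sd_floor: float) -> tuple[np.ndarray, int]:
    """Weighted EM for a K-component 1D Gaussian mixture on binned data.

    ``init`` is (K, 3): mean, sd, weight rows.  Returns parameters sorted
    by mean and the iteration count.  A component whose responsibility
    mass collapses keeps its previous (ultimately: initial) mean and sd.
    """
    mu = init[:, 0].astype(float).copy()
    sd = np.maximum(init[:, 1].astype(float), sd_floor)
    w = np.maximum(init[:, 2].astype(float), 1e-12)
    w = w / w.sum()
    n = float(weights.sum())

    prev_ll = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space for stability
        logp = (np.log(w)[:, None]
                - np.log(sd)[:, None]
                - 0.5 * np.log(2 * np.pi)
                - 0.5 * ((centers[None, :] - mu[:, None]) / sd[:, None]) ** 2)
        mx = logp.max(axis=0)
        norm = mx + np.log(np.exp(logp - mx).sum(axis=0))
        resp = np.exp(logp - norm)
        ll = float((weights * norm).sum())

        # M-step
        rk = resp * weights
        mass = rk.sum(axis=1)
        ok = mass > 1e-8 * n
        w = np.where(ok, mass / n, 1e-12)
        w = w / w.sum()
        new_mu = np.where(ok, rk @ centers / np.maximum(mass, 1e-300), mu)
        var = (rk @ centers ** 2) / np.maximum(mass, 1e-300) - new_mu ** 2
        new_sd = np.where(ok, np.sqrt(np.maximum(var, sd_floor ** 2)), sd)
        mu, sd = new_mu, np.maximum(new_sd, sd_floor)

        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll

    order = np.argsort(mu)
    return np.stack([mu[order], sd[order], w[order]], axis=1), it


def fit_gaussian_mixture_1d(samples: np.ndarray, n_components: int = 3,
                            init: np.ndarray | None = None,
                            config: SegmentationConfig | None = None
                            ) -> np.ndarray:
    """Fit a 1D Gaussian mixture to raw samples via a binned EM.

    Returns (K, 3) parameters: (mean, sd, weight) rows ordered by mean.
    Initialization defaults to equal-count intensity tertiles (quantile
    groups), which makes the fit equivariant under positive affine
    intensity transforms.  Raises on a near-constant histogram.
    """
    config = config or SegmentationConfig()
    x = np.asarray(samples, float).ravel()
    lo, hi = float(x.min()), float(x.max())
    span = hi - lo
    if span <= 0 or np.std(x) < 1e-6 * span:
        raise ValueError("degenerate histogram: near-constant intensity")
    counts, edges = np.histogram(x, bins=config.n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])

    if init is None:
        qs = np.quantile(x, np.linspace(0, 1, n_components + 1))
        init = np.empty((n_components, 3))
        for k in range(n_components):
            grp = x[(x >= qs[k]) & (x <= qs[k + 1])]
            if grp.size == 0:
                grp = np.array([0.5 * (qs[k] + qs[k + 1])])
            init[k] = (grp.mean(), max(grp.std(), 1e-4 * span),
                       grp.size / x.size)

    # the floor must cover one bin width: binned EM cannot resolve scales
    # below the bin spacing, and a spike half a bin from a tiny-sd
    # component would otherwise starve it
    sd_floor = max(1e-4 * span, span / config.n_bins)
    params, _ = _em_1d(centers.astype(float), counts.astype(float), init,
                       config.max_iter, config.tol, sd_floor)
    return params


# ---------------------------------------------------------------------------
# local model
# ---------------------------------------------------------------------------

@dataclass
class LocalGaussianModel:
    """Per-block CSF/GM/WM Gaussian parameters on a regular block grid.

    ``params`` has shape (nx, ny, nz, 3 classes, 3) holding (mean, sd,
    weight); ``origin``/``stride`` place block centres in voxel index
    space.  ``global_params`` is the whole-mask fallback fit.
    """

    params: np.ndarray
    origin: np.ndarray
    stride: np.ndarray
    global_params: np.ndarray
    intensity_span: float

    CLASS_ORDER = ("CSF", "GM", "WM")

    def interpolate(self, voxel_idx: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated (N, 3 classes, 3) parameters."""
        g = (np.asarray(voxel_idx, float) - self.origin) / self.stride
        nb = np.asarray(self.params.shape[:3])
        g = np.clip(g, 0, nb - 1).T  # (3, N)
        out = np.empty((g.shape[1], 3, 3))
        for k in range(3):
            for p in range(3):
                out[:, k, p] = ndimage.map_coordinates(
                    self.params[..., k, p], g, order=1, mode="nearest")
        return out


def fit_local_gaussian_model(t1: Volume3D, mask: SupratentorialMask,
                             config: SegmentationConfig | None = None
                             ) -> LocalGaussianModel:
    """Fit the localized histogram model over the supratentorial mask."""
    config = config or SegmentationConfig()
    m = mask.mask
    n_masked = int(m.sum())
    if n_masked < config.min_mask_voxels:
        raise ValueError(f"masked voxel count {n_masked} below minimum "
                         f"{config.min_mask_voxels}")
    x_all = t1.voxels[m]
    span = float(x_all.max() - x_all.min())
    glob = fit_gaussian_mixture_1d(x_all, config=config)

    bs = config.block_size
    stride = max(int(round(bs * (1 - config.overlap))), 1)
    shape = np.asarray(t1.shape)
    n_blocks = np.maximum((shape - 1) // stride + 1, 1)
    origin = np.full(3, stride // 2)

    params = np.tile(glob, (*n_blocks, 1, 1)).astype(float)
    half = bs // 2
    for ix in range(n_blocks[0]):
        for iy in range(n_blocks[1]):
            for iz in range(n_blocks[2]):
                c = origin + np.array([ix, iy, iz]) * stride
                sl = tuple(slice(max(cc - half, 0), cc + half)
                           for cc in c)
                bm = m[sl]
                if bm.sum() < config.min_block_voxels:
                    continue
                bx = t1.voxels[sl][bm]
                bspan = float(bx.max() - bx.min())
                if bspan < 1e-6 * max(span, 1e-12):
                    continue
                counts, edges = np.histogram(bx, bins=config.n_bins)
                centers = 0.5 * (edges[:-1] + edges[1:])
                sd_floor = max(1e-4 * max(span, 1e-12),
                               bspan / config.n_bins)
                fitted, _ = _em_1d(centers, counts.astype(float), glob,
                                   config.max_iter, config.tol, sd_floor)
                params[ix, iy, iz] = fitted

    return LocalGaussianModel(params=params, origin=origin.astype(float),
                              stride=np.full(3, float(stride)),
                              global_params=glob, intensity_span=span)


def classify_tissue(t1: Volume3D, model: LocalGaussianModel,
                    mask: SupratentorialMask) -> LabelVolume:
    """Assign CSF/GM/WM by maximum weighted Gaussian density per voxel.

    All CSF is initially labelled sulcal (sCSF); ventricular relabelling
    is a separate, seeded step.  Posterior ties break toward the class
    with the larger local weight, then the lower mean.
    """
    scheme = raw_tissue_scheme()
    labels = np.zeros(t1.shape, dtype=np.int16)
    idx = np.argwhere(mask.mask)
    if len(idx) == 0:
        return LabelVolume(labels, scheme, mask.affine)
    x = t1.voxels[mask.mask]
    p = model.interpolate(idx)  # (N, 3, 3)
    mu, sd, w = p[..., 0], np.maximum(p[..., 1], 1e-12), np.maximum(p[..., 2], 1e-300)
    logd = (np.log(w) - np.log(sd)
            - 0.5 * ((x[:, None] - mu) / sd) ** 2)

    best = np.argmax(logd, axis=1)
    # deterministic tie-break: larger weight, then lower mean
    top = logd[np.arange(len(x)), best]
    ties = (np.isclose(logd, top[:, None], rtol=0, atol=1e-12)
            .sum(axis=1) > 1)
    if ties.any():
        for i in np.flatnonzero(ties):
            cand = np.flatnonzero(np.isclose(logd[i], top[i], rtol=0,
                                             atol=1e-12))
            order = sorted(cand, key=lambda k: (-w[i, k], mu[i, k]))
            best[i] = order[0]

    class_label = np.array([scheme["sCSF"], scheme["GM"], scheme["WM"]],
                           dtype=np.int16)
    labels[mask.mask] = class_label[best]
    return LabelVolume(labels, scheme, mask.affine)


def relabel_ventricular_csf(tissue: LabelVolume, seeds) -> LabelVolume:
    """Promote seeded CSF connected components (26-connectivity) to vCSF.

    ``seeds`` is a binary LabelVolume, a boolean array on the study grid,
    or a list of world-mm points.  Every seed must land on a CSF voxel;
    offending seeds are reported.  Interior non-CSF voxels (choroid
    plexus-like islands) are left untouched.
    """
    scheme = tissue.scheme
    labels = tissue.labels.copy()
    csf = labels == scheme["sCSF"]

    if isinstance(seeds, LabelVolume):
        seed_mask = seeds.labels > 0
    elif isinstance(seeds, np.ndarray) and seeds.dtype == bool \
            and seeds.shape == labels.shape:
        seed_mask = seeds
    else:
        seed_mask = np.zeros(labels.shape, bool)
        inv = np.linalg.inv(tissue.affine)
        bad = []
        for pt in np.atleast_2d(np.asarray(seeds, float)):
            ijk = np.rint(inv[:3, :3] @ pt + inv[:3, 3]).astype(int)
            if np.any(ijk < 0) or np.any(ijk >= np.asarray(labels.shape)):
                bad.append(pt.tolist())
                continue
            seed_mask[tuple(ijk)] = True
        if bad:
            raise ValueError(f"seeds outside the volume: {bad}")

    if not seed_mask.any():
        raise ValueError("at least one ventricle seed is required")
    off = seed_mask & ~csf
    if off.any():
        raise ValueError("seeds on non-CSF voxels at indices "
                         f"{np.argwhere(off)[:5].tolist()}")

    comp, _ = ndimage.label(csf, structure=_STRUCT26)
    seeded = np.unique(comp[seed_mask & csf])
    vent = np.isin(comp, seeded[seeded > 0])
    labels[vent] = scheme["vCSF"]
    return LabelVolume(labels, scheme, tissue.affine)
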