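"""Shared fixtures: phantoms and pipeline runs reused across the suite.

Heavy objects are session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

from sabrevol import PhantomSpec, generate_phantom, run_study
from sabrevol.phantom import LesionLoad, PhantomTruth, generate_anatomy


@pytest.fixture(scope="session")
def phantom_default():
    """Default 96³ phantom at the standard noise level (seed 7)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def phantom_clean():
    """Noise-free default 96³ phantom (seed 5)."""
    return generate_phantom(PhantomSpec(seed=5, noise_sd=0.0))


@pytest.fixture(scope="session")
def anatomy_clean():
    """Lesion-free, noise-free 96³ phantom (mirror-symmetric anatomy)."""
    spec = PhantomSpec(seed=2, noise_sd=0.0, lesion_load=LesionLoad.none())
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def result_default(phantom_default):
    bundle, _ = phantom_default
    return run_study(bundle)


@pytest.fixture(scope="session")
def result_clean(phantom_clean):
    bundle, _ = phantom_clean
    return run_study(bundle)


@pytest.fixture(scope="session")
def result_anatomy(anatomy_clean):
    bundle, _ = anatomy_clean
    return run_study(bundle)


def random_mask_pair(rng: np.random.Generator, shape=(24, 24, 24),
                     p_wmh=0.08, p_vcsf=0.04):
    """Random lesion / ventricle mask pair for splitter oracle tests."""
    wmh = rng.random(shape) < p_wmh
    vcsf = (rng.random(shape) < p_vcsf) & ~wmh
    if not vcsf.any():
        vcsf[tuple(rng.integers(0, s) for s in shape)] = True
        vcsf &= ~wmh
        if not vcsf.any():
            vcsf[0, 0, 0] = True
            wmh[0, 0, 0] = False
    return wmh, vcsf


def bfs_periventricular_oracle(wmh: np.ndarray, vcsf: np.ndarray) -> np.ndarray:
    """Brute-force flood fill: a lesion voxel is periventricular iff some
    voxel of its 26-connected component touches ventricular CSF."""
    shape = wmh.shape
    wmh_set = {tuple(i) for i in np.argwhere(wmh)}
    vcsf_set = {tuple(i) for i in np.argwhere(vcsf)}
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]

    def neighbours(p):
        for o in offsets:
            q = (p[0] + o[0], p[1] + o[1], p[2] + o[2])
            if all(0 <= q[d] < shape[d] for d in range(3)):
                yield q

    pv = np.zeros(shape, bool)
    seen = set()
    for start in list(wmh_set):
        if start in seen:
            continue
        comp, stack, touches = [], [start], False
        seen.add(start)
        while stack:
            p = stack.pop()
            comp.append(p)
            for q in neighbours(p):
                if q in vcsf_set:
                    touches = True
                if q in wmh_set and q not in seen:
                    seen.add(q)
                    stack.append(q)
        if touches:
            for p in comp:
                pv[p] = True
    return pv


def nearest_distance_oracle(wmh: np.ndarray, vcsf: np.ndarray,
                            spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Per-voxel exhaustive nearest-vCSF scan (world mm)."""
    sp = np.asarray(spacing, float)
    wpts = np.argwhere(wmh) * sp
    vpts = np.argwhere(vcsf) * sp
    out = np.full(wmh.shape, np.inf)
    for idx, p in zip(np.argwhere(wmh), wpts):
        out[tuple(idx)] = np.sqrt(((vpts - p) ** 2).sum(axis=1)).min()
    return out
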