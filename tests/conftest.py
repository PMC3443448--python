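"""Shared fixtures: phantoms, trained models, and full pipeline runs.

Session-scoped fixtures keep the expensive end-to-end artifacts shared
between the pipeline tests and the acceptance suite.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from diskseg import (
    PhantomSpec,
    PipelineConfig,
    evaluate_against_truth,
    make_spine_phantom,
    run_pipeline,
    train_model_for,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A compact 3-disk phantom for fast unit/integration tests."""
    return PhantomSpec(
        grid_shape=(40, 36, 96),
        spacing_mm=(1.0, 1.0, 1.0),
        n_disks=3,
        cobb_like_angle_deg=15.0,
        noise_sigma=0.03,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_spine_phantom(small_spec)


@pytest.fixture(scope="session")
def default_phantom():
    """The evaluation phantom: 5 disks, 30-degree curve, medic contrast."""
    return make_spine_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def trained_model(default_config):
    return train_model_for(default_config)


@pytest.fixture(scope="session")
def default_pipeline_run(default_phantom, trained_model, default_config):
    """Full reconstruction of the default phantom plus its truth evaluation."""
    result = run_pipeline(default_phantom.volume, trained_model, default_config)
    report = evaluate_against_truth(default_phantom, result)
    return default_phantom, result, report


def flood_oracle(image: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Independent brute-force ordered flooding (frontier scan, no heap).

    At every step the whole frontier — undecided pixels 4-adjacent to a
    decided pixel — is scanned and the pixel with the smallest
    (gray value, row, col) key is decided: it joins the unique neighbouring
    basin, or becomes a watershed-line pixel (-1) when zero or several basins
    touch it.  Semantically equivalent to, but structurally independent of,
    the production flooding.
    """
    img = np.asarray(image, dtype=float)
    out = np.asarray(markers).astype(np.int64).copy()
    h, w = img.shape
    while True:
        best = None
        for r in range(h):
            for c in range(w):
                if out[r, c] != 0:
                    continue
                adjacent = False
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and out[rr, cc] != 0:
                        adjacent = True
                        break
                if not adjacent:
                    continue
                key = (img[r, c], r, c)
                if best is None or key < best:
                    best = key
        if best is None:
            break
        _, r, c = best
        labels = set()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and out[rr, cc] > 0:
                labels.add(out[rr, cc])
        out[r, c] = labels.pop() if len(labels) == 1 else -1
    return out


def regional_minima(image: np.ndarray) -> np.ndarray:
    """Label the regional minima of a 2D image by plateau flood fill.

    A regional minimum is a connected plateau (8-connectivity) none of whose
    outside neighbours is strictly lower.  Independent of any morphology
    library; used as the oracle for minima imposition.
    """
    from scipy import ndimage as ndi

    img = np.asarray(image, dtype=float)
    out = np.zeros(img.shape, dtype=np.int64)
    label = 0
    visited = np.zeros(img.shape, dtype=bool)
    h, w = img.shape
    for r0 in range(h):
        for c0 in range(w):
            if visited[r0, c0]:
                continue
            v = img[r0, c0]
            # flood the plateau at value v
            plateau = [(r0, c0)]
            visited[r0, c0] = True
            members = []
            is_min = True
            while plateau:
                r, c = plateau.pop()
                members.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == 0 and dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if not (0 <= rr < h and 0 <= cc < w):
                            continue
                        if img[rr, cc] == v:
                            if not visited[rr, cc]:
                                visited[rr, cc] = True
                                plateau.append((rr, cc))
                        elif img[rr, cc] < v:
                            is_min = False
            if is_min:
                label += 1
                for r, c in members:
                    out[r, c] = label
    return out
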