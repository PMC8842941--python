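import numpy as np
import pytest

from ltsq.synthetic import SlideSpec, generate_slide


@pytest.fixture(scope="session")
def small_slide():
    """One rendered slide with mixed-rank objects, reused across tests."""
    spec = SlideSpec(
        height=500,
        width=500,
        n_definite=6,
        n_probable=4,
        n_possible=3,
        n_background=4,
        seed=42,
    )
    return generate_slide(spec)


@pytest.fixture(scope="session")
def training_patches():
    """~200 labeled patches from six small synthetic slides (no background
    blobs, so positives and negatives are cleanly separable)."""
    from ltsq.detector import extract_patches

    patches = []
    for seed in range(6):
        r = generate_slide(
            SlideSpec(
                height=500,
                width=500,
                n_definite=8,
                n_probable=5,
                n_possible=4,
                n_background=0,
                seed=seed,
            )
        )
        patches += extract_patches(r.image, r.annotations, n_negatives=17, seed=seed)
    return patches


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
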