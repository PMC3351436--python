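"""Test-only helpers independent of the package internals."""

import numpy as np


def rigid_transform_frames(coords, seed=0):
    """Apply an independent random rotation+translation to every frame."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-50, 50, size=3)
        out[f] = coords[f] @ rot.T + shift
    return out
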