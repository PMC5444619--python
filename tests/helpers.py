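"""Shared test utilities."""

import numpy as np

from atherosim.lattice import LUMEN, WALL, ArteryLattice


def ec_shell_closed(lat: ArteryLattice) -> bool:
    """Every wall-material voxel face-adjacent to lumen is EC."""
    cls = lat.patch_class
    lumen = cls == LUMEN
    ok = True
    for axis, d in ((0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)):
        shifted = np.roll(lumen, d, axis=axis)
        idx = [slice(None)] * 3
        idx[axis] = 0 if d > 0 else -1
        shifted[tuple(idx)] = False
        ok &= not np.any(shifted & (cls == WALL))
    return bool(ok)
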