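"""Array allocation helper: plain numpy or fork-shareable buffers.

Shared arrays are backed by ``multiprocessing.sharedctypes.RawArray`` so that
worker processes forked after allocation see the same memory.  Serial runs
use ordinary numpy arrays.
"""

import numpy as np
from multiprocessing import sharedctypes

_CTYPES = {"float64": "d", "int64": "q", "int32": "i"}


def zeros(shape, dtype, shared=False):
    if not shared:
        return np.zeros(shape, dtype=dtype)
    n = int(np.prod(shape))
    raw = sharedctypes.RawArray(_CTYPES[np.dtype(dtype).name], n)
    arr = np.frombuffer(raw, dtype=dtype).reshape(shape)
    return arr
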