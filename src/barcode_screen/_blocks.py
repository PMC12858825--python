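"""Block-averaging over p x p windows, with trailing partial windows
averaged over the pixels actually present (no padding bias)."""

from __future__ import annotations

import numpy as np


def block_mean(arr: np.ndarray, p: int) -> np.ndarray:
    """Mean over p x p tiles of a 2-D array; output shape (ceil(m/p), ceil(n/p)).

    Trailing windows that do not fill a full tile are averaged over the
    available pixels only.
    """
    if p == 1:
        return np.asarray(arr, dtype=float)
    m, n = arr.shape
    row_idx = np.arange(0, m, p)
    col_idx = np.arange(0, n, p)
    s = np.add.reduceat(np.add.reduceat(np.asarray(arr, dtype=float), row_idx, axis=0),
                        col_idx, axis=1)
    rows = np.minimum(row_idx + p, m) - row_idx
    cols = np.minimum(col_idx + p, n) - col_idx
    return s / np.outer(rows, cols)
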