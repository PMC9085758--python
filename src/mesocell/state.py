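"""Flat state-vector layout shared by all concentration-based modules.

Every (compartment, entity) concentration pool registers a named block of
the global state vector; modules hold flat indices into it and return
dc/dt contributions of full length.  This keeps the embedded-pair stepping
and error bookkeeping a handful of vectorized array operations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["StateLayout"]


class StateLayout:
    def __init__(self):
        self._blocks: dict[str, tuple[slice, tuple[int, ...]]] = {}
        self.size = 0

    def add(self, name: str, shape: int | tuple[int, ...]) -> slice:
        if name in self._blocks:
            raise ValueError(f"block {name!r} already registered")
        if isinstance(shape, int):
            shape = (shape,)
        n = int(np.prod(shape))
        sl = slice(self.size, self.size + n)
        self._blocks[name] = (sl, shape)
        self.size += n
        return sl

    def __contains__(self, name: str) -> bool:
        return name in self._blocks

    def block_names(self) -> list[str]:
        return list(self._blocks)

    def slice_of(self, name: str) -> slice:
        return self._blocks[name][0]

    def shape_of(self, name: str) -> tuple[int, ...]:
        return self._blocks[name][1]

    def indices(self, name: str) -> np.ndarray:
        sl, _ = self._blocks[name]
        return np.arange(sl.start, sl.stop)

    def view(self, y: np.ndarray, name: str) -> np.ndarray:
        sl, shape = self._blocks[name]
        return y[sl].reshape(shape)

    def zeros(self) -> np.ndarray:
        return np.zeros(self.size, dtype=float)
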