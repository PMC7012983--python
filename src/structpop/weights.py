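"""Output weight functions w : Omega -> R^k and weight families.

Population outputs are weighted integrals N_i = int w_i(x) m(dx) of the
population measure.  Reducibility analysis additionally needs the
derivatives w_i'; these are supplied analytically where available, with a
central finite difference (step 1e-6 * scale) as documented fallback.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .core import ModelError

_FD_STEP = 1e-6


class Weight:
    """A scalar output weight function with (optional) derivative."""

    def __init__(self, fn: Callable, dfn: Callable | None = None, name: str = ""):
        self.fn = fn
        self.dfn = dfn
        self.name = name or getattr(fn, "__name__", "w")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return np.asarray(self.fn(x), dtype=float) * np.ones_like(x)

    def d(self, x):
        x = np.asarray(x, dtype=float)
        if self.dfn is not None:
            return np.asarray(self.dfn(x), dtype=float) * np.ones_like(x)
        h = _FD_STEP * np.maximum(1.0, np.abs(x))
        return (self(x + h) - self(x - h)) / (2.0 * h)

    def __repr__(self):
        return f"Weight({self.name})"


#: ready-made weights used throughout the chemostat examples
w_one = Weight(lambda x: np.ones_like(x), lambda x: np.zeros_like(x), "1")
w_x = Weight(lambda x: x, lambda x: np.ones_like(x), "x")
w_x23 = Weight(
    lambda x: x ** (2.0 / 3.0), lambda x: (2.0 / 3.0) * x ** (-1.0 / 3.0), "x**(2/3)"
)


class WeightFamily:
    """An ordered family of k output weights."""

    def __init__(self, components: Sequence[Weight]):
        self.components = list(components)

    def __len__(self):
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    def __getitem__(self, i):
        return self.components[i]

    def values(self, x_grid) -> np.ndarray:
        """Matrix of shape (k, n_x)."""
        x = np.asarray(x_grid, dtype=float)
        return np.stack([w(x) for w in self.components])

    def derivs(self, x_grid) -> np.ndarray:
        x = np.asarray(x_grid, dtype=float)
        return np.stack([w.d(x) for w in self.components])

    def check_rank(self, x_grid, rtol: float = 1e-10) -> None:
        """Raise if the components are linearly dependent on the grid."""
        W = self.values(x_grid)
        norms = np.linalg.norm(W, axis=1)
        if np.any(norms == 0):
            bad = self.components[int(np.argmin(norms))].name
            raise ModelError(f"weight component {bad!r} vanishes on the grid")
        Wn = W / norms[:, None]
        for i in range(1, len(self.components)):
            sub = Wn[: i + 1]
            s = np.linalg.svd(sub, compute_uv=False)
            if s[-1] < rtol * s[0]:
                raise ModelError(
                    f"weight component {self.components[i].name!r} is linearly "
                    "dependent on the preceding components on this grid"
                )

    @property
    def names(self):
        return [w.name for w in self.components]
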