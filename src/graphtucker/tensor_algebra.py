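"""Mode-wise primitives for third-order tensors.

The expression data live in a dense nonnegative 3-way array indexed
``(y, x, gene)``.  Everything the optimizer and the component builder need
reduces to three operations: mode-n matricization (unfolding), its inverse
(folding), and the n-mode product of a tensor with a matrix.  Modes are
0-based: mode 0 is the y axis, mode 1 the x axis, mode 2 the gene axis.

Unfolding convention: ``unfold(t, mode)`` has one row per index of ``mode``
and the remaining modes cycle in increasing order along the columns
(C-order reshape after moving ``mode`` to the front).  ``fold`` inverts it
exactly; the multiplicative-update algebra in :mod:`graphtucker.optimizer`
shares the same convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["unfold", "fold", "nmode_product", "tucker_reconstruct"]


def _check_mode(mode: int) -> None:
    if mode not in (0, 1, 2):
        raise ValueError(f"mode must be 0, 1 or 2, got {mode!r}")


def unfold(t: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` matricization of a 3-way tensor.

    Returns an array of shape ``(t.shape[mode], prod(other dims))`` whose
    columns run over the remaining modes in increasing order.
    """
    _check_mode(mode)
    t = np.asarray(t)
    if t.ndim != 3:
        raise ValueError(f"expected a 3-way tensor, got ndim={t.ndim}")
    return np.moveaxis(t, mode, 0).reshape(t.shape[mode], -1)


def fold(m: np.ndarray, mode: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given ``shape``."""
    _check_mode(mode)
    full = [shape[mode]] + [s for i, s in enumerate(shape) if i != mode]
    return np.moveaxis(np.asarray(m).reshape(full), 0, mode)


def nmode_product(t: np.ndarray, m: np.ndarray, mode: int) -> np.ndarray:
    """n-mode product ``t ×_mode m``: contract mode ``mode`` of ``t`` with
    the columns of ``m``.

    ``m`` may be a dense array or a scipy sparse matrix; the result replaces
    the size of ``mode`` by ``m.shape[0]``.
    """
    _check_mode(mode)
    t = np.asarray(t)
    if m.shape[1] != t.shape[mode]:
        raise ValueError(
            f"matrix has {m.shape[1]} columns but tensor mode {mode} has "
            f"size {t.shape[mode]}"
        )
    shape = list(t.shape)
    shape[mode] = m.shape[0]
    # sparse-friendly: act on the unfolding, then fold back
    return fold(m @ unfold(t, mode), mode, tuple(shape))


def tucker_reconstruct(
    core: np.ndarray, ay: np.ndarray, ax: np.ndarray, ag: np.ndarray
) -> np.ndarray:
    """Dense reconstruction ``T̂ = G ×0 Ay ×1 Ax ×2 Ag``.

    The core has shape ``(ry, rx, rg)`` and the factors ``(ny, ry)``,
    ``(nx, rx)``, ``(ng, rg)``; the result has shape ``(ny, nx, ng)`` and is
    nonnegative whenever all inputs are.
    """
    core = np.asarray(core)
    for mode, a in enumerate((ay, ax, ag)):
        if a.shape[1] != core.shape[mode]:
            raise ValueError(
                f"factor for mode {mode} has {a.shape[1]} columns, core "
                f"expects {core.shape[mode]}"
            )
    t = nmode_product(core, np.asarray(ay), 0)
    t = nmode_product(t, np.asarray(ax), 1)
    return nmode_product(t, np.asarray(ag), 2)
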