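"""Shared data containers for the (y, x, gene) tensor pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExpressionTensor", "MaskTensor", "RegionAnnotation"]


@dataclass
class ExpressionTensor:
    """Nonnegative spot-grid expression tensor.

    ``values`` is indexed ``(y, x, gene)``; ``gene_ids`` aligns to the gene
    axis; ``in_tissue`` is an optional (ny, nx) boolean map of capture spots
    that lie on tissue (grid positions with no spot are False).
    """

    values: np.ndarray
    gene_ids: list[str]
    in_tissue: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("expression tensor must be 3-way")
        if len(self.gene_ids) != self.values.shape[2]:
            raise ValueError("gene_ids length must match the gene axis")
        if self.values.size and self.values.min() < 0:
            raise ValueError("expression values must be nonnegative")
        if self.in_tissue is None:
            self.in_tissue = np.ones(self.values.shape[:2], dtype=bool)
        else:
            self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
            if self.in_tissue.shape != self.values.shape[:2]:
                raise ValueError("in_tissue map must be (ny, nx)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class MaskTensor:
    """Binary mask; 1 marks an observed (training) entry."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3-way")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("mask entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def density(self) -> float:
        return float(self.values.mean()) if self.values.size else 0.0


@dataclass
class RegionAnnotation:
    """A named tissue region as a binary (ny, nx) spot map."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("region mask must be (ny, nx)")

    @property
    def n_spots(self) -> int:
        return int(self.mask.sum())
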