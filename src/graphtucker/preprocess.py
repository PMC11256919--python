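"""From 10x-style spot count matrices to the (y, x, gene) tensor.

Visium arrays are hexagonally packed: odd array rows are offset by half a
spot and array columns advance by two, so row and column parity always
match.  Shifting odd rows by half a spot — y = array_row,
x = (array_col − array_row mod 2) / 2 — places every spot on a square
grid, after which counts are arranged into a 3-way tensor.  The standard
cleaning then applies: entries below 3 UMI are zeroed, genes with total
UMI below 4 are dropped, fully empty grid rows/columns are cropped, and
entries are log(1 + x) transformed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

from .containers import ExpressionTensor, MaskTensor, RegionAnnotation

__all__ = [
    "SpotTable",
    "read_visium",
    "hex_to_square",
    "build_tensor",
    "filter_counts",
    "crop_empty",
    "log_transform",
    "build_mask",
    "preprocess_pipeline",
    "load_annotations",
]


@dataclass
class SpotTable:
    """Spot-level counts with grid coordinates.

    ``counts`` is a sparse genes × spots matrix; ``array_row``/``array_col``
    are the platform's grid coordinates; ``grid`` is ``"visium-hex"`` or
    ``"square"``.
    """

    barcodes: list[str]
    array_row: np.ndarray
    array_col: np.ndarray
    in_tissue: np.ndarray
    counts: sp.csr_matrix
    gene_ids: list[str]
    grid: str = "visium-hex"

    def __post_init__(self) -> None:
        n = len(self.barcodes)
        if self.counts.shape != (len(self.gene_ids), n):
            raise ValueError("counts must be genes x spots")
        self.array_row = np.asarray(self.array_row, dtype=int)
        self.array_col = np.asarray(self.array_col, dtype=int)
        self.in_tissue = np.asarray(self.in_tissue, dtype=bool)


def read_visium(
    counts_mtx,
    features_tsv,
    barcodes_tsv,
    positions_csv,
    grid: str = "visium-hex",
) -> SpotTable:
    """Load a 10x-style triplet directory layout.

    ``positions_csv`` follows the tissue-positions dialect: barcode,
    in_tissue, array_row, array_col[, pixel coords] (header optional).
    """
    counts = sp.csr_matrix(mmread(str(counts_mtx)))
    feats = pd.read_csv(features_tsv, sep="\t", header=None)
    gene_ids = feats.iloc[:, 0].astype(str).tolist()
    barcodes = (
        pd.read_csv(barcodes_tsv, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    )
    if counts.shape != (len(gene_ids), len(barcodes)):
        raise ValueError(
            f"counts shape {counts.shape} does not match "
            f"{len(gene_ids)} features x {len(barcodes)} barcodes"
        )

    pos = pd.read_csv(positions_csv, header=None)
    if not str(pos.iloc[0, 1]).lstrip("-").isdigit():  # header row present
        pos = pos.iloc[1:].reset_index(drop=True)
    pos = pos.iloc[:, :4]
    pos.columns = ["barcode", "in_tissue", "array_row", "array_col"]
    pos = pos.set_index("barcode").loc[barcodes]
    return SpotTable(
        barcodes=barcodes,
        array_row=pos["array_row"].astype(int).to_numpy(),
        array_col=pos["array_col"].astype(int).to_numpy(),
        in_tissue=pos["in_tissue"].astype(int).to_numpy().astype(bool),
        counts=counts,
        gene_ids=gene_ids,
        grid=grid,
    )


def hex_to_square(spots: SpotTable) -> tuple[np.ndarray, np.ndarray]:
    """Square-grid (y, x) coordinates per spot.

    Visium hex layout: y = array_row, x = (array_col − array_row mod 2)/2.
    Square-grid input passes through unchanged.  The mapping must be
    injective over the table's spots.
    """
    if spots.grid == "square":
        y, x = spots.array_row.copy(), spots.array_col.copy()
    else:
        parity = spots.array_row % 2
        shifted = spots.array_col - parity
        bad = shifted % 2 != 0
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"spot {spots.barcodes[i]} violates Visium parity: "
                f"array_row={spots.array_row[i]}, array_col={spots.array_col[i]}"
            )
        y, x = spots.array_row.copy(), shifted // 2
    coords = set(zip(y.tolist(), x.tolist()))
    if len(coords) != len(y):
        raise ValueError("grid mapping is not injective: duplicate (y, x) spots")
    return y, x


def build_tensor(spots: SpotTable) -> tuple[ExpressionTensor, MaskTensor]:
    """Arrange counts into a (y, x, gene) tensor.

    Grid rows/columns containing no spots are dropped; the in-tissue map
    marks occupied positions.  The default mask marks nonzero entries
    (see :func:`build_mask` for the in-tissue alternative).
    """
    y, x = hex_to_square(spots)
    y = y - y.min()
    x = x - x.min()
    used_y = np.unique(y)
    used_x = np.unique(x)
    ymap = {v: i for i, v in enumerate(used_y)}
    xmap = {v: i for i, v in enumerate(used_x)}
    yy = np.array([ymap[v] for v in y])
    xx = np.array([xmap[v] for v in x])

    ny, nx, ng = len(used_y), len(used_x), len(spots.gene_ids)
    values = np.zeros((ny, nx, ng))
    in_tissue = np.zeros((ny, nx), dtype=bool)
    dense = np.asarray(spots.counts.todense(), dtype=float)  # genes x spots
    for j in range(len(spots.barcodes)):
        if in_tissue[yy[j], xx[j]]:
            raise ValueError(
                f"duplicate grid position ({yy[j]}, {xx[j]}) for spot "
                f"{spots.barcodes[j]}"
            )
        values[yy[j], xx[j], :] = dense[:, j]
        in_tissue[yy[j], xx[j]] = True

    t = ExpressionTensor(values, list(spots.gene_ids), in_tissue)
    return t, build_mask(t, mode="nonzero")


def build_mask(t: ExpressionTensor, mode: str = "nonzero") -> MaskTensor:
    """Observation mask.

    ``nonzero`` (default) treats only nonzero entries as observed —
    dropout zeros count as missing, which is what makes imputing complete
    expression meaningful.  ``in-tissue`` marks every gene at every
    occupied spot as observed.
    """
    if mode == "nonzero":
        m = (t.values > 0).astype(float)
    elif mode == "in-tissue":
        m = np.broadcast_to(
            t.in_tissue[:, :, None], t.values.shape
        ).astype(float).copy()
    else:
        raise ValueError(f"unknown mask mode {mode!r}")
    return MaskTensor(m)


def filter_counts(t: ExpressionTensor, entry_min: int = 3, gene_total_min: int = 4):
    """Zero entries below ``entry_min`` UMI, then drop genes whose total
    (after zeroing) is below ``gene_total_min``.  Returns the filtered
    tensor with its gene axis shrunk and identifiers updated."""
    values = t.values.copy()
    values[values < entry_min] = 0.0
    totals = values.sum(axis=(0, 1))
    keep = totals >= gene_total_min
    return ExpressionTensor(
        values[:, :, keep],
        [g for g, k in zip(t.gene_ids, keep) if k],
        t.in_tissue.copy(),
    )


def crop_empty(t: ExpressionTensor) -> ExpressionTensor:
    """Drop grid rows and columns with no in-tissue spot."""
    rows = t.in_tissue.any(axis=1)
    cols = t.in_tissue.any(axis=0)
    return ExpressionTensor(
        t.values[rows][:, cols, :], list(t.gene_ids), t.in_tissue[rows][:, cols]
    )


def log_transform(t: ExpressionTensor) -> ExpressionTensor:
    """Natural log(1 + x), elementwise; order-preserving on counts."""
    if t.values.size and t.values.min() < 0:
        raise ValueError("log transform requires nonnegative entries")
    return ExpressionTensor(np.log1p(t.values), list(t.gene_ids), t.in_tissue.copy())


def preprocess_pipeline(
    spots: SpotTable,
    entry_min: int = 3,
    gene_total_min: int = 4,
    mask_mode: str = "nonzero",
) -> tuple[ExpressionTensor, MaskTensor]:
    """Full cleaning pipeline: grid-shift → tensorize → entry threshold →
    gene filter → crop → log1p; the mask is built from the final tensor,
    so rerunning on the output is a no-op."""
    t, _ = build_tensor(spots)
    t = filter_counts(t, entry_min=entry_min, gene_total_min=gene_total_min)
    t = crop_empty(t)
    t = log_transform(t)
    return t, build_mask(t, mode=mask_mode)


def load_annotations(
    annotations_csv, spots: SpotTable, t: ExpressionTensor
) -> list[RegionAnnotation]:
    """Per-spot labels (CSV: barcode, label) to binary region maps on the
    cropped tensor grid.  Barcodes absent from the table are ignored."""
    df = pd.read_csv(annotations_csv)
    if df.shape[1] < 2:
        raise ValueError("annotations need barcode and label columns")
    df.columns = ["barcode", "label", *df.columns[2:]]
    label_of = dict(zip(df["barcode"].astype(str), df["label"].astype(str)))

    y, x = hex_to_square(spots)
    # rebuild the same cropping the pipeline applied, via in-tissue lookup
    grid = {}
    ys = sorted(set(y.tolist()))
    xs = sorted(set(x.tolist()))
    ymap = {v: i for i, v in enumerate(ys)}
    xmap = {v: i for i, v in enumerate(xs)}
    for j, bc in enumerate(spots.barcodes):
        lab = label_of.get(bc)
        if lab is not None:
            grid[(ymap[y[j]], xmap[x[j]])] = lab

    regions: dict[str, np.ndarray] = {}
    ny, nx = t.values.shape[:2]
    for (yy, xx), lab in grid.items():
        if yy >= ny or xx >= nx:
            continue
        regions.setdefault(lab, np.zeros((ny, nx), dtype=bool))[yy, xx] = True
    return [RegionAnnotation(name, mask) for name, mask in sorted(regions.items())]
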