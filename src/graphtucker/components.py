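"""Spatial components: per-gene-component activity maps over the spot grid.

Contracting the core with the two spatial factors leaves one (ny, nx) map
per gene component,

    Gxy[:, :, k] = sum_{i,j} G[i, j, k] · Ay[:, i] ∘ Ax[:, j],

so each map aggregates every multiway interaction that involves gene
component k.  Applying the gene factor along the component axis recovers
the full reconstruction: Gxy ×2 Ag = T̂ — that identity anchors the
construction.  Restricting the core to its largest entries (a sparse core)
isolates the dominant interactions before building the maps.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import RegionAnnotation
from .optimizer import TuckerModel
from .tensor_algebra import nmode_product

logger = logging.getLogger(__name__)

__all__ = [
    "spatial_components",
    "sparsify_core",
    "core_mass_fraction",
    "match_regions",
    "combine_components",
]


def spatial_components(
    model: TuckerModel, core_override: np.ndarray | None = None
) -> np.ndarray:
    """Components tensor of shape (ny, nx, rg): the core contracted with
    the y factor on mode 0 and the x factor on mode 1.

    ``core_override`` substitutes a (typically sparsified) core of the same
    shape.  Use a normalized model so core magnitudes are comparable.
    """
    core = model.core if core_override is None else np.asarray(core_override)
    if core.shape != model.core.shape:
        raise ValueError(
            f"override core shape {core.shape} != model core {model.core.shape}"
        )
    return nmode_product(nmode_product(core, model.ay, 0), model.ax, 1)


def _top_k(percent: float, n_entries: int) -> int:
    if not 0 < percent <= 100:
        raise ValueError(f"percent must be in (0, 100], got {percent}")
    return int(np.ceil(percent / 100.0 * n_entries))


def sparsify_core(
    core: np.ndarray, percent: float, by_magnitude: bool = False
) -> np.ndarray:
    """Keep the largest ``percent``% of core entries, zero the rest.

    k = ceil(percent/100 · #entries) entries are retained by value (or by
    absolute value with ``by_magnitude``); ties at the threshold are broken
    by flat C-order index, keeping exactly k entries.
    """
    core = np.asarray(core, dtype=float)
    k = _top_k(percent, core.size)
    key = np.abs(core) if by_magnitude else core
    # stable: among equal values, lower flat index wins
    order = np.lexsort((np.arange(core.size), -key.ravel()))
    keep = order[:k]
    out = np.zeros_like(core)
    out.ravel()[keep] = core.ravel()[keep]
    return out


def core_mass_fraction(core: np.ndarray, percent: float) -> float:
    """Fraction of total core mass carried by the largest percent% of
    entries — how concentrated the multiway interactions are."""
    core = np.asarray(core, dtype=float)
    total = core.sum()
    if total <= 0:
        raise ValueError("core must have positive total mass")
    return float(sparsify_core(core, percent).sum() / total)


def combine_components(comps: np.ndarray, ids) -> np.ndarray:
    """Elementwise mean of the selected component maps."""
    ids = list(ids)
    if not ids:
        raise ValueError("need at least one component id")
    return np.asarray(comps)[:, :, ids].mean(axis=2)


def match_regions(
    comps: np.ndarray,
    regions: list[RegionAnnotation],
    in_tissue: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assign each annotated region the component with the lowest
    normalized Euclidean distance.

    Computes AUC and ED for every (region, component) pair over in-tissue
    spots and keeps, per region, the ED-minimizing component; several
    regions may map to the same component.  Returns a DataFrame with
    columns region, component, auc, ed.
    """
    from .evaluation import auc, euclidean_distance

    comps = np.asarray(comps)
    ny, nx, rg = comps.shape
    if in_tissue is None:
        in_tissue = np.ones((ny, nx), dtype=bool)
    rows = []
    for region in regions:
        labels = region.mask[in_tissue].astype(int)
        if labels.sum() == 0:
            logger.warning("region %s has no positive spots; skipped", region.name)
            continue
        best = None
        for k in range(rg):
            values = comps[:, :, k][in_tissue]
            if not np.linalg.norm(values) > 0:  # dead component
                continue
            ed = euclidean_distance(values, labels)
            if best is None or ed < best[2]:
                a = auc(values, labels) if labels.min() == 0 else float("nan")
                best = (k, a, ed)
        if best is None:
            logger.warning("no usable component for region %s; skipped", region.name)
            continue
        rows.append(
            {
                "region": region.name,
                "component": best[0],
                "auc": best[1],
                "ed": best[2],
            }
        )
    return pd.DataFrame(rows, columns=["region", "component", "auc", "ed"])
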