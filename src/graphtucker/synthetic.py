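"""Self-contained synthetic spatial-transcriptome fixtures.

The generator plants exactly the structure the decomposition model
assumes: smooth nonnegative spatial factors (soft-edged plateau bumps
along each chain, emulating blocky tissue domains such as cortical
layers), sparse nonnegative gene loadings with one dominant component
per gene, and a sparse nonnegative core that pairs each gene component
with one (y-band, x-band) tile so the rg spatial blobs tile the slide.
On top of the noiseless low-rank tensor it applies multiplicative noise
and entry-level dropout down to a Visium-like density, builds a gene
network that connects genes sharing a dominant component (plus
distractor edges), and emits blocky region annotations as level sets of
the true spatial components — so recovery, imputation and
region-matching can all be scored against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .containers import ExpressionTensor, MaskTensor, RegionAnnotation
from .graphs import UndirectedGraph
from .optimizer import TuckerModel
from .tensor_algebra import tucker_reconstruct

__all__ = ["SimulationSpec", "SimulationResult", "simulate"]


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic slide.

    Defaults emulate a scaled-down Visium section: a 40×40 spot grid with
    60 genes, rank (4, 2, 8) — four y-bands × two x-bands giving eight
    tissue tiles, one per gene component — soft plateau edges of ~1.5
    spots, 50% multiplicative noise (the coefficient of variation of
    Poisson counts in the 3–10 UMI range typical of observed Visium
    entries), and 12% observed density, the top of
    the range seen on real Visium sections (appropriate here because the
    shrunken gene axis leaves far fewer observations per component than
    at full scale).
    """

    shape: tuple[int, int, int] = (40, 40, 60)
    rank: tuple[int, int, int] = (4, 2, 8)
    smoothness: float = 1.5  # plateau edge softness, in spots
    noise: float = 0.5  # multiplicative noise CV; 0 = exact low rank
    density: float = 0.12  # target fraction of observed (nonzero) entries
    expression_floor: float = 0.1  # entries below this are never observed
    profile: str = "plateau"  # spatial factor shape: "plateau" or "bump"
    distractor_edge_frac: float = 0.2  # random network edges / true edges
    n_regions: int | None = None  # default: one region per gene component
    region_level: float = 0.5  # region = component > level * component max
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if any(r < 1 or r > s for r, s in zip(self.rank, self.shape)):
            raise ValueError(f"rank {self.rank} infeasible for shape {self.shape}")
        if self.noise < 0 or self.smoothness <= 0:
            raise ValueError("noise must be >= 0 and smoothness > 0")
        if self.profile not in ("plateau", "bump"):
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclass
class SimulationResult:
    tensor: ExpressionTensor
    mask: MaskTensor
    network: UndirectedGraph
    regions: list[RegionAnnotation]
    true_model: TuckerModel
    true_labels: np.ndarray  # per-spot dominant component (ny, nx)


def _plateau_factor(
    n: int, r: int, softness: float, rng: np.random.Generator
) -> np.ndarray:
    """n×r matrix of soft-edged plateau bumps tiling the chain.

    The chain splits into r contiguous bands with jittered boundaries;
    column j is ~1 inside band j and rolls off over ``softness`` spots at
    the edges (a logistic edge) — smooth, nonnegative, and close to an
    indicator of a blocky domain."""
    grid = np.arange(n, dtype=float)
    edges = np.linspace(0, n, r + 1)
    jitter = rng.uniform(-0.1, 0.1, size=r - 1) * (n / r)
    edges[1:-1] += jitter
    a = np.empty((n, r))
    for j in range(r):
        lo, hi = edges[j], edges[j + 1]
        a[:, j] = 1.0 / (1.0 + np.exp(-(grid - lo + 0.5) / softness)) \
            / (1.0 + np.exp(-(hi - grid - 0.5) / softness))
    return a


def _gaussian_factor(n: int, r: int, rng: np.random.Generator) -> np.ndarray:
    """n×r matrix of discretized Gaussian bumps at stratified random
    centers, with width half the band spacing so neighbors overlap —
    generic smooth nonnegative factors rather than blocky domains."""
    grid = np.arange(n, dtype=float)
    edges = np.linspace(0, n, r + 1)
    sigma = max(n / (2.0 * r), 1.0)
    a = np.empty((n, r))
    for j in range(r):
        c = rng.uniform(edges[j], edges[j + 1])
        a[:, j] = np.exp(-0.5 * ((grid - c) / sigma) ** 2)
    return a


def _gene_factor(ng: int, rg: int, rng: np.random.Generator):
    """Sparse loadings: each gene loads ~uniform(0.5, 1) on one dominant
    component plus a small background on one other component."""
    ag = np.zeros((ng, rg))
    dominant = rng.integers(rg, size=ng)
    # guarantee every component owns at least one gene
    dominant[:rg] = np.arange(rg)
    ag[np.arange(ng), dominant] = rng.uniform(0.5, 1.0, size=ng)
    other = (dominant + rng.integers(1, rg, size=ng)) % rg
    ag[np.arange(ng), other] += rng.uniform(0.0, 0.1, size=ng)
    return ag, dominant


def simulate(spec: SimulationSpec) -> SimulationResult:
    """Generate one synthetic slide with known ground truth."""
    ny, nx, ng = spec.shape
    ry, rx, rg = spec.rank
    rng = np.random.default_rng(spec.seed)

    if spec.profile == "plateau":
        ay = _plateau_factor(ny, ry, spec.smoothness, rng)
        ax = _plateau_factor(nx, rx, spec.smoothness, rng)
    else:
        ay = _gaussian_factor(ny, ry, rng)
        ax = _gaussian_factor(nx, rx, rng)
    ag, dominant = _gene_factor(ng, rg, rng)

    # sparse core: each gene component rides one (y-band, x-band) tile.
    # The diagonal-shifted enumeration assigns distinct tiles (no two gene
    # components share a spatial position, which would make them nearly
    # collinear and the fit degenerate) while touching every band of both
    # axes, so the tensor has full multilinear rank.  A little extra
    # off-tile mass keeps the core from being trivially CP.
    core = np.zeros((ry, rx, rg))
    for k in range(rg):
        core[k % ry, (k + k // ry) % rx, k] = rng.uniform(4.0, 6.0)
    if spec.profile == "bump":
        # generic smooth regime: a dense low-level background populates
        # every multiway interaction
        core += rng.uniform(0.0, 0.5, size=core.shape)
    else:
        n_off = max(1, (ry * rx * rg) // 20)
        idx = rng.integers(0, [ry, rx, rg], size=(n_off, 3))
        core[idx[:, 0], idx[:, 1], idx[:, 2]] += rng.uniform(0.1, 0.3, size=n_off)

    clean = tucker_reconstruct(core, ay, ax, ag)
    true_model = TuckerModel(core, ay, ax, ag)

    values = clean.copy()
    if spec.noise > 0:
        values = values * np.maximum(
            rng.normal(1.0, spec.noise, size=values.shape), 0.0
        )

    # entry-level dropout to the target density.  Entries below the
    # expression floor are never captured (the analogue of the sub-3-UMI
    # zeroing real pipelines apply), and the keep probability is scaled so
    # observed entries still hit the density target.  density=1 requests
    # the fully observed ideal tensor, so dropout is skipped entirely.
    if spec.density < 1.0:
        observable = values >= spec.expression_floor
        frac = observable.mean()
        q = min(1.0, spec.density / max(frac, 1e-12))
        keep = observable & (rng.uniform(size=values.shape) < q)
        values = values * keep
    tensor = ExpressionTensor(values, [f"gene_{i:03d}" for i in range(ng)])
    mask = MaskTensor((values > 0).astype(float))

    # gene network: edges within dominant components, plus distractors
    rows, cols = [], []
    for k in range(rg):
        members = np.flatnonzero(dominant == k)
        for i in range(len(members) - 1):  # chain within the module
            rows.append(members[i])
            cols.append(members[i + 1])
        if len(members) > 2:  # a few extra within-module edges
            extra = rng.choice(members, size=(len(members) // 2, 2))
            for a, b in extra:
                if a != b:
                    rows.append(a)
                    cols.append(b)
    n_true = len(rows)
    n_distract = int(round(spec.distractor_edge_frac * n_true))
    d = rng.integers(0, ng, size=(n_distract, 2))
    for a, b in d:
        if a != b:
            rows.append(a)
            cols.append(b)
    data = np.ones(2 * len(rows))
    adj = sp.coo_matrix(
        (data, (rows + cols, cols + rows)), shape=(ng, ng)
    ).tocsr()
    adj.sum_duplicates()
    adj.data[:] = 1.0
    network = UndirectedGraph(adj, node_ids=list(tensor.gene_ids))

    # planted regions: level sets of the true spatial components
    comps = np.einsum("ijk,yi,xj->yxk", core, ay, ax)
    labels = np.argmax(comps, axis=2)
    n_regions = spec.n_regions if spec.n_regions is not None else rg
    regions = []
    for k in range(min(n_regions, rg)):
        mask_k = comps[:, :, k] > spec.region_level * comps[:, :, k].max()
        regions.append(RegionAnnotation(f"region_{k}", mask_k))

    return SimulationResult(
        tensor=tensor,
        mask=mask,
        network=network,
        regions=regions,
        true_model=true_model,
        true_labels=labels,
    )
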