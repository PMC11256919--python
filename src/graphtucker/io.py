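"""On-disk containers: tensors as .npy + JSON sidecar, models as .npz,
run manifests as JSON."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .containers import ExpressionTensor, MaskTensor
from .optimizer import FitConfig, FitResult, TuckerModel

__all__ = [
    "save_tensor",
    "load_tensor",
    "save_model",
    "load_model",
    "write_manifest",
]


def save_tensor(t: ExpressionTensor, path, mask: MaskTensor | None = None) -> None:
    """Write values to ``<path>.npy`` (+ ``<path>.mask.npy``) with a JSON
    sidecar carrying shape, axis names, gene ids and the in-tissue map."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), t.values)
    if mask is not None:
        np.save(path.with_suffix(".mask.npy"), mask.values)
    sidecar = {
        "shape": list(t.shape),
        "axes": ["y", "x", "gene"],
        "gene_ids": t.gene_ids,
        "in_tissue": t.in_tissue.astype(int).tolist(),
        "coordinate_convention": "0-based (y, x); y = row, increasing downward",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_tensor(path) -> tuple[ExpressionTensor, MaskTensor | None]:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    t = ExpressionTensor(
        values, meta["gene_ids"], np.asarray(meta["in_tissue"], dtype=bool)
    )
    mask_path = path.with_suffix(".mask.npy")
    mask = MaskTensor(np.load(mask_path)) if mask_path.exists() else None
    return t, mask


def save_model(result: FitResult, path) -> None:
    """Model checkpoint: core + factors + config + objective trace."""
    cfg = result.config or FitConfig()
    np.savez(
        Path(path),
        core=result.model.core,
        ay=result.model.ay,
        ax=result.model.ax,
        ag=result.model.ag,
        trace=np.asarray(result.objective_trace),
        n_iter=result.n_iter,
        converged=result.converged,
        config=json.dumps(asdict(cfg)),
    )


def load_model(path) -> FitResult:
    with np.load(Path(path), allow_pickle=False) as z:
        model = TuckerModel(z["core"], z["ay"], z["ax"], z["ag"])
        cfg_d = json.loads(str(z["config"]))
        cfg_d["rank"] = tuple(cfg_d["rank"])
        return FitResult(
            model=model,
            objective_trace=[tuple(row) for row in z["trace"]],
            n_iter=int(z["n_iter"]),
            converged=bool(z["converged"]),
            config=FitConfig(**cfg_d),
        )


def write_manifest(path, stage: str, config: dict, extra: dict | None = None) -> None:
    """Machine-readable record sufficient to reproduce a run."""
    manifest = {
        "stage": stage,
        "config": config,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
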