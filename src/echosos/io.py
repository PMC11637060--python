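"""Serialization: the HDF5 dataset container, TIFF/PNG image export and YAML
solver configs.

Dataset layout (one HDF5 file)::

    /rf         float32 or int16, (N, 128, 1024)   conditioned RF frames
    /sos_label  float32, (N, 384, 384)             ground-truth SoS maps (m/s)
    attrs: seed (int), specs (JSON list of phantom specs)

Real acquisitions with the same 128 x 1024 layout can be ingested through the
same container.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import h5py
import numpy as np
import yaml

from .phantoms import PhantomSpec


def save_dataset(path: str | Path, rf: np.ndarray, labels: np.ndarray,
                 specs: Optional[Sequence[PhantomSpec]] = None, seed: int = 0) -> None:
    rf = np.asarray(rf)
    labels = np.asarray(labels)
    if rf.shape[0] != labels.shape[0]:
        raise ValueError("rf / label sample counts differ")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("rf", data=rf.astype(np.float32), compression="gzip")
        fh.create_dataset("sos_label", data=labels.astype(np.float32), compression="gzip")
        fh.attrs["seed"] = int(seed)
        if specs is not None:
            fh.attrs["specs"] = json.dumps([json.loads(s.to_json()) for s in specs])


def load_dataset(path: str | Path) -> Tuple[np.ndarray, np.ndarray, List[PhantomSpec], int]:
    with h5py.File(path, "r") as fh:
        rf = fh["rf"][...]
        labels = fh["sos_label"][...]
        seed = int(fh.attrs.get("seed", 0))
        specs = [PhantomSpec.from_json(json.dumps(d))
                 for d in json.loads(fh.attrs.get("specs", "[]"))]
    return rf, labels, specs, seed


def save_tiff(path: str | Path, image: np.ndarray) -> None:
    """32-bit float TIFF export (SoS maps, PA images)."""
    import tifffile
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def save_png(path: str | Path, image: np.ndarray, vmin: Optional[float] = None,
             vmax: Optional[float] = None, cmap: str = "viridis") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image, vmin=vmin, vmax=vmax, cmap=cmap)
    ax.axis("off")
    fig.savefig(str(path), bbox_inches="tight", dpi=150)
    plt.close(fig)


def load_solver_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_solver_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)
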