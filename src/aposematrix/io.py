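"""Image-stack interchange: one lossless text file per channel plus a
JSON sidecar carrying masks, standards, gamma and rendering truth."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synthetic import RenderedImage
from .types import ValidationError


def write_image_stack(image: RenderedImage, directory: str | Path) -> Path:
    """Write a rendered image as ``<channel>.csv`` files (full float
    precision) and a ``stack.json`` sidecar."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(image.channel_names):
        np.savetxt(out / f"{name}.csv", image.image[:, :, i], delimiter=",",
                   fmt="%.17g")
    sidecar = {
        "channels": list(image.channel_names),
        "shape": list(image.image.shape[:2]),
        "gamma": image.gamma,
        "standards": list(image.standards),
        "masks": {k: np.flatnonzero(v.ravel()).tolist() for k, v in image.masks.items()},
        "truth_linear": {k: list(map(float, v)) for k, v in image.truth_linear.items()},
    }
    (out / "stack.json").write_text(json.dumps(sidecar))
    return out


def read_image_stack(directory: str | Path) -> RenderedImage:
    """Read a stack written by :func:`write_image_stack`."""
    src = Path(directory)
    sidecar_path = src / "stack.json"
    if not sidecar_path.exists():
        raise ValidationError(f"no stack.json sidecar in {src}")
    sidecar = json.loads(sidecar_path.read_text())
    h, w = sidecar["shape"]
    channels = sidecar["channels"]
    image = np.stack(
        [np.loadtxt(src / f"{name}.csv", delimiter=",").reshape(h, w)
         for name in channels],
        axis=-1,
    )
    masks = {}
    for name, flat_idx in sidecar["masks"].items():
        m = np.zeros(h * w, bool)
        m[np.asarray(flat_idx, int)] = True
        masks[name] = m.reshape(h, w)
    truth = {k: np.asarray(v, float) for k, v in sidecar["truth_linear"].items()}
    return RenderedImage(
        image=image,
        channel_names=tuple(channels),
        masks=masks,
        truth_linear=truth,
        standards=tuple(sidecar["standards"]),
        gamma=float(sidecar["gamma"]),
    )
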