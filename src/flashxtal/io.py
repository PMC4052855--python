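"""Pattern and report writers: HDF5/NPZ archives, JSON reports, PNG renders."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .diffraction import DiffractionPattern, QGrid

__all__ = ["write_pattern", "read_pattern", "write_png", "write_json_report"]

_FORMATS = ("h5", "npz")


def _arrays(pattern: DiffractionPattern) -> dict:
    arrays = {
        "q": pattern.grid.q,
        "bragg": pattern.bragg,
        "diffuse": pattern.diffuse,
        "total": pattern.intensity,
    }
    if pattern.mc_total is not None:
        arrays["mc_total"] = pattern.mc_total
    if pattern.mc_stderr is not None:
        arrays["mc_stderr"] = pattern.mc_stderr
    return arrays


def write_pattern(pattern: DiffractionPattern, path, fmt: str | None = None) -> Path:
    """Write a pattern to HDF5 (groups /q /bragg /diffuse /total /meta) or NPZ.

    The paired :func:`read_pattern` round-trips all arrays bitwise.
    """
    path = Path(path)
    fmt = fmt or (path.suffix.lstrip(".") or "h5")
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; supported: {_FORMATS}")
    meta = dict(pattern.meta)
    meta.update(d_omega=pattern.grid.d_omega, wavelength=pattern.grid.wavelength,
                shape=list(pattern.grid.shape) if pattern.grid.shape else None,
                plane_axes=list(pattern.grid.plane_axes))
    if fmt == "h5":
        import h5py

        with h5py.File(path, "w") as fh:
            for name, arr in _arrays(pattern).items():
                fh.create_dataset(name, data=arr)
            fh.create_dataset("meta", data=json.dumps(meta, default=str))
    else:
        np.savez(path, meta=json.dumps(meta, default=str), **_arrays(pattern))
    return path


def read_pattern(path) -> DiffractionPattern:
    path = Path(path)
    if path.suffix == ".h5":
        import h5py

        with h5py.File(path, "r") as fh:
            arrays = {k: fh[k][()] for k in fh if k != "meta"}
            meta = json.loads(fh["meta"][()])
    else:
        with np.load(path, allow_pickle=False) as data:
            arrays = {k: data[k] for k in data.files if k != "meta"}
            meta = json.loads(str(data["meta"]))
    shape = tuple(meta.pop("shape")) if meta.get("shape") else None
    if meta.get("shape", "absent") is None:
        meta.pop("shape")
    grid = QGrid(q=arrays["q"], d_omega=meta.pop("d_omega"),
                 wavelength=meta.pop("wavelength"), shape=shape,
                 plane_axes=tuple(meta.pop("plane_axes", (0, 1))))
    return DiffractionPattern(
        grid=grid, bragg=arrays["bragg"], diffuse=arrays["diffuse"],
        mc_total=arrays.get("mc_total"), mc_stderr=arrays.get("mc_stderr"),
        meta=meta,
    )


def write_png(pattern: DiffractionPattern, path) -> Path:
    """Render bragg/diffuse/total planar panels, each max-normalized, on a
    log-ish scale (power 0.25) so weak peaks stay visible."""
    if pattern.grid.shape is None:
        raise ValueError("PNG rendering requires a planar grid")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = pattern.grid.shape[0]
    panels = [("bragg", pattern.bragg), ("diffuse", pattern.diffuse),
              ("total", pattern.intensity)]
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, (name, arr) in zip(axes, panels):
        img = arr.reshape(n, n)
        top = img.max() or 1.0
        ax.imshow((img / top) ** 0.25, origin="lower", cmap="inferno")
        ax.set_title(name)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def write_json_report(report: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return path
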