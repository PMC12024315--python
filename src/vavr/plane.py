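"""Cross-sectional velocity plane container and its on-disk format.

A :class:`VelocityPlane` holds a regular in-plane grid of 3-component
velocity samples together with a boolean lumen mask.  The plane normal is
+z, so ``vz`` is the through-plane component and ``(vx, vy)`` the in-plane
part.  Coordinates are millimetres, velocities metres per second.

The on-disk format is a CSV with header
``x_mm,y_mm,vx_mps,vy_mps,vz_mps,in_lumen`` plus a JSON sidecar
``{"spacing_mm": ..., "lumen_radius_mm": ...}`` stored next to it with the
extension ``.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InputError

__all__ = ["VelocityPlane"]

_CSV_COLUMNS = ["x_mm", "y_mm", "vx_mps", "vy_mps", "vz_mps", "in_lumen"]


@dataclass
class VelocityPlane:
    """Velocity samples on a regular planar grid with a lumen mask.

    Parameters
    ----------
    x, y : ndarray, shape (n,)
        In-plane sample coordinates in mm (regular square lattice).
    vx, vy : ndarray, shape (n,)
        In-plane velocity components in m/s.
    vz : ndarray, shape (n,)
        Through-plane velocity component (along the +z plane normal) in m/s.
    mask : ndarray of bool, shape (n,)
        True for samples inside the lumen.
    spacing : float
        Grid spacing in mm.
    lumen_radius : float, optional
        Nominal lumen radius in mm when the plane was generated
        synthetically; informational only.
    """

    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray
    mask: np.ndarray
    spacing: float
    lumen_radius: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        self.vz = np.asarray(self.vz, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.x.shape[0]
        for name in ("y", "vx", "vy", "vz", "mask"):
            if getattr(self, name).shape != (n,):
                raise InputError(f"field '{name}' has shape "
                                 f"{getattr(self, name).shape}, expected ({n},)")

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise :class:`InputError` on failure.

        Requires positive spacing, at least 16 lumen samples, zero velocity
        outside the mask, and a single-connected lumen.
        """
        if not np.isfinite(self.spacing) or self.spacing <= 0:
            raise InputError(f"spacing must be positive, got {self.spacing}")
        n_lumen = int(self.mask.sum())
        if n_lumen < 16:
            raise InputError(f"lumen mask has {n_lumen} samples, need >= 16")
        out = ~self.mask
        if np.any(self.vx[out]) or np.any(self.vy[out]) or np.any(self.vz[out]):
            raise InputError("nonzero velocity outside the lumen mask")
        if self._n_components() != 1:
            raise InputError("lumen mask is not a single connected region")

    def _rasterize(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map flat samples onto an integer (row, col) lattice."""
        ix = np.rint((self.x - self.x.min()) / self.spacing).astype(int)
        iy = np.rint((self.y - self.y.min()) / self.spacing).astype(int)
        grid = np.zeros((iy.max() + 1, ix.max() + 1), dtype=bool)
        grid[iy[self.mask], ix[self.mask]] = True
        return grid, iy, ix

    def _n_components(self) -> int:
        grid, _, _ = self._rasterize()
        _, n = ndimage.label(grid)
        return int(n)

    # ------------------------------------------------------------------
    # convenience views
    # ------------------------------------------------------------------
    @property
    def n_lumen(self) -> int:
        return int(self.mask.sum())

    def lumen_velocities(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (vx, vy, vz) restricted to lumen samples."""
        m = self.mask
        return self.vx[m], self.vy[m], self.vz[m]

    # ------------------------------------------------------------------
    # I/O
    # ------------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the plane CSV and its JSON sidecar."""
        path = Path(path)
        df = pd.DataFrame({
            "x_mm": self.x,
            "y_mm": self.y,
            "vx_mps": self.vx,
            "vy_mps": self.vy,
            "vz_mps": self.vz,
            "in_lumen": self.mask.astype(int),
        })
        df.to_csv(path, index=False, float_format="%.17g")
        sidecar = {"spacing_mm": self.spacing,
                   "lumen_radius_mm": self.lumen_radius}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path: str | Path) -> "VelocityPlane":
        """Read a plane CSV written by :meth:`to_csv`."""
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"plane CSV missing columns: {missing}")
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise InputError(f"missing JSON sidecar: {sidecar_path}")
        sidecar = json.loads(sidecar_path.read_text())
        return cls(
            x=df["x_mm"].to_numpy(),
            y=df["y_mm"].to_numpy(),
            vx=df["vx_mps"].to_numpy(),
            vy=df["vy_mps"].to_numpy(),
            vz=df["vz_mps"].to_numpy(),
            mask=df["in_lumen"].to_numpy().astype(bool),
            spacing=float(sidecar["spacing_mm"]),
            lumen_radius=sidecar.get("lumen_radius_mm"),
        )
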