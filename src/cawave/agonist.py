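"""Per-EC agonist (J_PLC) maps.

Every simulation needs a map assigning each endothelial cell the IP3
production flux ``j_plc`` (uM/s) induced by the luminal ATP it sees.  Three
sources are supported: a synthetic sigmoid of axial position (centred on the
bifurcation point by default), conversion of an ATP wall profile from the
reduced transport solver, and plain files (CSV or HDF5).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import BifurcationMesh

__all__ = ["AgonistMap", "SigmoidSpec", "sigmoid_map", "atp_to_jplc",
           "load_map", "save_map"]


@dataclass
class AgonistMap:
    """J_PLC value per EC (uM/s), indexed like the mesh's EC enumeration."""

    values: np.ndarray
    provenance: str = "file"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("agonist map must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("agonist map values must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return (isinstance(other, AgonistMap)
                and np.array_equal(self.values, other.values))


@dataclass
class SigmoidSpec:
    """Axial sigmoid profile of J_PLC.

    ``j_min``/``j_max`` are the upstream/downstream plateaus (uM/s),
    ``x_center`` the inflection position along the centreline (mm; 0 is the
    bifurcation point, negative upstream) and ``steepness`` the logistic
    rate (1/mm).  Defaults span the Case-1 oscillatory window so that a tube
    or bifurcation carries steady, oscillatory and again steady bands.
    """

    j_min: float = 2.0
    j_max: float = 5.5
    x_center: float = 0.0
    steepness: float = 2.0

    def __post_init__(self) -> None:
        if not (self.j_max > self.j_min >= 0):
            raise ValueError("need j_max > j_min >= 0")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")

    def __call__(self, x_axial) -> np.ndarray:
        from scipy.special import expit

        x = np.asarray(x_axial, dtype=float)
        return self.j_min + (self.j_max - self.j_min) * expit(
            self.steepness * (x - self.x_center))


def sigmoid_map(mesh: BifurcationMesh, spec: SigmoidSpec | None = None
                ) -> AgonistMap:
    """Sigmoid agonist map: J_PLC as a function of axial distance only.

    The axial coordinate runs along the centreline path, negative upstream
    of the bifurcation point and positive towards the outlets, so the map is
    circumferentially uniform by construction.
    """
    if not mesh.tiled:
        raise ValueError("mesh must be tiled before building agonist maps")
    spec = spec or SigmoidSpec()
    return AgonistMap(spec(mesh.ec.axial), provenance="sigmoid")


def atp_to_jplc(atp, slope: float = 10.0, intercept: float = 0.0):
    """Linear ATP (uM) to J_PLC (uM/s) conversion, floored at zero.

    The ATP-to-IP3-production relationship is monotone increasing and well
    approximated as linear over the physiological ATP range; ``slope``
    ((uM/s)/uM) and ``intercept`` (uM/s) are calibration values.  The
    default slope maps a 0.1 uM luminal inlet concentration to 1.0 uM/s.
    """
    atp = np.asarray(atp, dtype=float)
    if np.any(atp < 0):
        raise ValueError("ATP concentrations must be non-negative")
    return np.maximum(slope * atp + intercept, 0.0)


def save_map(amap: AgonistMap, path) -> None:
    """Write a map as 2-column CSV (ec_index, j_plc) or an HDF5 dataset."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("j_plc", data=amap.values)
            d.attrs["units"] = "uM/s"
            d.attrs["provenance"] = amap.provenance
    else:
        pd.DataFrame({"ec_index": np.arange(len(amap)),
                      "j_plc": amap.values}).to_csv(
            path, index=False, float_format="%.17g")


def load_map(path, mesh: BifurcationMesh | None = None) -> AgonistMap:
    """Load a per-EC map; length-checked against the mesh when given."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            values = f["j_plc"][:]
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        values = df.sort_values(df.columns[0])[df.columns[1]].to_numpy()
    amap = AgonistMap(values, provenance="file")
    if mesh is not None and len(amap) != mesh.n_ec:
        raise ValueError(
            f"agonist map has {len(amap)} entries, mesh has {mesh.n_ec} ECs")
    return amap
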