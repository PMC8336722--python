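"""HDF5 serialization of phantoms, absorbed-energy stacks, and datasets."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .decoloring import LabeledSpectraSet
from .fluence import AbsorbedEnergyStack
from .phantoms import VoxelPhantom
from .spectra import ChromophoreMixture, WavelengthGrid

__all__ = ["save_phantom", "load_phantom", "save_stack", "load_stack",
           "save_dataset", "load_dataset"]


def save_phantom(path, phantom: VoxelPhantom, stack: AbsorbedEnergyStack | None = None
                 ) -> None:
    """Write a phantom (and optionally its stack) to one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("mu_a", data=phantom.mu_a, compression="gzip")
        f.create_dataset("mu_s_prime", data=phantom.mu_s_prime, compression="gzip")
        f.create_dataset("labels", data=phantom.labels)
        f.create_dataset("tube_saturations", data=phantom.tube_saturations)
        meta = {
            "wavelengths_nm": list(phantom.grid.values),
            "pitch_mm": phantom.pitch_mm,
            "extent_mm": list(phantom.extent_mm),
            "background": {
                "saturation": phantom.background.saturation,
                "volume_fraction": phantom.background.volume_fraction,
                "family": phantom.background.family,
            },
            "meta": phantom.meta,
        }
        f.attrs["meta_json"] = json.dumps(meta)
        if stack is not None:
            # dims: [illumination, wavelength, z, x]
            f.create_dataset("H", data=stack.H, compression="gzip")
            f.attrs["stack_json"] = json.dumps(
                {"backend": stack.backend, "seed": stack.seed, "meta": stack.meta})


def load_phantom(path) -> VoxelPhantom:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta_json"])
        bg = meta["background"]
        return VoxelPhantom(
            grid=WavelengthGrid(tuple(meta["wavelengths_nm"])),
            pitch_mm=meta["pitch_mm"],
            extent_mm=tuple(meta["extent_mm"]),
            mu_a=f["mu_a"][()],
            mu_s_prime=f["mu_s_prime"][()],
            labels=f["labels"][()],
            tube_saturations=f["tube_saturations"][()],
            background=ChromophoreMixture(bg["saturation"], bg["volume_fraction"],
                                          bg["family"]),
            meta=meta["meta"])


def save_stack(path, stack: AbsorbedEnergyStack) -> None:
    save_phantom(path, stack.phantom, stack)


def load_stack(path) -> AbsorbedEnergyStack:
    phantom = load_phantom(path)
    with h5py.File(path, "r") as f:
        if "H" not in f:
            raise KeyError(f"{path} holds no absorbed-energy stack")
        info = json.loads(f.attrs["stack_json"])
        return AbsorbedEnergyStack(H=f["H"][()], phantom=phantom,
                                   backend=info["backend"], seed=info["seed"],
                                   meta=info["meta"])


def save_dataset(path, ds: LabeledSpectraSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=ds.features, compression="gzip")
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset("provenance", data=ds.provenance)
        f.attrs["mode"] = ds.mode
        f.attrs["n_wavelengths"] = ds.n_wavelengths
        f.attrs["n_illuminations"] = ds.n_illuminations
        f.attrs["n_dropped"] = ds.n_dropped


def load_dataset(path) -> LabeledSpectraSet:
    with h5py.File(path, "r") as f:
        return LabeledSpectraSet(
            features=f["features"][()], labels=f["labels"][()],
            provenance=f["provenance"][()], mode=str(f.attrs["mode"]),
            n_wavelengths=int(f.attrs["n_wavelengths"]),
            n_illuminations=int(f.attrs["n_illuminations"]),
            n_dropped=int(f.attrs["n_dropped"]))
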