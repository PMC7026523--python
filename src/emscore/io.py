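"""File I/O: float32 TIFF phase/height maps, uint16 holograms and label
images, JSON ground-truth sidecars."""

from __future__ import annotations

import json

import numpy as np
import tifffile

from .holography import HeightMap, Hologram, PhaseMap
from .simulate import GroundTruth


def save_phase_map(path, phase: PhaseMap) -> None:
    tifffile.imwrite(path, phase.phase.astype(np.float32),
                     metadata={"pixel_pitch_um": phase.pixel_pitch})


def load_phase_map(path, pixel_pitch: float = 0.18) -> PhaseMap:
    return PhaseMap(tifffile.imread(path).astype(float), pixel_pitch)


def save_height_map(path, height: HeightMap) -> None:
    tifffile.imwrite(path, height.height.astype(np.float32),
                     metadata={"pixel_pitch_um": height.pixel_pitch,
                               "delta_n": height.delta_n})


def load_height_map(path, pixel_pitch: float = 0.18, delta_n: float = 0.044) -> HeightMap:
    return HeightMap(tifffile.imread(path).astype(float), pixel_pitch, delta_n)


def save_hologram(path, holo: Hologram) -> None:
    # scale to the uint16 range of a CMOS sensor
    inten = holo.intensity
    peak = inten.max() if inten.max() > 0 else 1.0
    scaled = np.clip(inten / peak * 65535.0, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, scaled, metadata={
        "pixel_pitch_um": holo.pixel_pitch,
        "wavelength_nm": holo.wavelength,
        "intensity_peak": float(peak),
    })


def load_hologram(path, pixel_pitch: float = 0.18, wavelength: float = 632.0) -> Hologram:
    arr = tifffile.imread(path).astype(float)
    return Hologram(arr, pixel_pitch, wavelength)


def save_ground_truth(json_path, gt: GroundTruth, labels_path=None) -> None:
    doc = gt.to_json_dict()
    doc["cells"] = [_jsonify(c) for c in doc["cells"]]
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=1)
    if labels_path is not None:
        tifffile.imwrite(labels_path, gt.labels.astype(np.uint16))


def load_ground_truth(json_path, labels_path=None) -> GroundTruth:
    with open(json_path) as fh:
        doc = json.load(fh)
    labels = (
        tifffile.imread(labels_path) if labels_path is not None
        else np.zeros((0, 0), dtype=np.uint16)
    )
    return GroundTruth(line=doc["line"], cells=doc["cells"], labels=labels,
                       optics=doc.get("optics", {}))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def sha256_of(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
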