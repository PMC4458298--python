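"""Reading and writing of stacks, scene configurations and results.

Array payloads go to NPZ; frame stacks are additionally exportable as
multi-page 32-bit-float TIFF (one page per time point) with the
acquisition times in a JSON sidecar.  Scene configurations are YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .errors import ConfigValidationError
from .forward import OpticalProperties
from .scenes import Inclusion, MeasurementStack, NoiseSpec, Scene, TimeCourse


def save_stack(path, stack: MeasurementStack):
    payload = {
        "frames": stack.frames,
        "times": stack.times,
        "background_subtracted": np.array(stack.background_subtracted),
    }
    if "preinjection" in stack.meta:
        payload["preinjection"] = stack.meta["preinjection"]
    np.savez(path, **payload)


def load_stack(path) -> MeasurementStack:
    with np.load(path) as z:
        meta = {}
        if "preinjection" in z:
            meta["preinjection"] = z["preinjection"]
        return MeasurementStack(frames=z["frames"], times=z["times"],
                                background_subtracted=bool(z["background_subtracted"]),
                                meta=meta)


def export_tiff(path, frames: np.ndarray, raster_shape=None, times=None):
    """Multi-page float32 TIFF; pixels reshaped to ``raster_shape`` when
    given (e.g. detectors as a sources x detectors raster)."""
    data = np.asarray(frames, dtype=np.float32)
    if raster_shape is not None:
        data = data.reshape(data.shape[0], *raster_shape)
    else:
        data = data.reshape(data.shape[0], 1, -1)
    tifffile.imwrite(path, data, photometric="minisblack")
    if times is not None:
        Path(str(path) + ".times.json").write_text(
            json.dumps({"times_min": list(map(float, times))}))


_OPTICS_KEYS = {"mu_a_x", "mu_s_prime_x", "mu_a_m", "mu_s_prime_m"}
_GEOM_KEYS = {"width_mm", "height_mm", "edge_mm"}


def scene_from_config(cfg: dict) -> Scene:
    """Build a Scene from a parsed YAML mapping, reporting every offending
    key in one pass."""
    bad = []
    if not isinstance(cfg, dict) or "scene" not in cfg:
        raise ConfigValidationError("missing top-level 'scene' section",
                                    keys=["scene"])
    sc = cfg["scene"]
    geom = sc.get("geometry", {})
    bad += [f"scene.geometry.{k}" for k in _GEOM_KEYS - set(geom)]
    optics = sc.get("optics", {})
    bad += [f"scene.optics.{k}" for k in _OPTICS_KEYS - set(optics)]
    incs = sc.get("inclusions")
    if not incs:
        bad.append("scene.inclusions")
    else:
        for i, inc in enumerate(incs):
            for k in ("center", "radius", "course"):
                if k not in inc:
                    bad.append(f"scene.inclusions[{i}].{k}")
            course = inc.get("course", {})
            for k in ("times", "values"):
                if k not in course:
                    bad.append(f"scene.inclusions[{i}].course.{k}")
    if bad:
        raise ConfigValidationError(
            "invalid scene config; missing keys: " + ", ".join(sorted(bad)),
            keys=bad)
    props = OpticalProperties(
        mu_a_x=float(optics["mu_a_x"]),
        mu_s_prime_x=float(optics["mu_s_prime_x"]),
        mu_a_m=float(optics["mu_a_m"]),
        mu_s_prime_m=float(optics["mu_s_prime_m"]),
        refractive_index=float(optics.get("refractive_index", 1.0)))
    inclusions = [
        Inclusion(center=tuple(map(float, inc["center"])),
                  radius=float(inc["radius"]),
                  course=TimeCourse(times=np.asarray(inc["course"]["times"], float),
                                    values=np.asarray(inc["course"]["values"], float),
                                    label=inc.get("label", f"source {i + 1}")),
                  epsilon=float(inc.get("epsilon", 1.0)),
                  eta=float(inc.get("eta", 1.0)))
        for i, inc in enumerate(incs)]
    return Scene(width=float(geom["width_mm"]), height=float(geom["height_mm"]),
                 edge_len=float(geom["edge_mm"]), optics=props,
                 inclusions=inclusions,
                 n_excitation_sources=int(sc.get("n_excitation_sources", 4)),
                 detector_every=int(sc.get("detector_every", 2)),
                 background=sc.get("background"))


def noise_from_config(cfg: dict) -> NoiseSpec | None:
    nz = cfg.get("noise")
    if nz is None:
        return None
    if not isinstance(nz, dict) or \
            ("psnr_db" not in nz and "variance" not in nz):
        raise ConfigValidationError("noise section needs psnr_db or variance",
                                    keys=["noise"])
    return NoiseSpec(psnr_db=nz.get("psnr_db"), variance=nz.get("variance"),
                     seed=int(nz.get("seed", 0)))


def load_config(path) -> dict:
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigValidationError(f"config is not valid YAML: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigValidationError("config must be a YAML mapping")
    cfg["_raw_text"] = text
    return cfg


def write_provenance(path, config_text: str, seed, extra=None):
    info = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": seed,
        "fmtunmix_version": __version__,
        "numpy_version": np.__version__,
    }
    if extra:
        info.update(extra)
    Path(path).write_text(json.dumps(info, indent=2))


def save_unmix_result(path, result):
    np.savez(path,
             sources=result.sources,
             mixing=result.mixing,
             sources_raw=(result.sources_raw if result.sources_raw is not None
                          else result.sources),
             method=np.array(result.method_tag),
             has_negative=np.array(result.has_negative))
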