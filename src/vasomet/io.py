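"""Reading and writing masks, grayscale stains, maps and section manifests.

Masks travel as single-channel 8-bit PNG or TIFF (0 background, 255
foreground); grayscale stains as 8- or 16-bit TIFF/PNG.  A *section
manifest* is a small YAML file naming the mask files by role::

    pixel_size_um: 2.0
    roi: roi.png
    vessels: cd34.png
    markers:
      GLUT1: glut1.png
      CAIX: caix.png

Relative paths resolve against the manifest's directory.  A *cohort
manifest* lists per-group section manifests::

    groups:
      GBM: [s01/section.yaml, s02/section.yaml]
      AA:  [s11/section.yaml]
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Tuple

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .errors import ValidationError
from .geometry import DistanceMap, DomainMap
from .masks import PixelMask, SectionBundle, validate_section

__all__ = [
    "read_mask",
    "write_mask",
    "read_image",
    "write_distance_map",
    "write_domain_map",
    "read_section_manifest",
    "write_section_manifest",
    "read_cohort_manifest",
]


def read_image(path: str | Path) -> np.ndarray:
    """A 2-D grayscale raster from PNG/TIFF (first channel if multichannel)."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValidationError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    return arr


def read_mask(path: str | Path, pixel_size_um: float) -> PixelMask:
    """A binary mask from an image file: any nonzero pixel is foreground."""
    return PixelMask(read_image(path) > 0, pixel_size_um)


def write_mask(mask: PixelMask, path: str | Path) -> None:
    """Write a mask as 8-bit PNG/TIFF with foreground 255."""
    iio.imwrite(Path(path), mask.grid.astype(np.uint8) * 255)


def write_distance_map(dmap: DistanceMap, path: str | Path) -> None:
    """Export a distance map as float32 TIFF (values in um)."""
    tifffile.imwrite(str(path), dmap.dist_um.astype(np.float32))


def write_domain_map(domains: DomainMap, path: str | Path) -> None:
    """Export a domain map as uint16 TIFF of component labels."""
    if domains.n_components > np.iinfo(np.uint16).max:
        raise ValidationError("too many components for a uint16 export")
    tifffile.imwrite(str(path), domains.assignment.astype(np.uint16))


def read_section_manifest(path: str | Path, section_id: str | None = None) -> SectionBundle:
    """Load and validate the section a manifest describes."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "pixel_size_um" not in doc or "roi" not in doc:
        raise ValidationError(f"{path}: manifest needs at least 'pixel_size_um' and 'roi'")
    px = float(doc["pixel_size_um"])
    base = path.parent

    def load(rel: str) -> PixelMask:
        return read_mask(base / rel, px)

    roi = load(doc["roi"])
    vessels = load(doc["vessels"]) if "vessels" in doc else None
    markers = {name: load(rel) for name, rel in (doc.get("markers") or {}).items()}
    return validate_section(
        roi=roi, vessels=vessels, markers=markers, section_id=section_id or path.stem
    )


def write_section_manifest(
    bundle: SectionBundle, directory: str | Path, manifest_name: str = "section.yaml"
) -> Path:
    """Write a bundle's masks as PNGs plus a manifest into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc: dict = {"pixel_size_um": bundle.pixel_size_um, "roi": "roi.png"}
    write_mask(bundle.roi, directory / "roi.png")
    if bundle.vessels is not None:
        write_mask(bundle.vessels, directory / "vessels.png")
        doc["vessels"] = "vessels.png"
    if bundle.markers:
        doc["markers"] = {}
        for name, mask in bundle.markers.items():
            fname = f"marker_{name}.png"
            write_mask(mask, directory / fname)
            doc["markers"][name] = fname
    out = directory / manifest_name
    with open(out, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return out


def read_cohort_manifest(path: str | Path) -> List[Tuple[str, SectionBundle]]:
    """Load ``(group, bundle)`` pairs from a cohort manifest."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    groups: Dict[str, List[str]] = (doc or {}).get("groups") or {}
    if not groups:
        raise ValidationError(f"{path}: cohort manifest has no 'groups'")
    out: List[Tuple[str, SectionBundle]] = []
    for group, manifests in groups.items():
        for rel in manifests:
            mpath = path.parent / rel
            out.append((group, read_section_manifest(mpath, section_id=Path(rel).parent.name or Path(rel).stem)))
    return out
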