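"""Rendering of MMPs as consistently formatted pair images.

Each MMP is encoded as one image with three horizontally concatenated
panels: the shared core, the substituent of the more potent compound and
the substituent of the less potent compound.  Fragments are depicted as
standard 2D structure drawings on a white background with the attachment
site drawn as an asterisk.  Panels are rendered at 500x500, resized to
300x300 (bilinear) and concatenated into a 300x900x3 tensor, converted
to 32-bit float and scaled to [0, 1] by dividing by 255 so that white is
exactly 1.0 in every image.

A reduced geometry (panel height 150, composite 150x450) is available
for desk-scale runs; all layout logic scales with the panel size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from rdkit import Chem
from rdkit.Chem import rdDepictor
from rdkit.Chem.Draw import rdMolDraw2D

from .errors import DataError, UsageError

logger = logging.getLogger(__name__)

PANEL_RASTER_SIZE = 500  # native render resolution of one fragment panel
PANEL_SIZE = 300  # panel edge after resizing, full-size profile
N_PANELS = 3


@dataclass(frozen=True)
class StructurePanel:
    """A rendered fragment: 8-bit RGB raster with one asterisk attachment."""

    fragment_key: str
    pixels: np.ndarray  # (size, size, 3) uint8

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise UsageError("panel pixels must be HxWx3")


@dataclass(frozen=True)
class MMPImage:
    """Normalized composite tensor: [core | sub (more potent) | sub (less)]."""

    mmp_id: str
    tensor: np.ndarray  # (H, 3H, 3) float32 in [0, 1]


def render_panel(fragment_key: str, raster_size: int = PANEL_RASTER_SIZE) -> StructurePanel:
    """Deterministically depict one fragment on a square white canvas.

    The fragment must carry exactly one attachment point (a ``*`` dummy
    atom), which the drawing shows as an asterisk glyph.
    """
    mol = Chem.MolFromSmiles(fragment_key)
    if mol is None:
        raise DataError(f"render_panel: unparsable fragment {fragment_key!r}")
    n_attach = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
    if n_attach != 1:
        raise DataError(
            f"render_panel: fragment {fragment_key!r} has {n_attach} attachment points, expected 1"
        )
    # strip atom-map numbers so the attachment renders as a bare asterisk
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    rdDepictor.Compute2DCoords(mol)
    drawer = rdMolDraw2D.MolDraw2DCairo(raster_size, raster_size)
    opts = drawer.drawOptions()
    opts.fixedBondLength = -1  # scale to fit canvas
    rdMolDraw2D.PrepareAndDrawMolecule(drawer, mol)
    drawer.FinishDrawing()
    png_bytes = drawer.GetDrawingText()
    import io

    with Image.open(io.BytesIO(png_bytes)) as img:
        pixels = np.asarray(img.convert("RGB"), dtype=np.uint8)
    return StructurePanel(fragment_key=fragment_key, pixels=pixels)


def _resize_panel(panel: StructurePanel, size: int) -> np.ndarray:
    img = Image.fromarray(panel.pixels)
    return np.asarray(img.resize((size, size), Image.BILINEAR), dtype=np.uint8)


def compose_mmp_image(
    core: StructurePanel,
    sub_hi: StructurePanel,
    sub_lo: StructurePanel,
    panel_size: int = PANEL_SIZE,
    mmp_id: str = "",
) -> MMPImage:
    """Resize three panels and concatenate them into one float tensor.

    Panel order is core, substituent of the more potent compound,
    substituent of the less potent compound.  Pixel values are divided by
    255, keeping the white background at exactly 1.0.
    """
    shapes = {core.pixels.shape, sub_hi.pixels.shape, sub_lo.pixels.shape}
    if len(shapes) != 1:
        raise UsageError(f"compose_mmp_image: mismatched panel shapes {shapes}")
    panels = [_resize_panel(p, panel_size) for p in (core, sub_hi, sub_lo)]
    tensor = np.concatenate(panels, axis=1).astype(np.float32) / 255.0
    return MMPImage(mmp_id=mmp_id, tensor=tensor)


class PanelCache:
    """Render each unique fragment once."""

    def __init__(self, raster_size: int = PANEL_RASTER_SIZE):
        self.raster_size = raster_size
        self._panels: dict[str, StructurePanel] = {}
        self.render_count = 0

    def get(self, fragment_key: str) -> StructurePanel:
        if fragment_key not in self._panels:
            self._panels[fragment_key] = render_panel(fragment_key, self.raster_size)
            self.render_count += 1
        return self._panels[fragment_key]


def render_mmp(labeled_mmp, cache: PanelCache, panel_size: int = PANEL_SIZE) -> MMPImage:
    """Composite image of one labeled MMP (panels through the cache)."""
    m = labeled_mmp.mmp
    return compose_mmp_image(
        cache.get(m.core_key),
        cache.get(m.substituent_a),
        cache.get(m.substituent_b),
        panel_size=panel_size,
        mmp_id=m.mmp_id,
    )


def render_tensors(
    labeled_mmps,
    panel_size: int = PANEL_SIZE,
    cache: PanelCache | None = None,
    augment_swap: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """In-memory image stack (n, H, 3H, 3) plus matching MMP ids.

    With ``augment_swap`` each MMP additionally yields a second image
    (id suffixed ``__swap``) with the two substituent panels exchanged,
    so a model can be trained free of the panel-order convention.
    """
    cache = cache or PanelCache()
    tensors, ids, skipped = [], [], 0
    for lm in labeled_mmps:
        try:
            img = render_mmp(lm, cache, panel_size=panel_size)
        except DataError as exc:
            logger.warning("skipping %s: %s", lm.mmp_id, exc)
            skipped += 1
            continue
        tensors.append(img.tensor)
        ids.append(img.mmp_id)
        if augment_swap:
            swapped = np.concatenate(
                [
                    img.tensor[:, :panel_size],
                    img.tensor[:, 2 * panel_size :],
                    img.tensor[:, panel_size : 2 * panel_size],
                ],
                axis=1,
            )
            tensors.append(swapped)
            ids.append(f"{img.mmp_id}__swap")
    if skipped:
        logger.warning("render_tensors: skipped %d MMP(s)", skipped)
    stack = (
        np.stack(tensors)
        if tensors
        else np.empty((0, panel_size, N_PANELS * panel_size, 3), dtype=np.float32)
    )
    return stack, ids


def render_dataset(
    labeled_mmps,
    out_dir,
    panel_size: int = PANEL_SIZE,
    cache: PanelCache | None = None,
) -> pd.DataFrame:
    """Write one PNG per MMP and return the manifest (mmp_id, path, label)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cache = cache or PanelCache()
    rows = []
    n_failed = 0
    for lm in labeled_mmps:
        try:
            img = render_mmp(lm, cache, panel_size=panel_size)
        except DataError as exc:
            logger.warning("skipping %s: %s", lm.mmp_id, exc)
            n_failed += 1
            continue
        path = out_dir / f"{img.mmp_id}.png"
        arr = np.clip(np.rint(img.tensor * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(path)
        rows.append({"mmp_id": img.mmp_id, "path": str(path), "label": lm.label.value})
    if n_failed:
        logger.warning("render_dataset: %d MMP(s) skipped", n_failed)
    manifest = pd.DataFrame(rows, columns=["mmp_id", "path", "label"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_tensor(path) -> np.ndarray:
    """Read a stored composite PNG back into the normalized float form."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"), dtype=np.float32) / 255.0
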