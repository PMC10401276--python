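"""Scene handling: radiometric calibration, background masking, zonal means.

A :class:`Scene` is five co-registered raster planes (blue, green, red,
red edge, NIR) in scene-local metric coordinates — origin at the top-left
corner, x increasing rightwards, y increasing downwards, row-major pixels.
Pixel values are either raw 16-bit digital numbers (DN) or reflectance
fractions; a flag records which, and every downstream operation requires
reflectance.

The path from a scene to the screening stage is:

1. :func:`calibrate` — DN to reflectance through a calibration-panel reading,
2. :func:`train_pixel_classifier` — a supervised per-pixel classifier
   separating corn canopy from soil and weed background,
3. :func:`mask_and_zonal_mean` — per-plot mean reflectance over the pixels
   inside the plot polygon that the classifier retains as corn, plus the
   canopy fraction (retained / total in-polygon pixels).

Plot polygons delimit the harvested middle rows of each subplot and live in
the same scene-local frame; the pixel-in-polygon rule is pixel-center
containment.  No CRS handling or reprojection is done here — inputs are
assumed already stitched and registered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, shape, mapping
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .bands import BAND_NAMES, BandSet

__all__ = [
    "Scene",
    "PlotPolygon",
    "PixelLabelSet",
    "PixelClassifier",
    "CalibrationError",
    "calibrate",
    "train_pixel_classifier",
    "mask_and_zonal_mean",
    "read_scene_tiff",
    "write_scene_tiff",
    "read_plot_polygons",
    "write_plot_polygons",
    "read_pixel_labels",
    "write_pixel_labels",
]

PIXEL_CLASSES = ("corn", "soil", "weed")


class CalibrationError(ValueError):
    pass


@dataclass
class Scene:
    """Five co-registered raster planes with scene-local georeferencing.

    data: float or integer array of shape (5, rows, cols), band order
    blue/green/red/rededge/nir.  pixel_size in metres; origin is the (x, y)
    of the top-left corner of pixel (0, 0).
    """

    data: np.ndarray
    pixel_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    is_reflectance: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] != len(BAND_NAMES):
            raise ValueError(f"scene data must be (5, rows, cols), got {self.data.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.is_reflectance:
            if np.nanmin(self.data) < 0 or np.nanmax(self.data) > 1:
                raise ValueError("reflectance scene values must lie in [0, 1]")
        else:
            if np.nanmin(self.data) < 0 or np.nanmax(self.data) > 65535:
                raise ValueError("DN scene values must lie in [0, 65535]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) scene coordinates of every pixel center, each (rows, cols)."""
        rows, cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.pixel_size
        ys = y0 + (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def bounds(self) -> tuple[float, float, float, float]:
        rows, cols = self.shape
        x0, y0 = self.origin
        return x0, y0, x0 + cols * self.pixel_size, y0 + rows * self.pixel_size


@dataclass(frozen=True)
class PlotPolygon:
    """A digitized plot boundary (the harvested middle rows of one subplot)."""

    plot_id: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError(f"plot {self.plot_id!r}: polygon must be simple with positive area")


@dataclass
class PixelLabelSet:
    """Labelled pixel coordinates for classifier training.

    x, y are scene coordinates of labelled pixel centers; classes are drawn
    from corn/soil/weed.  The minimum per-class count defaults to the field
    protocol's 5,000 and is relaxable for small fixtures.
    """

    x: np.ndarray
    y: np.ndarray
    label: np.ndarray
    min_per_class: int = 5000

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.label = np.asarray(self.label, dtype=object)
        if not (self.x.shape == self.y.shape == self.label.shape):
            raise ValueError("x, y, label must have identical shapes")
        bad = set(self.label) - set(PIXEL_CLASSES)
        if bad:
            raise ValueError(f"unknown pixel classes {sorted(bad)}; allowed {PIXEL_CLASSES}")
        for cls in set(self.label):
            count = int(np.sum(self.label == cls))
            if count < self.min_per_class:
                raise ValueError(
                    f"class {cls!r} has {count} labelled pixels, fewer than the "
                    f"configured minimum {self.min_per_class}")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.label))


# ---------------------------------------------------------------------------
# calibration

def calibrate(scene: Scene, panel_dn: Sequence[float],
              panel_reflectance: Sequence[float]) -> Scene:
    """Convert a DN scene to reflectance via a calibration-panel reading.

    Per band: reflectance = DN * (panel_reflectance / panel_dn), clipped to
    [0, 1].  The panel reading is the mean DN of the reference tile whose
    true reflectance is known per band.
    """
    if scene.is_reflectance:
        raise CalibrationError("scene is already in reflectance units")
    panel_dn = np.asarray(panel_dn, dtype=float)
    panel_reflectance = np.asarray(panel_reflectance, dtype=float)
    if panel_dn.shape != (5,) or panel_reflectance.shape != (5,):
        raise CalibrationError("panel readings must provide one value per band")
    if np.any(panel_dn <= 0):
        raise CalibrationError("panel DN must be positive in every band")
    factors = (panel_reflectance / panel_dn)[:, None, None]
    reflectance = np.clip(scene.data.astype(float) * factors, 0.0, 1.0)
    return Scene(reflectance, scene.pixel_size, scene.origin, is_reflectance=True)


# ---------------------------------------------------------------------------
# per-pixel classification

@dataclass
class PixelClassifier:
    """A fitted 3-class per-pixel classifier over the 5-band feature vector.

    The default learner is a linear maximum-margin classifier on
    standardized bands; the family is pluggable — anything exposing
    fit/predict on (n, 5) arrays satisfies the contract.
    """

    model: object
    classes: tuple[str, ...]
    holdout_accuracy: float
    seed: int = 0

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.predict(np.asarray(features, dtype=float)))


def _features_at(scene: Scene, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    cols = np.floor((np.asarray(x) - scene.origin[0]) / scene.pixel_size).astype(int)
    rows = np.floor((np.asarray(y) - scene.origin[1]) / scene.pixel_size).astype(int)
    nrows, ncols = scene.shape
    if np.any((rows < 0) | (rows >= nrows) | (cols < 0) | (cols >= ncols)):
        raise ValueError("labelled pixel outside the scene")
    return scene.data[:, rows, cols].T.astype(float)


def train_pixel_classifier(scene: Scene, labels: PixelLabelSet,
                           holdout_fraction: float = 0.2,
                           seed: int = 0) -> PixelClassifier:
    """Fit the corn/soil/weed per-pixel classifier and report holdout accuracy.

    A stratified holdout split (default 20%) estimates accuracy; the model
    is then kept as fitted on the training split so the reported accuracy
    refers to exactly the model returned.  Deterministic given seed.
    """
    if not scene.is_reflectance:
        raise ValueError("classifier expects a reflectance scene; calibrate first")
    if len(labels.classes) < 2:
        raise ValueError("need labelled pixels from at least two classes")
    features = _features_at(scene, labels.x, labels.y)
    target = labels.label.astype(str)
    x_train, x_test, y_train, y_test = train_test_split(
        features, target, test_size=holdout_fraction, random_state=seed,
        stratify=target)
    model = make_pipeline(
        StandardScaler(),
        LinearSVC(C=1.0, random_state=seed, max_iter=5000, dual="auto"),
    )
    model.fit(x_train, y_train)
    accuracy = float(np.mean(model.predict(x_test) == y_test))
    return PixelClassifier(model=model, classes=tuple(sorted(set(target))),
                           holdout_accuracy=accuracy, seed=seed)


# ---------------------------------------------------------------------------
# zonal statistics

def mask_and_zonal_mean(scene: Scene, classifier: PixelClassifier,
                        polygons: Sequence[PlotPolygon], keep_class: str = "corn"
                        ) -> dict[str, tuple[BandSet | None, float]]:
    """Per-plot mean reflectance over in-polygon pixels classified as ``keep_class``.

    Returns ``plot_id -> (BandSet | None, canopy_fraction)`` where
    canopy_fraction = retained pixels / in-polygon pixels.  A plot whose
    polygon contains no retained pixel yields ``(None, 0.0)``; a polygon
    that does not intersect the scene raises, naming the plot.
    """
    if not scene.is_reflectance:
        raise ValueError("zonal means require a reflectance scene")
    xs, ys = scene.pixel_centers()
    out: dict[str, tuple[BandSet | None, float]] = {}
    scene_box = shapely.box(*scene.bounds())
    for plot in polygons:
        if not plot.polygon.intersects(scene_box):
            raise ValueError(f"plot {plot.plot_id!r}: polygon outside the scene")
        minx, miny, maxx, maxy = plot.polygon.bounds
        c0 = max(0, int((minx - scene.origin[0]) / scene.pixel_size) - 1)
        c1 = min(scene.shape[1], int(np.ceil((maxx - scene.origin[0]) / scene.pixel_size)) + 1)
        r0 = max(0, int((miny - scene.origin[1]) / scene.pixel_size) - 1)
        r1 = min(scene.shape[0], int(np.ceil((maxy - scene.origin[1]) / scene.pixel_size)) + 1)
        sub_x, sub_y = xs[r0:r1, c0:c1], ys[r0:r1, c0:c1]
        inside = shapely.contains_xy(plot.polygon, sub_x.ravel(), sub_y.ravel())
        n_inside = int(inside.sum())
        if n_inside == 0:
            out[plot.plot_id] = (None, 0.0)
            continue
        rr, cc = np.nonzero(inside.reshape(sub_x.shape))
        rr, cc = rr + r0, cc + c0
        features = scene.data[:, rr, cc].T.astype(float)
        kept = classifier.predict(features) == keep_class
        n_kept = int(kept.sum())
        if n_kept == 0:
            out[plot.plot_id] = (None, 0.0)
            continue
        means = features[kept].mean(axis=0)
        out[plot.plot_id] = (
            BandSet(**dict(zip(BAND_NAMES, np.clip(means, 0.0, 1.0)))),
            n_kept / n_inside,
        )
    return out


# ---------------------------------------------------------------------------
# I/O: 5-band TIFF scenes, GeoJSON plot polygons, CSV pixel labels

def write_scene_tiff(scene: Scene, path: str | Path) -> None:
    import tifffile

    meta = {"pixel_size": scene.pixel_size, "origin": list(scene.origin),
            "is_reflectance": scene.is_reflectance, "bands": list(BAND_NAMES)}
    tifffile.imwrite(path, scene.data, photometric="minisblack",
                     description=json.dumps(meta))


def read_scene_tiff(path: str | Path) -> Scene:
    import tifffile

    with tifffile.TiffFile(path) as handle:
        data = handle.asarray()
        desc = handle.pages[0].description or "{}"
    meta = json.loads(desc)
    return Scene(data, pixel_size=float(meta.get("pixel_size", 1.0)),
                 origin=tuple(meta.get("origin", (0.0, 0.0))),
                 is_reflectance=bool(meta.get("is_reflectance", True)))


def write_plot_polygons(polygons: Sequence[PlotPolygon], path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {"plot_id": p.plot_id},
         "geometry": mapping(p.polygon)}
        for p in polygons
    ]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))


def read_plot_polygons(path: str | Path) -> list[PlotPolygon]:
    collection = json.loads(Path(path).read_text())
    return [
        PlotPolygon(str(feat["properties"]["plot_id"]), shape(feat["geometry"]))
        for feat in collection["features"]
    ]


def write_pixel_labels(labels: PixelLabelSet, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame({"x": labels.x, "y": labels.y, "class": labels.label}).to_csv(
        path, index=False)


def read_pixel_labels(path: str | Path, min_per_class: int = 5000) -> PixelLabelSet:
    import pandas as pd

    frame = pd.read_csv(path)
    return PixelLabelSet(frame["x"].to_numpy(), frame["y"].to_numpy(),
                         frame["class"].to_numpy(), min_per_class=min_per_class)
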