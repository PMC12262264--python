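"""Point patterns, observation windows and the image/patient/cohort design.

Coordinates are continuous, in micrometres, with the origin at the lower
left corner of the (axis-aligned, rectangular) observation window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation window [x_min,x_max]x[y_min,y_max] (μm)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("window must have positive side lengths")

    @staticmethod
    def square(side: float) -> "Window":
        return Window(0.0, float(side), 0.0, float(side))

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def contains(self, coords: np.ndarray) -> np.ndarray:
        c = np.atleast_2d(coords)
        return ((c[:, 0] >= self.x_min) & (c[:, 0] <= self.x_max)
                & (c[:, 1] >= self.y_min) & (c[:, 1] <= self.y_max))

    def boundary_distance(self, coords: np.ndarray) -> np.ndarray:
        """Distance from each point to the nearest window edge."""
        c = np.atleast_2d(coords)
        return np.minimum.reduce([c[:, 0] - self.x_min, self.x_max - c[:, 0],
                                  c[:, 1] - self.y_min, self.y_max - c[:, 1]])

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        xy = rng.random((n, 2))
        xy[:, 0] = self.x_min + xy[:, 0] * (self.x_max - self.x_min)
        xy[:, 1] = self.y_min + xy[:, 1] * (self.y_max - self.y_min)
        return xy


@dataclass
class PointPattern:
    """A multitype planar point pattern: one image's cells.

    ``coords`` is an (n, 2) float array of μm locations, ``types`` a length-n
    array of categorical labels drawn from ``type_set``. Empty patterns are
    allowed; every coordinate must lie inside ``window``.
    """

    coords: np.ndarray
    types: np.ndarray
    window: Window
    type_set: tuple[str, ...] = field(default=())

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        self.types = np.asarray(self.types, dtype=object).reshape(-1)
        if self.coords.shape[0] != self.types.shape[0]:
            raise ValueError("coords and types must have equal length")
        if self.coords.size and not np.all(self.window.contains(self.coords)):
            raise ValueError("all coordinates must lie inside the window")
        if not self.type_set:
            self.type_set = tuple(sorted(set(self.types.tolist())))
        else:
            extra = set(self.types.tolist()) - set(self.type_set)
            if extra:
                raise ValueError(f"types {sorted(extra)} not in declared type set")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def subset(self, cell_type: str) -> "PointPattern":
        """Single-type sub-pattern (same window)."""
        mask = self.types == cell_type
        return PointPattern(self.coords[mask], self.types[mask], self.window,
                            type_set=(cell_type,))

    def counts(self) -> dict[str, int]:
        return {t: int(np.sum(self.types == t)) for t in self.type_set}

    @staticmethod
    def from_coords(coords, window: Window, cell_type: str = "cell") -> "PointPattern":
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        return PointPattern(coords, np.full(coords.shape[0], cell_type, dtype=object),
                            window, type_set=(cell_type,))


@dataclass(frozen=True)
class StudyDesign:
    """The image -> patient -> cohort hierarchy.

    ``image_patient[m]`` is the patient index of image m; ``patient_cohort[n]``
    the cohort index of patient n. Id tuples carry the external labels.
    """

    image_ids: tuple
    patient_ids: tuple
    cohort_ids: tuple
    image_patient: np.ndarray
    patient_cohort: np.ndarray

    def __post_init__(self):
        ip = np.asarray(self.image_patient, dtype=int)
        pc = np.asarray(self.patient_cohort, dtype=int)
        if ip.shape != (len(self.image_ids),) or pc.shape != (len(self.patient_ids),):
            raise ValueError("hierarchy maps inconsistent with id lists")
        if ip.size and (ip.min() < 0 or ip.max() >= len(self.patient_ids)):
            raise ValueError("image_patient out of range")
        if pc.size and (pc.min() < 0 or pc.max() >= len(self.cohort_ids)):
            raise ValueError("patient_cohort out of range")
        object.__setattr__(self, "image_patient", ip)
        object.__setattr__(self, "patient_cohort", pc)

    @property
    def n_images(self) -> int:
        return len(self.image_ids)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_ids)

    @property
    def image_cohort(self) -> np.ndarray:
        return self.patient_cohort[self.image_patient]

    def image_index(self, image_id) -> int:
        return self.image_ids.index(image_id)

    def patient_index(self, patient_id) -> int:
        return self.patient_ids.index(patient_id)

    def cohort_index(self, cohort_id) -> int:
        return self.cohort_ids.index(cohort_id)

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "StudyDesign":
        """Build the hierarchy from rows with image_id, patient_id, group_id columns."""
        trip = df[["image_id", "patient_id", "group_id"]].drop_duplicates()
        if trip["image_id"].duplicated().any():
            raise ValueError("an image maps to more than one patient/group")
        pp = trip[["patient_id", "group_id"]].drop_duplicates()
        if pp["patient_id"].duplicated().any():
            raise ValueError("a patient maps to more than one group")
        image_ids = tuple(trip["image_id"])
        patient_ids = tuple(pp["patient_id"])
        cohort_ids = tuple(dict.fromkeys(pp["group_id"]))
        p_index = {p: i for i, p in enumerate(patient_ids)}
        c_index = {c: i for i, c in enumerate(cohort_ids)}
        image_patient = np.array([p_index[p] for p in trip["patient_id"]])
        patient_cohort = np.array([c_index[c] for c in pp["group_id"]])
        return StudyDesign(image_ids, patient_ids, cohort_ids,
                           image_patient, patient_cohort)


# ---------------------------------------------------------------------- I/O

POINT_COLUMNS = ["x", "y", "cell_type", "image_id", "patient_id", "group_id"]


def read_patterns_csv(points_path, windows_path=None
                      ) -> tuple[dict, StudyDesign]:
    """Read per-image point patterns and the study hierarchy from CSV.

    The points CSV must have columns x, y, cell_type, image_id, patient_id,
    group_id (μm units). ``windows_path``, if given, is a per-image metadata
    CSV with columns image_id, x_min, x_max, y_min, y_max (or image_id,
    width, height for lower-left-origin windows). When absent, each image's
    window is inferred as the bounding box of its points (logged as a
    warning, since this truncates the true field of view).

    Returns ``(patterns, design)`` where patterns maps image_id -> PointPattern.
    """
    df = pd.read_csv(points_path)
    missing = [c for c in POINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"points CSV missing required columns: {missing}")
    windows: dict = {}
    if windows_path is not None:
        wdf = pd.read_csv(windows_path)
        for _, row in wdf.iterrows():
            if {"x_min", "x_max", "y_min", "y_max"} <= set(wdf.columns):
                w = Window(row["x_min"], row["x_max"], row["y_min"], row["y_max"])
            else:
                w = Window(0.0, row["width"], 0.0, row["height"])
            windows[row["image_id"]] = w
    design = StudyDesign.from_frame(df)
    patterns = {}
    for image_id, sub in df.groupby("image_id", sort=False):
        coords = sub[["x", "y"]].to_numpy(dtype=float)
        if image_id in windows:
            w = windows[image_id]
        else:
            warnings.warn(f"no window metadata for image {image_id!r}; "
                          "using the bounding box of its points", stacklevel=2)
            w = Window(coords[:, 0].min(), coords[:, 0].max(),
                       coords[:, 1].min(), coords[:, 1].max())
        patterns[image_id] = PointPattern(coords, sub["cell_type"].to_numpy(object), w)
    return patterns, design


def write_patterns_csv(patterns: dict, design: StudyDesign, points_path,
                       windows_path=None) -> None:
    """Write per-image patterns (+hierarchy) to the CSV layout read_patterns_csv expects."""
    rows = []
    for m, image_id in enumerate(design.image_ids):
        pat = patterns[image_id]
        patient_id = design.patient_ids[design.image_patient[m]]
        group_id = design.cohort_ids[design.patient_cohort[design.image_patient[m]]]
        for (x, y), t in zip(pat.coords, pat.types):
            rows.append((x, y, t, image_id, patient_id, group_id))
    pd.DataFrame(rows, columns=POINT_COLUMNS).to_csv(points_path, index=False)
    if windows_path is not None:
        wrows = [(iid, patterns[iid].window.x_min, patterns[iid].window.x_max,
                  patterns[iid].window.y_min, patterns[iid].window.y_max)
                 for iid in design.image_ids]
        pd.DataFrame(wrows, columns=["image_id", "x_min", "x_max", "y_min", "y_max"]
                     ).to_csv(windows_path, index=False)
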