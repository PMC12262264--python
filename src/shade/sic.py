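"""Spatial interaction curves and their posterior summaries.

A SIC gives, for each distance s, the expected contribution of one source
cell at distance s to the log-intensity of the target type:
``SIC(s) = sum_p c_p phi_p(s)``. Positive values indicate attraction
(clustering), negative values repulsion. Curves exist at the image,
patient and cohort level of the hierarchy; per-draw curves are exact
linear images of the coefficient draws, so posterior bands follow by
pointwise quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import BasisSpec, eval_basis
from .model import PosteriorDraws

DEFAULT_DISTANCES = np.arange(0.0, 151.0, 1.0)  # μm


@dataclass
class SICCurve:
    """Posterior draws of one spatial interaction curve on a distance grid."""

    distances: np.ndarray         # (n_d,)
    draws: np.ndarray             # (S, n_d) log-intensity contributions
    level: str
    unit_id: object
    source: str

    @property
    def median(self) -> np.ndarray:
        return np.median(self.draws, axis=0)

    @property
    def lower(self) -> np.ndarray:
        return np.quantile(self.draws, 0.025, axis=0)

    @property
    def upper(self) -> np.ndarray:
        return np.quantile(self.draws, 0.975, axis=0)

    def band(self, distance: float) -> tuple[float, float]:
        """Interpolated (lower, upper) 95% credible bounds at one distance."""
        lo = float(np.interp(distance, self.distances, self.lower))
        hi = float(np.interp(distance, self.distances, self.upper))
        return lo, hi

    def to_frame(self, target: str = "target") -> pd.DataFrame:
        return pd.DataFrame({
            "level": self.level, "unit": self.unit_id, "source": self.source,
            "target": target, "distance": self.distances,
            "median": self.median, "lo95": self.lower, "hi95": self.upper,
        })


def sic_curve(draws: PosteriorDraws, spec: BasisSpec, level: str, unit_id,
              source: str, distances=None) -> SICCurve:
    """Reconstruct the posterior SIC for one unit at one hierarchy level.

    Per draw, the curve is the exact linear combination of that draw's
    coefficients with the basis evaluated on the distance grid.
    """
    distances = DEFAULT_DISTANCES if distances is None else np.asarray(distances, float)
    if distances.size and distances.max() > 2 * spec.r_max:
        warnings.warn("distances extend beyond 2*r_max; the curve is identically "
                      "zero out there for compactly supported bases", stacklevel=2)
    coeff = draws.coefficients(level, unit_id, source)  # (S, P)
    phi = eval_basis(spec, distances)                   # (n_d, P)
    return SICCurve(distances=distances, draws=coeff @ phi.T,
                    level=level, unit_id=unit_id, source=source)


def sign_detection(curve: SICCurve, test_distances) -> list[str]:
    """Classify the interaction sign at each test distance from the 95% band.

    "positive" if the credible interval's lower bound exceeds 0, "negative"
    if its upper bound is below 0, otherwise "undetected".
    """
    test_distances = np.atleast_1d(np.asarray(test_distances, float))
    if (test_distances.min() < curve.distances.min()
            or test_distances.max() > curve.distances.max()):
        raise ValueError("test distances must lie within the curve's grid range")
    labels = []
    for s in test_distances:
        lo, hi = curve.band(s)
        labels.append("positive" if lo > 0 else "negative" if hi < 0 else "undetected")
    return labels


@dataclass
class GroupDifferenceCurve:
    """Posterior difference of two cohort-level SICs, with flagged ranges."""

    distances: np.ndarray
    draws: np.ndarray            # (S, n_d): cohort_a minus cohort_b
    cohort_a: object
    cohort_b: object
    source: str
    threshold: float

    @property
    def median(self) -> np.ndarray:
        return np.median(self.draws, axis=0)

    @property
    def flags(self) -> np.ndarray:
        return np.abs(self.median) > self.threshold

    @property
    def flagged_ranges(self) -> list[tuple[float, float]]:
        """Contiguous distance intervals where |median difference| > threshold."""
        f = self.flags
        ranges = []
        start = None
        for i, on in enumerate(f):
            if on and start is None:
                start = self.distances[i]
            elif not on and start is not None:
                ranges.append((float(start), float(self.distances[i - 1])))
                start = None
        if start is not None:
            ranges.append((float(start), float(self.distances[-1])))
        return ranges


def group_difference(draws: PosteriorDraws, spec: BasisSpec, cohort_a, cohort_b,
                     source: str, distances=None,
                     threshold: float = 0.05) -> GroupDifferenceCurve:
    """Per-draw difference of cohort-level SICs (a minus b) with flagging.

    Distances where the absolute posterior median difference in
    log-intensity exceeds ``threshold`` (default 0.05) are flagged.
    """
    distances = DEFAULT_DISTANCES if distances is None else np.asarray(distances, float)
    for c in (cohort_a, cohort_b):
        if c not in draws.design_meta.cohort_ids:
            raise ValueError(f"unknown cohort {c!r}")
    ca = sic_curve(draws, spec, "cohort", cohort_a, source, distances)
    cb = sic_curve(draws, spec, "cohort", cohort_b, source, distances)
    return GroupDifferenceCurve(distances=distances, draws=ca.draws - cb.draws,
                                cohort_a=cohort_a, cohort_b=cohort_b,
                                source=source, threshold=threshold)


def mad(values: np.ndarray, axis=0, consistency: float = 1.0) -> np.ndarray:
    """Median absolute deviation from the median (unscaled by default)."""
    med = np.median(values, axis=axis, keepdims=True)
    return consistency * np.median(np.abs(values - med), axis=axis)


@dataclass
class HeterogeneityMAD:
    """Distance-resolved between-patient and between-image spread of SICs."""

    distances: np.ndarray
    between_patient: np.ndarray   # (n_d,)
    between_image: np.ndarray     # (n_d,)
    source: str

    @property
    def between_patient_mean(self) -> float:
        return float(self.between_patient.mean())

    @property
    def between_image_mean(self) -> float:
        return float(self.between_image.mean())

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (source, level, distance, mad) for heatmap export."""
        frames = []
        for level, values in (("between_patient", self.between_patient),
                              ("between_image", self.between_image)):
            frames.append(pd.DataFrame({"source": self.source, "level": level,
                                        "distance": self.distances, "mad": values}))
        return pd.concat(frames, ignore_index=True)


def heterogeneity_mad(draws: PosteriorDraws, spec: BasisSpec, distances=None,
                      source: str | None = None, consistency: float = 1.0,
                      use_posterior_draws: bool = False) -> dict[str, HeterogeneityMAD]:
    """Between-patient and between-image MAD of posterior-median SICs.

    Between-patient MAD at s: the MAD over patients (within each cohort) of
    patient-level posterior-median SIC values, averaged over cohorts.
    Between-image MAD at s: the MAD over a patient's image-level
    posterior-median SICs, averaged over patients. Requires >= 2 patients
    in some cohort and >= 2 images for some patient.

    With ``use_posterior_draws`` the MAD is computed per posterior draw and
    averaged, giving the posterior mean of the MAD instead of the MAD of
    point estimates.
    """
    meta = draws.design_meta
    if meta is None:
        raise ValueError("heterogeneity requires a hierarchical fit")
    distances = DEFAULT_DISTANCES if distances is None else np.asarray(distances, float)
    phi = eval_basis(spec, distances)
    sources = [source] if source is not None else list(draws.source_types)

    def _unit_curves(level, unit_ids, src):
        rows = []
        for u in unit_ids:
            c = draws.coefficients(level, u, src) @ phi.T
            rows.append(c if use_posterior_draws else np.median(c, axis=0))
        return np.stack(rows)  # (U, n_d) or (U, S, n_d)

    out = {}
    for src in sources:
        # between patients within cohort, averaged over cohorts
        per_cohort = []
        for g, cid in enumerate(meta.cohort_ids):
            pts = [meta.patient_ids[n] for n in range(meta.n_patients)
                   if meta.patient_cohort[n] == g]
            if len(pts) >= 2:
                curves = _unit_curves("patient", pts, src)
                m = mad(curves, axis=0, consistency=consistency)
                per_cohort.append(m.mean(axis=0) if use_posterior_draws else m)
        if not per_cohort:
            raise ValueError("between-patient MAD needs >= 2 patients in some cohort")
        bp = np.mean(per_cohort, axis=0)
        # between images within patient, averaged over patients
        per_patient = []
        for n, pid in enumerate(meta.patient_ids):
            imgs = [iid for m_i, iid in enumerate(draws.image_ids)
                    if meta.image_patient[meta.image_index(iid)] == n]
            if len(imgs) >= 2:
                curves = _unit_curves("image", imgs, src)
                m = mad(curves, axis=0, consistency=consistency)
                per_patient.append(m.mean(axis=0) if use_posterior_draws else m)
        if not per_patient:
            raise ValueError("between-image MAD needs >= 2 images for some patient")
        bi = np.mean(per_patient, axis=0)
        out[src] = HeterogeneityMAD(distances=distances, between_patient=bp,
                                    between_image=bi, source=src)
    return out


def curves_to_frame(curves: list[SICCurve], target: str = "target") -> pd.DataFrame:
    """Tidy CSV-ready table of curve summaries."""
    return pd.concat([c.to_frame(target) for c in curves], ignore_index=True)
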