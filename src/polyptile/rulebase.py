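"""Fuzzy rulebase construction from training-set feature histograms.

Each active antecedent gets one triangular membership function per consequent
class (polyp / no_polyp), fitted to the empirical distribution of that
antecedent over the training tiles of that class.  Three fit modes exist:

* ``mean``      -- triangle (min, mean, max) of the values,
* ``median``    -- triangle (min, median, max),
* ``histogram`` -- core at the centre of the tallest histogram bin; support
  endpoints at the centres of the first bins from each side whose count,
  normalised so the tallest bin is 1, exceeds 0.01.

The histogram fit is what makes sparse, heavy-tailed antecedent
distributions usable: the support hugs the bulk of the data instead of being
stretched by outliers.  Triangles may additionally be replaced by Gaussian or
two-sided half-Gaussian bells that agree with the triangle at its
characteristic points but stay strictly positive on the whole axis, so a
Mamdani system never sees an observation with zero membership everywhere.

Antecedent selection compares the polyp and no_polyp triangles of each
antecedent on a min-max normalised [0, 1] scale: the *total distance* is the
summed absolute offset of the three characteristic points, the *centre
distance* that of the cores alone.  Antecedents whose triangles are very
narrow carry almost no overlap with observations and empirically hurt the
classification, so they can be pruned by a minimum normalised support width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .features import ANTECEDENT_NAMES

#: Membership level at which an extended support matches the triangle ends.
SUPPORT_LEVEL = 0.01

RULEBASE_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class TriangularMF:
    """Triangle with support [left, right] and membership 1 at ``core``."""

    left: float
    core: float
    right: float
    degenerate: bool = False

    def __post_init__(self):
        if not self.left <= self.core <= self.right:
            raise ValueError(
                f"triangle points must be ordered: {self.left}, "
                f"{self.core}, {self.right}"
            )

    @property
    def width(self) -> float:
        return self.right - self.left

    def __call__(self, x: float) -> float:
        if x < self.left or x > self.right:
            return 0.0
        if x == self.core:
            return 1.0
        if x < self.core:
            return (x - self.left) / (self.core - self.left)
        return (self.right - x) / (self.right - self.core)

    def scaled(self, lo: float, hi: float) -> "TriangularMF":
        """Affine image of the triangle under min-max scaling by [lo, hi]."""
        span = hi - lo if hi > lo else 1.0
        return TriangularMF((self.left - lo) / span, (self.core - lo) / span,
                            (self.right - lo) / span, self.degenerate)


@dataclass(frozen=True)
class ExtendedMF:
    """A triangle, optionally smoothed into a (half-)Gaussian bell.

    ``gaussian`` uses a single width chosen so that membership at the two
    support ends is as close as possible (least squares) to
    :data:`SUPPORT_LEVEL`; ``half_gaussian`` uses separate left and right
    widths so both ends are matched exactly even for skew triangles.  Both
    kinds are strictly positive everywhere, unlike the raw triangle.
    """

    base: TriangularMF
    kind: str = "triangle"
    sigma_left: Optional[float] = None
    sigma_right: Optional[float] = None

    def __call__(self, x: float) -> float:
        if self.kind == "triangle":
            return self.base(x)
        dx = x - self.base.core
        sigma = self.sigma_left if dx < 0 else self.sigma_right
        return float(np.exp(-dx * dx / (2.0 * sigma * sigma)))

    def scaled(self, lo: float, hi: float) -> "ExtendedMF":
        span = hi - lo if hi > lo else 1.0
        sl = None if self.sigma_left is None else self.sigma_left / span
        sr = None if self.sigma_right is None else self.sigma_right / span
        return ExtendedMF(self.base.scaled(lo, hi), self.kind, sl, sr)


@dataclass
class HistogramModel:
    """Equal-width histogram with counts normalised so the tallest bin is 1."""

    bin_edges: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray
    degenerate: bool = False

    @property
    def centers(self) -> np.ndarray:
        edges = np.asarray(self.bin_edges, dtype=float)
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass(frozen=True)
class Rule:
    """One fuzzy rule: IF antecedent i is ``mf`` THEN class ``consequent``."""

    antecedent_index: int
    consequent: str
    mf: ExtendedMF
    fit_mode: str = "histogram"


@dataclass
class Rulebase:
    """All rules plus the frozen training-set min-max normalisation.

    ``rules[(index, consequent)]`` maps each active 1-based antecedent index
    and class name to its rule; ``normalization[index]`` holds the pooled
    training (min, max) of the antecedent, frozen at fit time and reused
    unchanged on test data.
    """

    rules: Dict = field(default_factory=dict)
    active_antecedents: tuple = ()
    normalization: Dict = field(default_factory=dict)
    fit_mode: str = "histogram"
    extension_kind: str = "triangle"
    histogram_bins: int = 100

    CONSEQUENTS = ("polyp", "no_polyp")

    def rule(self, index: int, consequent: str) -> Rule:
        try:
            return self.rules[(index, consequent)]
        except KeyError:
            raise ValueError(
                f"no {consequent!r} rule for antecedent {index}"
            ) from None

    def scaled_mf(self, index: int, consequent: str) -> ExtendedMF:
        lo, hi = self.normalization[index]
        return self.rule(index, consequent).mf.scaled(lo, hi)

    def normalize_value(self, index: int, x: float) -> float:
        lo, hi = self.normalization[index]
        span = hi - lo if hi > lo else 1.0
        return (x - lo) / span

    def with_active(self, indices: Sequence[int]) -> "Rulebase":
        """A view restricted to ``indices`` (must all carry rules)."""
        idx = tuple(int(i) for i in indices)
        for i in idx:
            for c in self.CONSEQUENTS:
                self.rule(i, c)  # raises if missing
        return replace(self, active_antecedents=idx)


# --------------------------------------------------------------------------
# Histogram and triangle fitting
# --------------------------------------------------------------------------

def build_histogram(values: Sequence[float], bins: int = 100) -> HistogramModel:
    """Equal-width histogram over [min, max], tallest bin scaled to 1."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot histogram an empty sample")
    if bins <= 0:
        raise ValueError("bins must be positive")
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:
        return HistogramModel(
            bin_edges=np.array([lo, hi]),
            counts=np.array([arr.size]),
            normalized=np.array([1.0]),
            degenerate=True,
        )
    counts, edges = np.histogram(arr, bins=bins, range=(lo, hi))
    return HistogramModel(bin_edges=edges, counts=counts,
                          normalized=counts / counts.max())


def fit_triangle(values: Sequence[float],
                 hist: Optional[HistogramModel] = None,
                 mode: str = "histogram",
                 bins: int = 100) -> TriangularMF:
    """Fit a triangular membership function to a sample.

    ``mean`` / ``median`` span the full data range with the core at the
    sample mean / median.  ``histogram`` places the core at the centre of the
    tallest bin and the support ends at the centres of the outermost bins
    whose normalised height exceeds :data:`SUPPORT_LEVEL`, scanning inward
    from each side.  Ties for the tallest bin resolve to the leftmost.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot fit a triangle to an empty sample")
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:
        return TriangularMF(lo, lo, lo, degenerate=True)
    if mode == "mean":
        return TriangularMF(lo, float(arr.mean()), hi)
    if mode == "median":
        return TriangularMF(lo, float(np.median(arr)), hi)
    if mode != "histogram":
        raise ValueError(f"unknown fit mode {mode!r}")
    if hist is None:
        hist = build_histogram(arr, bins=bins)
    if hist.degenerate:
        c = hist.centers[0] if hist.centers.size else lo
        return TriangularMF(c, c, c, degenerate=True)
    centers = hist.centers
    above = np.nonzero(hist.normalized > SUPPORT_LEVEL)[0]
    left = centers[above[0]]
    right = centers[above[-1]]
    core = centers[int(np.argmax(hist.normalized))]
    if not left <= core <= right:  # can only happen with exotic histograms
        core = min(max(core, left), right)
        return TriangularMF(left, core, right, degenerate=True)
    return TriangularMF(left, core, right)


def extend_support(mf: TriangularMF, kind: str = "triangle") -> ExtendedMF:
    """Wrap a triangle as-is, or smooth it into a (half-)Gaussian bell.

    Gaussian kinds pin the bell's peak at the core and choose widths so the
    membership at the triangle's support ends equals :data:`SUPPORT_LEVEL`
    (exactly for ``half_gaussian``; in least squares for the single-width
    ``gaussian``).
    """
    if kind == "triangle":
        return ExtendedMF(base=mf, kind="triangle")
    if kind not in ("gaussian", "half_gaussian"):
        raise ValueError(f"unknown extension kind {kind!r}")
    dl = mf.core - mf.left
    dr = mf.right - mf.core
    if dl <= 0 and dr <= 0:
        raise ValueError("cannot fit a Gaussian to a degenerate triangle")
    scale = np.sqrt(2.0 * np.log(1.0 / SUPPORT_LEVEL))
    if kind == "half_gaussian":
        sl = dl / scale if dl > 0 else (dr / scale)
        sr = dr / scale if dr > 0 else (dl / scale)
        return ExtendedMF(base=mf, kind="half_gaussian",
                          sigma_left=sl, sigma_right=sr)
    # single-width gaussian: least squares on the two boundary conditions
    # mu(left) = mu(right) = SUPPORT_LEVEL in terms of t = 1 / (2 sigma^2)
    from scipy.optimize import minimize_scalar

    d2 = np.array([dl * dl, dr * dr])
    d2 = d2[d2 > 0]

    def loss(log_t):
        t = np.exp(log_t)
        return float(((np.exp(-d2 * t) - SUPPORT_LEVEL) ** 2).sum())

    t0 = scale ** 2 / (2.0 * d2.mean())
    res = minimize_scalar(loss, bracket=(np.log(t0) - 3, np.log(t0) + 3))
    sigma = float(1.0 / np.sqrt(2.0 * np.exp(res.x)))
    return ExtendedMF(base=mf, kind="gaussian",
                      sigma_left=sigma, sigma_right=sigma)


# --------------------------------------------------------------------------
# Rulebase training and antecedent selection
# --------------------------------------------------------------------------

def train_rulebase(features: pd.DataFrame,
                   mode: str = "histogram",
                   bins: int = 100,
                   extension_kind: str = "triangle",
                   label_column: str = "label") -> Rulebase:
    """Fit one rule per (antecedent, consequent) from a labelled feature table.

    ``features`` must contain the 99 antecedent columns (named as in
    :data:`polyptile.features.ANTECEDENT_NAMES`) and a label column with both
    classes present.  Min-max normalisation constants come from the pooled
    training values and are frozen into the returned rulebase.  Deterministic:
    identical tables give identical rulebases.
    """
    labels = features[label_column].astype(str)
    for consequent in Rulebase.CONSEQUENTS:
        if not (labels == consequent).any():
            raise ValueError(
                f"training data has no {consequent!r} tiles; both classes "
                "are required to fit a rulebase"
            )
    present = [n for n in ANTECEDENT_NAMES if n in features.columns]
    if len(present) != 99:
        missing = sorted(set(ANTECEDENT_NAMES) - set(present))
        raise ValueError(f"feature table lacks antecedent columns {missing[:5]} ...")

    rb = Rulebase(fit_mode=mode, extension_kind=extension_kind,
                  histogram_bins=bins)
    active = []
    for idx1, name in enumerate(ANTECEDENT_NAMES, start=1):
        col = features[name].to_numpy(dtype=float)
        rb.normalization[idx1] = (float(col.min()), float(col.max()))
        for consequent in Rulebase.CONSEQUENTS:
            vals = col[(labels == consequent).to_numpy()]
            tri = fit_triangle(vals, mode=mode, bins=bins)
            if extension_kind != "triangle" and not tri.degenerate:
                mf = extend_support(tri, extension_kind)
            else:
                mf = ExtendedMF(base=tri, kind="triangle")
            rb.rules[(idx1, consequent)] = Rule(
                antecedent_index=idx1, consequent=consequent,
                mf=mf, fit_mode=mode,
            )
        active.append(idx1)
    rb.active_antecedents = tuple(active)
    return rb


def _normalized_triangles(rb: Rulebase, index: int) -> tuple:
    lo, hi = rb.normalization[index]
    tp = rb.rule(index, "polyp").mf.base.scaled(lo, hi)
    tn = rb.rule(index, "no_polyp").mf.base.scaled(lo, hi)
    return tp, tn


def antecedent_total_distance(rb: Rulebase, index: int) -> float:
    """Summed |offset| of the three characteristic points, on [0, 1] scale."""
    tp, tn = _normalized_triangles(rb, index)
    return (abs(tp.left - tn.left) + abs(tp.core - tn.core)
            + abs(tp.right - tn.right))


def antecedent_center_distance(rb: Rulebase, index: int) -> float:
    """|core_polyp - core_no_polyp| on the normalised scale."""
    tp, tn = _normalized_triangles(rb, index)
    return abs(tp.core - tn.core)


def select_by_distance(rb: Rulebase, threshold: float,
                       metric: str = "total") -> Rulebase:
    """Restrict the rulebase to antecedents whose class triangles differ.

    ``metric='total'`` uses :func:`antecedent_total_distance`, ``'center'``
    uses :func:`antecedent_center_distance`; antecedents strictly above
    ``threshold`` stay active, ordered by decreasing distance.
    """
    fn = {"total": antecedent_total_distance,
          "center": antecedent_center_distance}.get(metric)
    if fn is None:
        raise ValueError(f"unknown distance metric {metric!r}")
    dist = {i: fn(rb, i) for i in rb.active_antecedents}
    keep = sorted((i for i, d in dist.items() if d > threshold),
                  key=lambda i: -dist[i])
    if not keep:
        raise ValueError("distance threshold deactivates every antecedent")
    return rb.with_active(keep)


def prune_narrow(rb: Rulebase, min_width: float = 0.05) -> Rulebase:
    """Drop antecedents whose normalised support is very narrow for either class.

    Narrow triangle rules rarely overlap observations and degrade the
    classification even under rule interpolation, so they are removed.
    """
    if not 0 < min_width < 1:
        raise ValueError("min_width must lie in (0, 1)")
    keep = []
    for i in rb.active_antecedents:
        tp, tn = _normalized_triangles(rb, i)
        if tp.width >= min_width and tn.width >= min_width:
            keep.append(i)
    if not keep:
        raise ValueError("pruning removed every antecedent")
    return rb.with_active(keep)


# --------------------------------------------------------------------------
# Serialization (versioned JSON schema; lossless round trip)
# --------------------------------------------------------------------------

def _mf_to_dict(mf: ExtendedMF) -> dict:
    return {
        "kind": mf.kind,
        "left": mf.base.left, "core": mf.base.core, "right": mf.base.right,
        "degenerate": mf.base.degenerate,
        "sigma_left": mf.sigma_left, "sigma_right": mf.sigma_right,
    }


def _mf_from_dict(d: dict) -> ExtendedMF:
    tri = TriangularMF(d["left"], d["core"], d["right"],
                       degenerate=d.get("degenerate", False))
    return ExtendedMF(base=tri, kind=d["kind"],
                      sigma_left=d.get("sigma_left"),
                      sigma_right=d.get("sigma_right"))


def save_rulebase(rb: Rulebase, path) -> None:
    doc = {
        "schema_version": RULEBASE_SCHEMA_VERSION,
        "fit_mode": rb.fit_mode,
        "extension_kind": rb.extension_kind,
        "histogram_bins": rb.histogram_bins,
        "active_antecedents": list(rb.active_antecedents),
        "normalization": {str(i): list(v) for i, v in rb.normalization.items()},
        "rules": [
            {"antecedent_index": r.antecedent_index,
             "consequent": r.consequent,
             "fit_mode": r.fit_mode,
             "mf": _mf_to_dict(r.mf)}
            for r in rb.rules.values()
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_rulebase(path) -> Rulebase:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != RULEBASE_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported rulebase schema version {doc.get('schema_version')!r}"
        )
    rb = Rulebase(
        fit_mode=doc["fit_mode"],
        extension_kind=doc["extension_kind"],
        histogram_bins=doc["histogram_bins"],
        active_antecedents=tuple(doc["active_antecedents"]),
        normalization={int(k): tuple(v)
                       for k, v in doc["normalization"].items()},
    )
    for r in doc["rules"]:
        rule = Rule(antecedent_index=r["antecedent_index"],
                    consequent=r["consequent"],
                    mf=_mf_from_dict(r["mf"]),
                    fit_mode=r["fit_mode"])
        rb.rules[(rule.antecedent_index, rule.consequent)] = rule
    return rb
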