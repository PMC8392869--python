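"""Mamdani inference and Koczy-Hirota rule interpolation over the rulebase.

The decision axis is [0, 1] with singleton consequents: 1 for ``polyp`` and
0 for ``no_polyp``.  Classic Mamdani-Assilian inference connects the
antecedents of a rule with a fuzzy AND (Zadeh min-norm) and the two rules
with OR (max / weighted aggregation): the firing strength of each consequent
is the minimum membership of the observation across the active antecedents,
and the defuzzified decision value is the strength-weighted average of the
consequent singletons.

Histogram-fitted triangles can be so narrow that an observation has zero
membership in *both* rules of some antecedent, which zeroes both firing
strengths and leaves Mamdani with no valid output.  Koczy-Hirota (KH) rule
interpolation fills this gap: the closer the observation is to a rule, the
closer the conclusion is to that rule's consequent.  For the characteristic
alpha-cuts (alpha = 0 and alpha = 1) of the conclusion, each endpoint is the
distance-weighted mean of the rules' consequent endpoints with weights
``(1 / d)^k``, where ``d`` is the Euclidean distance (over the active
antecedents, on the min-max normalised scale) between the observation and
the rule's corresponding alpha-cut endpoint, and ``k`` defaults to the
number of active antecedents (the stabilized-KH convention).  With singleton
consequents the three conclusion points (support ends at alpha = 0 and core
at alpha = 1) are defuzzified by their centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Union

import numpy as np

from .features import AntecedentVector
from .rulebase import ExtendedMF, Rulebase

#: Singleton consequent positions on the decision axis.
CONSEQUENT_VALUES = {"polyp": 1.0, "no_polyp": 0.0}

#: Distance floor guarding the division in the KH weights; observations
#: closer than this to a rule point take the exact-hit fast path.
DISTANCE_EPS = 1e-12


@dataclass
class Observation:
    """Crisp feature values for every active antecedent of a rulebase.

    ``values`` maps 1-based antecedent index to the (already normalised,
    when ``normalized`` is set) measurement.  A crisp observation is a
    fuzzy singleton, so all its alpha-cuts collapse to the point itself.
    """

    values: Dict[int, float]
    normalized: bool = True


@dataclass
class InterpolationConfig:
    """KH interpolation knobs: ``k`` is the distance exponent."""

    k: Optional[float] = None  # None -> number of active antecedents

    def exponent(self, n_active: int) -> float:
        k = float(n_active if self.k is None else self.k)
        if k <= 0:
            raise ValueError("distance exponent k must be positive")
        return k


@dataclass
class Decision:
    """Outcome of classifying one tile."""

    fuzzy_value: float
    label: str
    method_used: str
    firing_strengths: Dict[str, float] = field(default_factory=dict)
    indeterminate: bool = False


@dataclass
class InferenceConfig:
    """End-to-end classification settings.

    ``mode`` is ``auto`` (Mamdani, falling back to KH interpolation when the
    observation misses every rule), ``mamdani`` (pure Mamdani; sensible with
    extended supports) or ``interpolation`` (always KH).  Exact ties at the
    decision threshold go to the majority class, no_polyp.
    """

    mode: str = "auto"
    decision_threshold: float = 0.5
    interpolation: InterpolationConfig = field(
        default_factory=InterpolationConfig)


def membership(mf: ExtendedMF, x: float) -> float:
    """Membership value of ``x`` in an (extended) fuzzy set, in [0, 1]."""
    if not np.isfinite(x):
        raise ValueError("membership requires a finite observation")
    return float(mf(x))


def _require_active(rb: Rulebase) -> tuple:
    if not rb.active_antecedents:
        raise ValueError("rulebase has no active antecedents")
    return rb.active_antecedents


def _label_for(value: float, threshold: float) -> str:
    return "polyp" if value > threshold else "no_polyp"


def mamdani_infer(rb: Rulebase, obs: Observation,
                  decision_threshold: float = 0.5) -> Decision:
    """Min-AND / weighted-OR Mamdani inference with singleton consequents.

    The firing strength of each consequent is the minimum membership of the
    observation over the active antecedents' rules for that consequent; the
    fuzzy decision value is ``w_polyp / (w_polyp + w_no_polyp)``.  When both
    strengths vanish the decision is flagged indeterminate (the caller may
    hand it to KH interpolation).
    """
    active = _require_active(rb)
    strengths = {}
    for consequent in rb.CONSEQUENTS:
        mus = []
        for i in active:
            mf = rb.scaled_mf(i, consequent) if obs.normalized \
                else rb.rule(i, consequent).mf
            mus.append(membership(mf, obs.values[i]))
        strengths[consequent] = min(mus)
    total = strengths["polyp"] + strengths["no_polyp"]
    if total == 0:
        return Decision(fuzzy_value=0.5, label="no_polyp",
                        method_used="mamdani", firing_strengths=strengths,
                        indeterminate=True)
    value = strengths["polyp"] / total
    return Decision(fuzzy_value=value,
                    label=_label_for(value, decision_threshold),
                    method_used="mamdani", firing_strengths=strengths)


def _rule_points(rb: Rulebase, obs: Observation) -> dict:
    """Per-consequent (left, core, right) vectors over active antecedents."""
    active = _require_active(rb)
    pts = {}
    for consequent in rb.CONSEQUENTS:
        tri = [rb.scaled_mf(i, consequent).base if obs.normalized
               else rb.rule(i, consequent).mf.base for i in active]
        pts[consequent] = {
            "left": np.array([t.left for t in tri]),
            "core": np.array([t.core for t in tri]),
            "right": np.array([t.right for t in tri]),
        }
    return pts


def _weighted_endpoint(x: np.ndarray, pts: dict, endpoint: str,
                       k: float) -> float:
    """One conclusion endpoint: (1/d)^k-weighted mean of the consequents.

    An exact hit (distance below :data:`DISTANCE_EPS`) returns the mean of
    the coinciding rules' consequents -- the limit of the weights.
    """
    dists = {}
    for consequent, tri in pts.items():
        dists[consequent] = float(np.linalg.norm(x - tri[endpoint]))
    hits = [c for c, d in dists.items() if d < DISTANCE_EPS]
    if hits:
        return float(np.mean([CONSEQUENT_VALUES[c] for c in hits]))
    log_w = {c: -k * np.log(d) for c, d in dists.items()}
    shift = max(log_w.values())  # overflow guard for large k
    w = {c: np.exp(v - shift) for c, v in log_w.items()}
    total = sum(w.values())
    return float(sum(w[c] * CONSEQUENT_VALUES[c] for c in w) / total)


def kh_interpolate(rb: Rulebase, obs: Observation,
                   cfg: Optional[InterpolationConfig] = None,
                   decision_threshold: float = 0.5) -> Decision:
    """Stabilized Koczy-Hirota interpolation with singleton consequents.

    The conclusion's three characteristic points (alpha = 0 support ends and
    the alpha = 1 core) are distance-weighted averages of the consequent
    singletons, using the Euclidean distance between the crisp observation
    and each rule's corresponding triangle points over the active
    antecedents.  The defuzzified value is the centroid of the three points;
    it always lies in the convex hull [0, 1] of the consequents.
    """
    cfg = cfg or InterpolationConfig()
    active = _require_active(rb)
    if not rb.rules:
        raise ValueError("rulebase has no rules")
    k = cfg.exponent(len(active))
    x = np.array([obs.values[i] for i in active], dtype=float)
    pts = _rule_points(rb, obs)
    b_lower = _weighted_endpoint(x, pts, "left", k)   # inf at alpha = 0
    b_core = _weighted_endpoint(x, pts, "core", k)    # alpha = 1 cut
    b_upper = _weighted_endpoint(x, pts, "right", k)  # sup at alpha = 0
    value = (b_lower + b_core + b_upper) / 3.0
    return Decision(fuzzy_value=value,
                    label=_label_for(value, decision_threshold),
                    method_used="interpolation",
                    firing_strengths={"polyp": value, "no_polyp": 1 - value})


def classify(rb: Rulebase,
             features: Union[AntecedentVector, np.ndarray, Dict[int, float]],
             cfg: Optional[InferenceConfig] = None) -> Decision:
    """Classify one tile's antecedent vector with the rulebase.

    Raw feature values are min-max normalised with the constants frozen in
    the rulebase at training time, then handed to Mamdani inference and --
    if the observation fires no rule and the mode allows it -- to KH
    interpolation.
    """
    cfg = cfg or InferenceConfig()
    active = _require_active(rb)
    if isinstance(features, AntecedentVector):
        raw = {i: features[i] for i in active}
    elif isinstance(features, dict):
        raw = {i: features[i] for i in active}
    else:
        arr = np.asarray(features, dtype=float)
        if arr.shape != (99,):
            raise ValueError("feature arrays must have 99 entries")
        raw = {i: float(arr[i - 1]) for i in active}
    missing = [i for i in active if i not in raw]
    if missing:
        raise ValueError(f"observation lacks antecedents {missing}")
    obs = Observation(
        values={i: rb.normalize_value(i, raw[i]) for i in active},
        normalized=True,
    )
    if cfg.mode == "interpolation":
        return kh_interpolate(rb, obs, cfg.interpolation,
                              cfg.decision_threshold)
    if cfg.mode not in ("auto", "mamdani"):
        raise ValueError(f"unknown inference mode {cfg.mode!r}")
    decision = mamdani_infer(rb, obs, cfg.decision_threshold)
    if decision.indeterminate and cfg.mode == "auto":
        return kh_interpolate(rb, obs, cfg.interpolation,
                              cfg.decision_threshold)
    return decision


def classify_frame(rb: Rulebase, features, cfg: Optional[InferenceConfig] = None):
    """Classify every row of a feature table; returns a decisions DataFrame."""
    import pandas as pd

    from .features import ANTECEDENT_NAMES

    cfg = cfg or InferenceConfig()
    cols = [ANTECEDENT_NAMES[i - 1] for i in rb.active_antecedents]
    rows = []
    values = features[cols].to_numpy(dtype=float)
    for r in range(values.shape[0]):
        raw = {i: values[r, j] for j, i in enumerate(rb.active_antecedents)}
        d = classify(rb, raw, cfg)
        rows.append({
            "fuzzy_value": d.fuzzy_value,
            "predicted": d.label,
            "method_used": d.method_used,
        })
    out = pd.DataFrame(rows, index=features.index)
    for col in ("source_id", "origin_row", "origin_col", "label"):
        if col in features.columns:
            out[col] = features[col]
    return out
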