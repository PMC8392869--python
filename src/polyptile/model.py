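"""Model / Results front end for the fuzzy tile classifier.

:class:`PolypTileClassifier` is built from a labelled antecedent table (one
row per training tile, the 99 feature columns plus a label column) and
``fit()`` returns a :class:`FuzzyRuleResults` holding the trained rulebase,
per-antecedent separation diagnostics, prediction and evaluation methods,
and a ``summary()`` table.  The heavy lifting lives in the library modules
(:mod:`polyptile.rulebase`, :mod:`polyptile.inference`,
:mod:`polyptile.evaluation`); this front end wires them together the way an
interactive analysis wants them.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import evaluation, inference, presets, rulebase
from .features import (ANTECEDENT_NAMES, AntecedentVector, FeatureConfig,
                       extract_antecedents, features_to_frame)
from .imaging import Tile


class PolypTileClassifier:
    """Fuzzy rule classifier for polyp content of image tiles.

    Parameters
    ----------
    features : DataFrame
        Training table: the 99 antecedent columns (named as in
        ``ANTECEDENT_NAMES``) and a label column with values ``polyp`` /
        ``no_polyp``.
    label_column : str
        Name of the label column.
    antecedents : str or sequence of int, optional
        Active antecedents: a preset name (``all99``, ``entropy``,
        ``total02``, ``total035``, ``center``) or explicit 1-based indices.
        Defaults to all 99.
    """

    def __init__(self, features: pd.DataFrame, label_column: str = "label",
                 antecedents: Union[str, Sequence[int], None] = None):
        missing = [n for n in ANTECEDENT_NAMES if n not in features.columns]
        if missing:
            raise ValueError(
                f"feature table lacks {len(missing)} antecedent columns "
                f"(first: {missing[:3]})"
            )
        if label_column not in features.columns:
            raise ValueError(f"no label column {label_column!r}")
        self.features = features
        self.label_column = label_column
        if antecedents is None:
            self.active = tuple(range(1, 100))
        elif isinstance(antecedents, str):
            self.active = presets.preset_indices(antecedents)
        else:
            self.active = tuple(int(i) for i in antecedents)
            if any(not 1 <= i <= 99 for i in self.active):
                raise ValueError("antecedent indices must lie in 1..99")

    @classmethod
    def from_tiles(cls, tiles: Sequence[Tile],
                   feature_config: Optional[FeatureConfig] = None,
                   **kwargs) -> "PolypTileClassifier":
        """Extract antecedents from labelled tiles and build the model."""
        vectors = [extract_antecedents(t, feature_config) for t in tiles]
        return cls(features_to_frame(vectors), **kwargs)

    def fit(self, mode: str = "histogram", bins: int = 100,
            extension_kind: str = "triangle") -> "FuzzyRuleResults":
        """Fit one triangular rule per (antecedent, class) and return results.

        ``mode`` picks where the triangle core sits (``mean``, ``median`` or
        the tallest-histogram-bin ``histogram`` fit); ``extension_kind``
        optionally smooths the triangles into strictly positive (half-)
        Gaussian bells.
        """
        rb = rulebase.train_rulebase(
            self.features, mode=mode, bins=bins,
            extension_kind=extension_kind, label_column=self.label_column,
        ).with_active(self.active)
        return FuzzyRuleResults(self, rb)


class FuzzyRuleResults:
    """Fitted rulebase plus diagnostics, prediction and reporting."""

    def __init__(self, model: PolypTileClassifier, rb: rulebase.Rulebase):
        self.model = model
        self.rulebase = rb

    # -- diagnostics -------------------------------------------------------

    def separation(self) -> pd.DataFrame:
        """Per-antecedent class separation on the normalised scale.

        Columns: total and centre distance between the polyp and no_polyp
        triangles, and each class's support width.
        """
        rows = []
        for i in self.rulebase.active_antecedents:
            lo, hi = self.rulebase.normalization[i]
            tp = self.rulebase.rule(i, "polyp").mf.base.scaled(lo, hi)
            tn = self.rulebase.rule(i, "no_polyp").mf.base.scaled(lo, hi)
            rows.append({
                "antecedent": i,
                "name": ANTECEDENT_NAMES[i - 1],
                "total_distance": rulebase.antecedent_total_distance(
                    self.rulebase, i),
                "center_distance": rulebase.antecedent_center_distance(
                    self.rulebase, i),
                "width_polyp": tp.width,
                "width_no_polyp": tn.width,
            })
        return pd.DataFrame(rows).set_index("antecedent")

    # -- refinement --------------------------------------------------------

    def select(self, threshold: float, metric: str = "total"
               ) -> "FuzzyRuleResults":
        """Keep only antecedents whose class triangles differ enough."""
        return FuzzyRuleResults(
            self.model,
            rulebase.select_by_distance(self.rulebase, threshold, metric))

    def restrict(self, antecedents: Union[str, Sequence[int]]
                 ) -> "FuzzyRuleResults":
        """Restrict to a preset name or explicit index set."""
        if isinstance(antecedents, str):
            antecedents = presets.preset_indices(antecedents)
        return FuzzyRuleResults(self.model,
                                self.rulebase.with_active(antecedents))

    def prune_narrow(self, min_width: float = 0.05) -> "FuzzyRuleResults":
        """Drop antecedents with very narrow normalised rule supports."""
        return FuzzyRuleResults(self.model,
                                rulebase.prune_narrow(self.rulebase,
                                                      min_width))

    # -- prediction and evaluation ----------------------------------------

    def predict(self, features: Union[pd.DataFrame, AntecedentVector],
                config: Optional[inference.InferenceConfig] = None):
        """Classify new tiles.

        A DataFrame yields a decisions table (fuzzy value, label, method
        used per row); a single antecedent vector yields one
        :class:`polyptile.inference.Decision`.
        """
        if isinstance(features, AntecedentVector):
            return inference.classify(self.rulebase, features, config)
        return inference.classify_frame(self.rulebase, features, config)

    def evaluate(self, features: pd.DataFrame,
                 config: Optional[inference.InferenceConfig] = None,
                 ci: bool = True, frac: float = 0.8, n: int = 100,
                 seed: int = 0) -> evaluation.MetricReport:
        """Predict a labelled table and report confusion metrics (+ CIs)."""
        decisions = self.predict(features, config)
        return evaluation.evaluate_decisions(decisions, ci=ci, frac=frac,
                                             n=n, seed=seed)

    # -- persistence and presentation -------------------------------------

    def save(self, path) -> None:
        rulebase.save_rulebase(self.rulebase, path)

    @classmethod
    def load(cls, path, model: Optional[PolypTileClassifier] = None
             ) -> "FuzzyRuleResults":
        return cls(model, rulebase.load_rulebase(path))

    def summary(self) -> str:
        """Plain-text overview of the fit."""
        rb = self.rulebase
        labels = None
        n_tiles = "?"
        if self.model is not None:
            labels = self.model.features[self.model.label_column].value_counts()
            n_tiles = len(self.model.features)
        sep = self.separation().sort_values("total_distance",
                                            ascending=False)
        lines = [
            "Fuzzy polyp tile classifier",
            "=" * 44,
            f"training tiles:      {n_tiles}",
        ]
        if labels is not None:
            for lab, cnt in labels.items():
                lines.append(f"  {lab:<18} {cnt}")
        lines += [
            f"fit mode:            {rb.fit_mode}",
            f"histogram bins:      {rb.histogram_bins}",
            f"membership kind:     {rb.extension_kind}",
            f"active antecedents:  {len(rb.active_antecedents)} of 99",
            "",
            "most separated antecedents (normalised total distance):",
        ]
        for i, row in sep.head(8).iterrows():
            lines.append(
                f"  {i:>3} {row['name']:<24} total={row['total_distance']:.3f}"
                f"  centre={row['center_distance']:.3f}"
            )
        return "\n".join(lines)

    def plot_rules(self, index: int, ax=None):
        """Plot the two class membership functions of one antecedent."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lo, hi = self.rulebase.normalization[index]
        xs = np.linspace(lo - 0.1 * (hi - lo or 1),
                         hi + 0.1 * (hi - lo or 1), 400)
        for consequent, colour in (("polyp", "tab:blue"),
                                   ("no_polyp", "tab:gray")):
            mf = self.rulebase.rule(index, consequent).mf
            ax.plot(xs, [mf(x) for x in xs], color=colour, label=consequent)
        ax.set_xlabel(ANTECEDENT_NAMES[index - 1])
        ax.set_ylabel("membership")
        ax.legend()
        return ax
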