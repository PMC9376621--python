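"""The DS-ANFIS classifier as a model / results pair.

``DominantSetAnfis`` bundles the full pipeline — preprocessing, Gaussian
affinity graph, dominant-set peeling, rule induction, hybrid ANFIS
training — behind a statsmodels-style interface: build the model from
arrays or a DataFrame, call :meth:`~DominantSetAnfis.fit`, and get a
``DominantSetAnfisResults`` carrying the fitted rule base, training
history, diagnostics, and a ``summary()`` table.

Example
-------
>>> from dsanfis import synthetic, DominantSetAnfis
>>> table, _ = synthetic.make_blobs(synthetic.BlobSpec(
...     centers=[[0.2, 0.2], [0.8, 0.8]], spreads=[0.05, 0.05],
...     sizes=[20, 20], labels=[0, 1], seed=7))
>>> res = DominantSetAnfis(table.labels, table.values,
...                        feature_names=table.columns).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import preprocessing as prep
from .preprocessing import FeatureTable
from .graph import gaussian_affinity
from .dominant_sets import peel_off, DominantSetPartition
from .rules import build_rule_base, render_rule_base, RuleBase
from .anfis import AnfisModel, AnfisConfig, predict_class

__all__ = ["PipelineConfig", "DominantSetAnfis", "DominantSetAnfisResults"]


@dataclass
class PipelineConfig:
    """Everything tunable about the pipeline, with field-standard defaults.

    ``fit_scope`` controls where normalization/imputation statistics come
    from in cross-validation: ``"train_fold"`` (default, leakage-free) fits
    them on each training fold; ``"global"`` fits them once on the full
    table before splitting.
    """

    # preprocessing
    drop: tuple = ()
    fit_scope: str = "train_fold"          # "train_fold" | "global"
    # graph
    bandwidth: object = "auto"             # "auto" | "auto_sqdist_var" | float
    # dominant-set peeling
    support_eps: float = 1e-5
    min_remaining: int = 2
    max_iter: int = 1000
    min_increment: float = 1e-8
    # rule induction
    include_residual: bool = True
    sigma_floor: float = 0.01
    # ANFIS
    mf_convention: str = "half"
    epochs: int = 50
    learning_rate: float = 0.01
    ds_only: bool = False                  # skip ANFIS fit (ablation)

    def __post_init__(self):
        if self.fit_scope not in ("train_fold", "global"):
            raise ValueError("fit_scope must be 'train_fold' or 'global'")

    def anfis_config(self) -> AnfisConfig:
        return AnfisConfig(epochs=self.epochs, learning_rate=self.learning_rate,
                           sigma_floor=self.sigma_floor,
                           mf_convention=self.mf_convention)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drop"] = list(d["drop"])
        return d


class DominantSetAnfis:
    """Interpretable fuzzy classifier initialized by dominant-set clustering.

    Parameters
    ----------
    endog : (M,) array-like of {0, 1}
        Binary diagnosis labels (1 = positive).
    exog : (M, n) array-like
        Raw feature matrix; NaN marks missing entries.
    feature_names : sequence of str, optional
    config : PipelineConfig, optional
    """

    def __init__(self, endog, exog, feature_names=None,
                 config: PipelineConfig | None = None):
        exog = np.asarray(exog, dtype=float)
        if exog.ndim != 2:
            raise ValueError("exog must be 2-D")
        self.endog = np.asarray(endog, dtype=int)
        if self.endog.shape != (exog.shape[0],):
            raise ValueError("endog/exog length mismatch")
        if feature_names is None:
            feature_names = [f"x{k+1}" for k in range(exog.shape[1])]
        self.feature_names = list(feature_names)
        self.exog = exog
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str,
                       drop=(), config: PipelineConfig | None = None,
                       categorical_mappings: dict | None = None):
        """Build from a DataFrame with the label in ``label_col``.

        Two-level object columns are encoded 0/1 automatically (codes in
        sorted category order) unless an explicit mapping is supplied.
        """
        table = FeatureTable(df.drop(columns=[label_col]),
                             labels=df[label_col].to_numpy())
        return cls.from_table(table, drop=drop, config=config,
                              categorical_mappings=categorical_mappings)

    @classmethod
    def from_table(cls, table: FeatureTable, drop=(),
                   config: PipelineConfig | None = None,
                   categorical_mappings: dict | None = None):
        if table.labels is None:
            raise ValueError("table has no labels")
        config = config or PipelineConfig()
        if drop:
            config = PipelineConfig(**{**config.to_dict(), "drop": tuple(drop)})
        table = _encode_object_columns(table, categorical_mappings or {})
        if config.drop:
            table = prep.drop_columns(table, [c for c in config.drop
                                              if c in table.columns])
        return cls(table.labels, table.values, feature_names=table.columns,
                   config=config)

    def fit(self, epochs: int | None = None,
            preprocessor: dict | None = None) -> "DominantSetAnfisResults":
        """Run the full pipeline on the model's data.

        ``preprocessor`` overrides the imputation/normalization statistics
        (used by the CV harness under ``fit_scope="global"``); by default
        they are fitted on this model's own rows.
        """
        cfg = self.config
        fitted_prep = preprocessor or fit_preprocessor(self.exog,
                                                       self.feature_names)
        X = apply_preprocessor(self.exog, self.feature_names, fitted_prep)
        graph = gaussian_affinity(X, sigma2=cfg.bandwidth)
        partition = peel_off(graph.A, min_remaining=cfg.min_remaining,
                             support_eps=cfg.support_eps,
                             max_iter=cfg.max_iter,
                             min_increment=cfg.min_increment)
        rb = build_rule_base(X, self.endog, self.feature_names, partition,
                             include_residual=cfg.include_residual,
                             sigma_floor=cfg.sigma_floor)
        engine = AnfisModel(rb, cfg.anfis_config())
        if not cfg.ds_only:
            engine.fit(X, self.endog, epochs=epochs)
        return DominantSetAnfisResults(
            model=self, engine=engine, initial_rulebase=rb,
            partition=partition, preprocessor=fitted_prep, sigma2=graph.sigma2)


# ---------------------------------------------------------------------------
# Preprocessing state shared between training and held-out data
# ---------------------------------------------------------------------------

def fit_preprocessor(exog: np.ndarray, names) -> dict:
    """Learn per-column mean (for imputation, raw scale, fitted first) and
    min/max (for normalization) from the given rows."""
    stats = {}
    for k, name in enumerate(names):
        col = exog[:, k]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(f"column {name!r} entirely missing")
        lo, hi = float(obs.min()), float(obs.max())
        stats[name] = {"mean": float(obs.mean()), "min": lo, "max": hi,
                       "degenerate": bool(lo == hi)}
    return stats


def apply_preprocessor(exog: np.ndarray, names, stats: dict) -> np.ndarray:
    """Impute with the fitted means, then min-max normalize (no clamping)."""
    X = np.array(exog, dtype=float, copy=True)
    for k, name in enumerate(names):
        st = stats[name]
        col = X[:, k]
        col[np.isnan(col)] = st["mean"]
        if st["degenerate"]:
            X[:, k] = 0.0
        else:
            X[:, k] = (col - st["min"]) / (st["max"] - st["min"])
    return X


def _encode_object_columns(table: FeatureTable, mappings: dict) -> FeatureTable:
    for col in table.columns:
        if pd.api.types.is_numeric_dtype(table.data[col]):
            continue
        if col in mappings:
            mapping = mappings[col]
        else:
            cats = sorted(set(v for v in table.data[col] if not pd.isna(v)))
            if len(cats) > 2:
                raise ValueError(
                    f"column {col!r} has {len(cats)} categories; provide an "
                    "explicit 0/1 mapping")
            mapping = {c: i for i, c in enumerate(cats)}
        table = prep.encode_categorical(table, col, mapping)
    return table


class DominantSetAnfisResults:
    """Fitted DS-ANFIS state: rule base, history, diagnostics, summary."""

    def __init__(self, model: DominantSetAnfis, engine: AnfisModel,
                 initial_rulebase: RuleBase, partition: DominantSetPartition,
                 preprocessor: dict, sigma2: float):
        self.model = model
        self.engine = engine
        self.initial_rulebase = initial_rulebase
        self.partition = partition
        self.preprocessor = preprocessor
        self.sigma2 = sigma2

    # -- core accessors -------------------------------------------------------
    @property
    def n_rules(self) -> int:
        return self.engine.n_rules

    @property
    def history(self) -> list:
        return self.engine.history

    def rule_base(self) -> RuleBase:
        return self.engine.rule_base()

    # -- inference ------------------------------------------------------------
    def _prepare(self, exog) -> np.ndarray:
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        return apply_preprocessor(exog, self.model.feature_names,
                                  self.preprocessor)

    def infer(self, exog) -> np.ndarray:
        """Raw TSK outputs (convex combinations of rule consequents)."""
        return self.engine.infer(self._prepare(exog))

    def predict(self, exog):
        """(classes, confidences); threshold 0.5, ties toward positive."""
        return self.engine.predict(self._prepare(exog))

    def explain(self, x) -> dict:
        """Per-rule decomposition of one prediction (firing strengths,
        normalized contributions, consequents, final output)."""
        X = self._prepare(np.atleast_2d(x))
        w = self.engine.firing_strengths(X)[0]
        total = w.sum()
        wbar = w / total if total > 0 else np.full_like(w, 1.0 / w.size)
        z = float(wbar @ self.engine.consequents)
        cls, conf = predict_class(z)
        return {"firing": w, "normalized": wbar,
                "consequents": self.engine.consequents.copy(),
                "output": z, "class": cls, "confidence": conf}

    def training_accuracy(self) -> float:
        X = apply_preprocessor(self.model.exog, self.model.feature_names,
                               self.preprocessor)
        cls, _ = self.engine.predict(X)
        return float(np.mean(cls == self.model.endog))

    # -- reporting ------------------------------------------------------------
    def rules_report(self) -> str:
        return render_rule_base(self.rule_base())

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Dominant-Set ANFIS classifier",
            "=" * 64,
            f"Observations:        {self.model.exog.shape[0]}",
            f"Features:            {len(self.model.feature_names)} "
            f"({', '.join(self.model.feature_names)})",
            f"Kernel bandwidth:    sigma^2 = {self.sigma2:.6g}",
            f"Clusters extracted:  {self.partition.n_clusters} "
            f"(+{self.partition.residual.size} residual nodes)",
            f"Rules:               {self.n_rules}",
            f"Training epochs:     {len(self.history)} "
            f"(lr={cfg.learning_rate}, {cfg.mf_convention} MFs)",
        ]
        if self.history:
            lines.append(f"Final training MSE:  {self.history[-1]:.6f}")
        lines.append(f"Training accuracy:   {self.training_accuracy():.4f}")
        lines.append("-" * 64)
        lines.append(f"{'rule':>4} {'support':>8} {'consequent':>11}  antecedent centers")
        rb = self.rule_base()
        for d, rule in enumerate(rb.rules, start=1):
            centers = ", ".join(f"{mf.center:.3f}" for mf in rule.antecedents)
            lines.append(f"{d:>4} {rule.support_size:>8} "
                         f"{rule.consequent:>11.4f}  [{centers}]")
        lines.append("=" * 64)
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "engine": json.loads(self.engine.to_json()),
            "preprocessor": self.preprocessor,
            "feature_names": self.model.feature_names,
            "sigma2": self.sigma2,
            "config": self.model.config.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)

    def predictions_to_csv(self, exog, path) -> None:
        z = self.infer(exog)
        cls = (z >= 0.5).astype(int)
        conf = np.where(cls == 1, z, 1.0 - z)
        pd.DataFrame({"row_id": np.arange(len(z)), "raw_output": z,
                      "class": cls, "confidence": conf}).to_csv(path, index=False)

    # -- plotting -------------------------------------------------------------
    def plot_memberships(self, feature, ax=None, initial=False):
        """Plot the Gaussian membership functions of one feature across all
        rules (normalized-feature axis)."""
        import matplotlib.pyplot as plt

        k = self.model.feature_names.index(feature)
        rb = self.initial_rulebase if initial else self.rule_base()
        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(-0.2, 1.2, 400)
        for d, rule in enumerate(rb.rules, start=1):
            mf = rule.antecedents[k]
            denom = 2.0 * mf.sigma ** 2 \
                if self.engine.config.mf_convention == "half" else mf.sigma ** 2
            ax.plot(grid, np.exp(-(grid - mf.center) ** 2 / denom),
                    label=f"Rule {d}")
        ax.set_xlabel(f"{feature} (normalized)")
        ax.set_ylabel("membership")
        ax.legend(fontsize="x-small")
        return ax
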