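"""Zero-order TSK inference and hybrid ANFIS training.

The five-layer network: (1) Gaussian memberships per rule and attribute,
(2) product T-norm firing strengths w_d, (3) normalization w̄_d = w_d/Σw,
(4) weighting of the constant consequents, (5) summation to the overall
output z = Σ w̄_d z_d — a convex combination of the rule consequents.

Training is the classic hybrid scheme: in each epoch the consequents are
solved exactly by least squares with the premises frozen (the design
matrix is the normalized-firing matrix), then the premise centers and
widths take one batch gradient-descent step on the squared output error
with the consequents frozen. The rule count and feature set never change;
only parameters adapt. Consequents become unclamped reals after training
and act as per-rule confidence levels.

Two membership conventions are supported: the standard "half" form
exp(-(x-c)^2 / (2 sigma^2)) (default) and the "plain" form
exp(-((x-c)/sigma)^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .rules import RuleBase, GaussianMF, FuzzyRule, DEFAULT_SIGMA_FLOOR

__all__ = ["AnfisConfig", "AnfisModel", "membership_degree",
           "normalize_firing", "predict_class"]


@dataclass
class AnfisConfig:
    epochs: int = 50
    learning_rate: float = 0.01
    sigma_floor: float = DEFAULT_SIGMA_FLOOR
    mf_convention: str = "half"   # "half" -> exp(-(x-c)^2/(2 s^2)); "plain" -> exp(-((x-c)/s)^2)

    def __post_init__(self):
        if self.mf_convention not in ("half", "plain"):
            raise ValueError("mf_convention must be 'half' or 'plain'")
        if self.epochs < 0 or self.learning_rate <= 0 or self.sigma_floor <= 0:
            raise ValueError("invalid training configuration")


def membership_degree(mf: GaussianMF, x: float, convention: str = "half") -> float:
    """Gaussian membership of a scalar x; in (0, 1], peaks at the center."""
    d2 = (float(x) - mf.center) ** 2
    if convention == "half":
        return float(np.exp(-d2 / (2.0 * mf.sigma ** 2)))
    if convention == "plain":
        return float(np.exp(-d2 / mf.sigma ** 2))
    raise ValueError(f"unknown convention {convention!r}")


def normalize_firing(w: np.ndarray):
    """w̄ = w / Σw; on total underflow fall back to uniform 1/D, flagged.

    Returns (wbar, degenerate_flag). The uniform fallback corresponds to an
    input so far from every rule that no rule meaningfully fires.
    """
    w = np.asarray(w, dtype=float)
    total = w.sum(axis=-1, keepdims=True)
    degenerate = total <= 0.0
    safe = np.where(degenerate, 1.0, total)
    wbar = np.where(degenerate, 1.0 / w.shape[-1], w / safe)
    return wbar, bool(np.any(degenerate))


def predict_class(output: float):
    """Round the TSK output to a diagnosis: class 1 iff z >= 0.5 (ties to
    positive); confidence is z for class 1 and 1 - z for class 0."""
    z = float(output)
    if z >= 0.5:
        return 1, z
    return 0, 1.0 - z


class AnfisModel:
    """A rule base plus training configuration and fitted state.

    Construct from an initialized :class:`~dsanfis.rules.RuleBase` (typically
    produced by dominant-set clustering) and call :meth:`fit`. Inference is
    vectorized over rows.
    """

    def __init__(self, rulebase: RuleBase, config: AnfisConfig | None = None):
        self.config = config or AnfisConfig()
        self.feature_names = list(rulebase.feature_names)
        self.class_labels = tuple(rulebase.class_labels)
        self.centers = rulebase.centers_matrix().astype(float)      # (D, n)
        self.sigmas = rulebase.sigmas_matrix().astype(float)        # (D, n)
        self.consequents = rulebase.consequents_vector().astype(float)  # (D,)
        self._supports = [r.support_size for r in rulebase.rules]
        self._sources = [r.source_cluster for r in rulebase.rules]
        self.sigmas = np.maximum(self.sigmas, self.config.sigma_floor)
        self.history: list[float] = []

    # -- structure ----------------------------------------------------------
    @property
    def n_rules(self) -> int:
        return self.centers.shape[0]

    @property
    def n_features(self) -> int:
        return self.centers.shape[1]

    def rule_base(self) -> RuleBase:
        """Current parameters as a RuleBase (e.g. for rendering/saving)."""
        rules = [
            FuzzyRule(
                antecedents=[GaussianMF(float(c), float(s))
                             for c, s in zip(self.centers[d], self.sigmas[d])],
                consequent=float(self.consequents[d]),
                source_cluster=self._sources[d],
                support_size=self._supports[d],
            )
            for d in range(self.n_rules)
        ]
        return RuleBase(rules=rules, feature_names=self.feature_names,
                        class_labels=self.class_labels)

    # -- forward pass --------------------------------------------------------
    def _log_memberships(self, X: np.ndarray) -> np.ndarray:
        # (M, D, n) squared standardized distances, summed over features
        diff = X[:, None, :] - self.centers[None, :, :]
        q = diff ** 2 / self.sigmas[None, :, :] ** 2
        if self.config.mf_convention == "half":
            q = q / 2.0
        return -q.sum(axis=2)  # (M, D) log firing strengths

    def firing_strengths(self, X) -> np.ndarray:
        """Product-T-norm firing strength per rule, w_d = prod_k mu_dk(x_k)."""
        X = self._check_X(X)
        return np.exp(self._log_memberships(X))

    def infer(self, X) -> np.ndarray:
        """Overall output z = sum_d w̄_d z_d per row (convex combination)."""
        w = self.firing_strengths(X)
        wbar, _ = normalize_firing(w)
        return wbar @ self.consequents

    def predict(self, X):
        """(classes, confidences) for each row; threshold 0.5, ties positive."""
        z = self.infer(X)
        cls = (z >= 0.5).astype(int)
        conf = np.where(cls == 1, z, 1.0 - z)
        return cls, conf

    def _check_X(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}")
        if np.isnan(X).any():
            raise ValueError("missing feature values; impute upstream")
        return X

    # -- hybrid learning -----------------------------------------------------
    def lse_consequents(self, X, y) -> np.ndarray:
        """Forward pass: solve the consequents exactly by least squares.

        With premises fixed, the model output is linear in the consequents
        with design matrix the normalized firing strengths; the minimum-norm
        solution handles rank deficiency (two rules firing identically).
        """
        X = self._check_X(X)
        y = np.asarray(y, dtype=float)
        wbar, _ = normalize_firing(self.firing_strengths(X))
        try:
            sol, *_ = np.linalg.lstsq(wbar, y, rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover - pathological
            G = wbar.T @ wbar + 1e-10 * np.eye(self.n_rules)
            sol = np.linalg.solve(G, wbar.T @ y)
        self.consequents = sol
        return self.consequents

    def gradient_premise_step(self, X, y, learning_rate: float | None = None):
        """Backward pass: one batch gradient step on centers and sigmas.

        Analytic gradients of the mean squared output error through the
        membership/product/normalization/summation layers; sigmas are
        re-floored after the update. Rows whose total firing strength
        underflows carry no usable gradient and are skipped; if the step
        itself is non-finite (extreme parameters) it is rejected.
        """
        X = self._check_X(X)
        y = np.asarray(y, dtype=float)
        lr = self.config.learning_rate if learning_rate is None else learning_rate
        w = self.firing_strengths(X)                    # (M, D)
        total = w.sum(axis=1)                           # (M,)
        ok = total > 1e-100
        if not np.any(ok):
            return self.centers, self.sigmas
        Xo, wo, yo = X[ok], w[ok], y[ok]
        to = total[ok][:, None]
        wbar = wo / to
        yhat = wbar @ self.consequents
        err = yhat - yo                                 # (Mo,)
        # dE/dw_id = 2 e_i (z_d - yhat_i) / total_i, E averaged over rows
        gw = (2.0 * err[:, None]) * (self.consequents[None, :] - yhat[:, None]) / to
        gw = gw * wo / len(yo)                          # chain through w_d = exp(...)
        diff = Xo[:, None, :] - self.centers[None, :, :]        # (Mo, D, n)
        scale = 1.0 if self.config.mf_convention == "half" else 2.0
        grad_c = scale * np.einsum("md,mdk->dk", gw, diff / self.sigmas[None] ** 2)
        grad_s = scale * np.einsum("md,mdk->dk", gw, diff ** 2 / self.sigmas[None] ** 3)
        if not (np.all(np.isfinite(grad_c)) and np.all(np.isfinite(grad_s))):
            return self.centers, self.sigmas
        self.centers = self.centers - lr * grad_c
        self.sigmas = np.maximum(self.sigmas - lr * grad_s, self.config.sigma_floor)
        return self.centers, self.sigmas

    def mse(self, X, y) -> float:
        y = np.asarray(y, dtype=float)
        resid = self.infer(X) - y
        return float(np.mean(resid ** 2))

    def fit(self, X, y, epochs: int | None = None) -> "AnfisModel":
        """Hybrid training: per epoch an exact LSE forward pass on the
        consequents, then one gradient step on the premises. Structure
        (rule count, feature set) is invariant; ``epochs=0`` is a no-op."""
        n_epochs = self.config.epochs if epochs is None else epochs
        for _ in range(n_epochs):
            self.lse_consequents(X, y)
            self.gradient_premise_step(X, y)
            self.history.append(self.mse(X, y))
        return self

    # -- persistence ----------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "rulebase": json.loads(self.rule_base().to_json()),
            "history": self.history,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnfisModel":
        payload = json.loads(text)
        rb = RuleBase.from_json(json.dumps(payload["rulebase"]))
        model = cls(rb, AnfisConfig(**payload["config"]))
        model.history = list(payload["history"])
        return model
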