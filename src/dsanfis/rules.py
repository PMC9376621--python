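"""Convert dominant-set clusters into a zero-order TSK fuzzy rule base.

Each cluster becomes one rule "If x1 is Gaussian(c1, s1) and ... and xn is
Gaussian(cn, sn) Then z": the center of each antecedent is the mean of the
cluster's points projected on that attribute, the width is the population
standard deviation of the same projection (floored to keep memberships
proper on degenerate clusters), and the consequent is the majority class
of the cluster. Centers live in normalized-feature units, which makes a
rule readable as e.g. "MMSE is Around 0.96".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GaussianMF", "FuzzyRule", "RuleBase", "init_membership",
           "cluster_to_rule", "build_rule_base", "render_rule_base"]

DEFAULT_SIGMA_FLOOR = 0.01


@dataclass
class GaussianMF:
    """Gaussian membership parameters: center and width (sigma > 0)."""

    center: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class FuzzyRule:
    antecedents: list  # one GaussianMF per attribute
    consequent: float
    source_cluster: int = -1
    support_size: int = 0


@dataclass
class RuleBase:
    rules: list
    feature_names: list
    class_labels: tuple = (0, 1)

    def __post_init__(self):
        if len(self.rules) < 1:
            raise ValueError("rule base must contain at least one rule")
        for r in self.rules:
            if len(r.antecedents) != len(self.feature_names):
                raise ValueError("antecedent count must match feature count")

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    # matrix views used by the ANFIS engine ---------------------------------
    def centers_matrix(self) -> np.ndarray:
        return np.array([[mf.center for mf in r.antecedents] for r in self.rules])

    def sigmas_matrix(self) -> np.ndarray:
        return np.array([[mf.sigma for mf in r.antecedents] for r in self.rules])

    def consequents_vector(self) -> np.ndarray:
        return np.array([r.consequent for r in self.rules], dtype=float)

    # serialization ----------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "features": list(self.feature_names),
            "class_labels": list(self.class_labels),
            "rules": [
                {
                    "centers": [mf.center for mf in r.antecedents],
                    "sigmas": [mf.sigma for mf in r.antecedents],
                    "consequent": r.consequent,
                    "support": r.support_size,
                    "source_cluster": r.source_cluster,
                }
                for r in self.rules
            ],
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RuleBase":
        payload = json.loads(text)
        rules = [
            FuzzyRule(
                antecedents=[GaussianMF(c, s) for c, s in
                             zip(r["centers"], r["sigmas"])],
                consequent=r["consequent"],
                source_cluster=r.get("source_cluster", -1),
                support_size=r.get("support", 0),
            )
            for r in payload["rules"]
        ]
        return cls(rules=rules, feature_names=payload["features"],
                   class_labels=tuple(payload["class_labels"]))


def init_membership(points, sigma_floor: float = DEFAULT_SIGMA_FLOOR) -> GaussianMF:
    """Gaussian MF from a cluster's projection on one attribute.

    center = mean of the points; sigma = population standard deviation
    (denominator |S|), floored at ``sigma_floor`` so singleton or constant
    projections still yield a proper membership function.
    """
    x = np.asarray(points, dtype=float)
    if x.size < 1:
        raise ValueError("empty cluster projection")
    c = float(x.mean())
    s = float(x.std(ddof=0))
    return GaussianMF(center=c, sigma=max(s, sigma_floor))


def _majority(labels, tie_break: int) -> int:
    labels = np.asarray(labels, dtype=int)
    ones = int(labels.sum())
    zeros = labels.size - ones
    if ones > zeros:
        return 1
    if zeros > ones:
        return 0
    return int(tie_break)


def cluster_to_rule(X, y, cluster, source_cluster: int = -1,
                    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
                    tie_break: int | None = None) -> FuzzyRule:
    """One rule from one cluster: per-attribute MFs + majority-class consequent.

    Ties in the majority vote are broken toward ``tie_break`` — by default
    the globally more frequent class in ``y`` (deterministic and maximizes
    prior accuracy).
    """
    cluster = np.asarray(cluster, dtype=int)
    if cluster.size == 0:
        raise ValueError("empty cluster")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if tie_break is None:
        tie_break = _majority(y, tie_break=1)
    mfs = [init_membership(X[cluster, k], sigma_floor=sigma_floor)
           for k in range(X.shape[1])]
    consequent = float(_majority(y[cluster], tie_break=tie_break))
    return FuzzyRule(antecedents=mfs, consequent=consequent,
                     source_cluster=source_cluster, support_size=int(cluster.size))


def build_rule_base(X, y, feature_names, partition,
                    include_residual: bool = True,
                    sigma_floor: float = DEFAULT_SIGMA_FLOOR) -> RuleBase:
    """One rule per extracted cluster; the residual clutter group becomes a
    rule too by default (it carries real, if diverse, subjects)."""
    groups = [np.asarray(c, dtype=int) for c in partition.clusters]
    if include_residual and partition.residual.size:
        groups.append(np.asarray(partition.residual, dtype=int))
    if not groups:
        raise ValueError("partition has no clusters")
    tie = _majority(y, tie_break=1)
    rules = [cluster_to_rule(X, y, g, source_cluster=i, sigma_floor=sigma_floor,
                             tie_break=tie)
             for i, g in enumerate(groups)]
    return RuleBase(rules=rules, feature_names=list(feature_names))


def render_rule_base(rb: RuleBase, class_names=("Negative", "Positive")) -> str:
    """Human-readable listing: '<feature> is Around <center>' antecedents."""
    if not rb.feature_names:
        raise ValueError("rule base has no feature names")
    lines = []
    for d, rule in enumerate(rb.rules, start=1):
        parts = [
            f"{name} is Around {mf.center:.3g} (±{mf.sigma:.3g})"
            for name, mf in zip(rb.feature_names, rule.antecedents)
        ]
        cls = class_names[1] if rule.consequent >= 0.5 else class_names[0]
        lines.append(
            f"Rule {d}: If " + " and ".join(parts)
            + f" Then {cls} (confidence {rule.consequent:.3f}, "
            + f"support {rule.support_size})"
        )
    return "\n".join(lines)
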