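"""Synthetic fixtures: Gaussian blobs with clutter, and an OASIS-like table.

Two generators cover the two kinds of structure the pipeline must handle.

``make_blobs`` produces well-separated isotropic Gaussian clusters plus a
sprinkling of uniform clutter on the unit cube — the blob-plus-noise
geometry on which dominant-set peeling should recover cluster memberships
exactly and keep the clutter as a residual group.

``make_oasis_like`` emulates the marginal statistics of the OASIS-2 visit
table (373 rows; Age, Gender, EDUC, SES, MMSE, eTIV, nWBV, ASF): continuous
columns are truncated normals matching the published means/SDs and ranges,
SES is an integer 1-5 score, eTIV is generated as a noisy reciprocal of ASF
so the correlation screen has a genuinely near-collinear pair to catch, and
missing values are injected into SES and MMSE. The binary diagnosis is a
logistic function of (-MMSE, -nWBV) — lower cognition and lower brain
volume raise the odds — giving the table a recoverable supervised signal.
The joint distribution is NOT claimed to match the real cohort; only the
marginals and the collinearity/missingness structure are emulated.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import FeatureTable

__all__ = ["BlobSpec", "make_blobs", "make_oasis_like", "OASIS_MARGINALS"]


@dataclass
class BlobSpec:
    """Blueprint for labeled Gaussian blobs with optional uniform clutter."""

    centers: list                      # list of n-vectors in [0,1]^n
    spreads: list                      # per-blob isotropic SD
    sizes: list                        # per-blob point counts (>= 1)
    labels: list                       # per-blob class in {0, 1}
    clutter: int = 0                   # uniform-noise point count
    clutter_label: int = 0
    seed: int = 0

    def __post_init__(self):
        k = len(self.centers)
        if not (len(self.spreads) == len(self.sizes) == len(self.labels) == k):
            raise ValueError("centers/spreads/sizes/labels must align")
        if any(s < 1 for s in self.sizes):
            raise ValueError("blob sizes must be >= 1")
        if any(sp <= 0 for sp in self.spreads):
            raise ValueError("spreads must be positive")


def make_blobs(spec: BlobSpec):
    """Draw the blobs; returns (FeatureTable, ground-truth blob ids).

    Features are clipped to [0, 1]; clutter points are uniform on the cube
    and carry ground-truth id = number of blobs.
    """
    rng = np.random.default_rng(spec.seed)
    n_dim = len(spec.centers[0])
    rows, true_ids, labels = [], [], []
    for b, (c, sp, m, lab) in enumerate(
            zip(spec.centers, spec.spreads, spec.sizes, spec.labels)):
        pts = rng.normal(loc=np.asarray(c, dtype=float), scale=sp,
                         size=(int(m), n_dim))
        rows.append(pts)
        true_ids.extend([b] * int(m))
        labels.extend([int(lab)] * int(m))
    if spec.clutter:
        pts = rng.uniform(0.0, 1.0, size=(int(spec.clutter), n_dim))
        rows.append(pts)
        true_ids.extend([len(spec.centers)] * int(spec.clutter))
        labels.extend([int(spec.clutter_label)] * int(spec.clutter))
    X = np.clip(np.vstack(rows), 0.0, 1.0)
    cols = [f"x{k+1}" for k in range(n_dim)]
    table = FeatureTable(pd.DataFrame(X, columns=cols), labels=np.array(labels))
    return table, np.array(true_ids)


#: published marginal summaries the generator targets:
#: (mean, sd, min, max) per continuous column; counts refer to M = 373.
OASIS_MARGINALS = {
    "Age": (77.013, 7.641, 60.0, 98.0),
    "EDUC": (14.598, 2.876, 6.0, 23.0),
    "SES": (2.460, 1.134, 1.0, 5.0),
    "MMSE": (27.342, 3.683, 4.0, 30.0),
    "eTIV": (1488.129, 176.139, 1106.0, 2004.0),
    "nWBV": (0.730, 0.037, 0.644, 0.837),
    "ASF": (1.195, 0.138, 0.876, 1.587),
}

#: reference missing-entry counts at M = 373 (SES observed 354, MMSE 371)
_MISSING_DEFAULT = {"SES": 19.0 / 373.0, "MMSE": 2.0 / 373.0}

#: reference positive-class prevalence: 167 demented of 373 sessions
_POSITIVE_RATE = 167.0 / 373.0


def _trunc_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (ranges are several SDs wide, so
    acceptance is high and the loop is short)."""
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mean, sd, size=remaining.size)
        good = (draw >= lo) & (draw <= hi)
        out[remaining[good]] = draw[good]
        remaining = remaining[~good]
    return out


def make_oasis_like(M: int = 373, missing_rate: dict | None = None,
                    seed: int = 0, encode_gender: bool = True) -> FeatureTable:
    """An OASIS-like subject table with binary dementia labels.

    Parameters
    ----------
    M : int
        Number of rows (>= 10).
    missing_rate : dict, optional
        Per-column missing fractions; defaults to the reference rates for
        SES (19/373) and MMSE (2/373).
    seed : int
        Drives every random draw.
    encode_gender : bool
        If False, Gender is left as "M"/"F" strings so the categorical
        encoding step can be exercised.
    """
    if M < 10:
        raise ValueError("need at least 10 rows")
    rng = np.random.default_rng(seed)
    rates = dict(_MISSING_DEFAULT if missing_rate is None else missing_rate)

    cols: dict[str, np.ndarray] = {}
    for name in ("Age", "EDUC", "MMSE", "nWBV", "ASF"):
        mean, sd, lo, hi = OASIS_MARGINALS[name]
        cols[name] = _trunc_normal(rng, mean, sd, lo, hi, M)
    cols["EDUC"] = np.round(cols["EDUC"])
    cols["MMSE"] = np.round(cols["MMSE"])
    # SES: integer 1..5 with probabilities tuned to mean ~2.46, sd ~1.13
    ses_p = np.array([0.22, 0.33, 0.26, 0.12, 0.07])
    cols["SES"] = rng.choice(np.arange(1.0, 6.0), size=M, p=ses_p)
    # eTIV is a noisy reciprocal of ASF (both measure head size up to the
    # atlas normalization), giving the near-collinear pair to screen out
    etiv = 1778.0 / cols["ASF"] + rng.normal(0.0, 12.0, size=M)
    cols["eTIV"] = np.clip(etiv, *OASIS_MARGINALS["eTIV"][2:])
    gender_codes = rng.choice([0.0, 1.0], size=M, p=[0.43, 0.57])  # 0=M, 1=F

    # diagnosis: logistic in standardized (-MMSE, -nWBV); intercept chosen by
    # bisection so the expected prevalence matches the reference 167/373
    z_mmse = (cols["MMSE"] - OASIS_MARGINALS["MMSE"][0]) / OASIS_MARGINALS["MMSE"][1]
    z_nwbv = (cols["nWBV"] - OASIS_MARGINALS["nWBV"][0]) / OASIS_MARGINALS["nWBV"][1]
    lin = -2.0 * z_mmse - 1.0 * z_nwbv
    lo_b, hi_b = -10.0, 10.0
    for _ in range(60):
        b0 = (lo_b + hi_b) / 2.0
        if np.mean(1.0 / (1.0 + np.exp(-(lin + b0)))) < _POSITIVE_RATE:
            lo_b = b0
        else:
            hi_b = b0
    prob = 1.0 / (1.0 + np.exp(-(lin + b0)))
    labels = (rng.uniform(size=M) < prob).astype(int)

    # inject missingness (SES, MMSE by default)
    for name, rate in rates.items():
        if rate <= 0:
            continue
        n_miss = int(round(rate * M))
        idx = rng.choice(M, size=n_miss, replace=False)
        cols[name][idx] = np.nan

    df = pd.DataFrame({
        "Age": cols["Age"],
        "Gender": gender_codes if encode_gender
        else np.where(gender_codes == 1.0, "F", "M"),
        "EDUC": cols["EDUC"],
        "SES": cols["SES"],
        "MMSE": cols["MMSE"],
        "eTIV": cols["eTIV"],
        "nWBV": cols["nWBV"],
        "ASF": cols["ASF"],
    })
    return FeatureTable(df, labels=labels)
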