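"""Engineered predictors for the genotype recaller.

From the two-channel summaries (r, theta) each record gets:

* three signed *angle errors* — the deviation of theta (radians) from the
  expected cluster angles 0 (AA), pi/4 (AB) and pi/2 (BB) under equal probe
  efficiency:  a_AA = theta,  a_AB = pi/4 - theta,  a_BB = pi/2 - theta;
* three signed *subtended arcs* — the arc length those deviations subtend at
  radius r:  s_g = r * a_g;
* two sample-level degradation proxies — the mean and (n-1) variance of total
  intensity r over the sample's QC-passing records: degraded, low-input
  samples show lower mean signal and higher variability.

All predictors are z-scored with statistics learned from the training
partition only (:class:`Normalizer`), guarding against train/test leakage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical predictor set, in fixed order
FEATURE_COLUMNS = [
    "gencall", "gentrain", "cluster_sep", "r", "x", "y", "theta",
    "a_aa", "a_ab", "a_bb", "s_aa", "s_ab", "s_bb",
    "sample_mean_r", "sample_var_r",
]

_QUARTER_PI = np.pi / 4
_HALF_PI = np.pi / 2


def theta_radians(theta_norm) -> np.ndarray:
    """Convert Illumina normalized theta in [0,1] to radians in [0, pi/2]."""
    t = np.asarray(theta_norm, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("theta_norm outside [0, 1]")
    return t * _HALF_PI


def angle_errors(theta) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed deviations of theta (radians) from the AA/AB/BB cluster angles."""
    t = np.asarray(theta, dtype=float)
    if np.any((t < 0) | (t > _HALF_PI)):
        raise ValueError("theta outside [0, pi/2]")
    return t, _QUARTER_PI - t, _HALF_PI - t


def subtended_arcs(r, theta) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arc lengths subtended by the angle errors at radius r (signed)."""
    rr = np.asarray(r, dtype=float)
    if np.any(rr < 0):
        raise ValueError("negative intensity r")
    a_aa, a_ab, a_bb = angle_errors(theta)
    return rr * a_aa, rr * a_ab, rr * a_bb


def sample_summaries(r_values) -> tuple[float, float]:
    """Mean and unbiased variance of total intensity over one sample's records."""
    r = np.asarray(r_values, dtype=float)
    if r.size < 2:
        raise ValueError("sample summaries need at least 2 records")
    return float(r.mean()), float(r.var(ddof=1))


def compute_features(records: pd.DataFrame) -> pd.DataFrame:
    """Attach the engineered predictor columns to QC-passed records.

    Sample-level summaries are computed per ``sample_id`` over the records
    given (i.e. post-QC autosomal records) and broadcast to every record of
    the sample.
    """
    out = records.copy()
    out["theta"] = theta_radians(out["theta_norm"].to_numpy())
    out["a_aa"], out["a_ab"], out["a_bb"] = angle_errors(out["theta"].to_numpy())
    out["s_aa"], out["s_ab"], out["s_bb"] = subtended_arcs(
        out["r"].to_numpy(), out["theta"].to_numpy())
    grp = out.groupby("sample_id")["r"]
    sizes = grp.size()
    if (sizes < 2).any():
        raise ValueError(
            f"samples with <2 records: {sizes[sizes < 2].index.tolist()}")
    out["sample_mean_r"] = grp.transform("mean")
    out["sample_var_r"] = grp.transform(lambda s: s.var(ddof=1))
    return out


@dataclass
class Normalizer:
    """Per-feature z-scoring statistics learned from the training partition.

    Constant (zero-variance) features are dropped with a warning and recorded
    in ``dropped``.
    """

    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    dropped: list[str] = field(default_factory=list)

    @classmethod
    def fit(cls, df: pd.DataFrame, feature_names: list[str] | None = None) -> "Normalizer":
        names = list(feature_names or FEATURE_COLUMNS)
        X = df[names].to_numpy(dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        dropped = [n for n, k in zip(names, keep) if not k]
        if dropped:
            warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
        kept = [n for n, k in zip(names, keep) if k]
        return cls(kept, mean[keep], sd[keep], dropped)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        X = df[self.feature_names].to_numpy(dtype=float)
        return pd.DataFrame((X - self.mean) / self.sd,
                            columns=self.feature_names, index=df.index)

    def inverse_transform(self, z: pd.DataFrame) -> pd.DataFrame:
        X = z[self.feature_names].to_numpy(dtype=float)
        return pd.DataFrame(X * self.sd + self.mean,
                            columns=self.feature_names, index=z.index)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "feature_names": self.feature_names,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "dropped": self.dropped,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Normalizer":
        d = json.loads(Path(path).read_text())
        return cls(d["feature_names"], np.asarray(d["mean"]),
                   np.asarray(d["sd"]), d["dropped"])
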