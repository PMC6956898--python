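"""Dataset meta-features: simple, statistical, information-theoretic, and
aggregated fingerprints.

Information-theoretic quantities are plug-in estimates (empirical joint
frequencies) in nats. They are defined for nominal variables; the binary
fingerprint bits are nominal as-is, and the continuous response is made
nominal by equal-frequency binning into ``ceil(sqrt(n))`` bins (minimum 2).

The total correlation of all fingerprint bits is intractable through the
joint entropy, so it is estimated on a seeded random subset of columns
(default 8), which keeps the joint state space enumerable.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# plug-in information theory
# ---------------------------------------------------------------------------

def entropy(v) -> float:
    """Plug-in Shannon entropy of a nominal vector, in nats."""
    v = np.asarray(v)
    if v.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    _, counts = np.unique(v, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def joint_entropy(columns) -> float:
    """Plug-in entropy of the joint distribution of several nominal vectors."""
    arr = np.column_stack([np.asarray(c) for c in columns])
    _, counts = np.unique(arr, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(x, y) -> float:
    """Plug-in mutual information MI(X; Y) = H(X) + H(Y) - H(X, Y), nats.

    Equals ``H(Y) - H(Y|X)``: the reduction in uncertainty about Y from
    knowing X. Symmetric, non-negative up to floating error.
    """
    x, y = np.asarray(x), np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 2:
        raise ValueError("mutual information needs at least 2 observations")
    return max(0.0, entropy(x) + entropy(y) - joint_entropy([x, y]))


def total_correlation(columns, max_columns: int = 8, seed: int = 0) -> float:
    """Multiple information (total correlation): sum of marginal entropies
    minus the joint entropy.

    Zero iff the columns are mutually independent (in the plug-in sense).
    When more than ``max_columns`` columns are given, a seeded random
    subset of that size is used, since the joint-state space grows
    exponentially with the column count.
    """
    columns = [np.asarray(c) for c in columns]
    if len(columns) < 2:
        raise ValueError("total correlation needs at least 2 columns")
    if len(columns) > max_columns:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(columns), size=max_columns, replace=False)
        columns = [columns[i] for i in sorted(keep)]
    marginal = sum(entropy(c) for c in columns)
    return max(0.0, marginal - joint_entropy(columns))


def normalized_entropy(v, n: int, denominator: str = "count") -> float:
    """Entropy of ``v`` divided by ``log(n)``.

    ``denominator="count"`` takes ``n`` at face value (the caller passes
    e.g. the number of features); ``denominator="levels"`` ignores ``n``
    and normalises by the log of the number of observed levels, which
    guarantees a value in [0, 1].
    """
    if denominator == "levels":
        n = len(np.unique(np.asarray(v)))
        if n < 2:
            return 0.0
    if n < 2:
        raise ValueError("normalisation denominator needs n >= 2")
    return entropy(v) / math.log(n)


def equal_frequency_bins(x, n_bins: int | None = None) -> np.ndarray:
    """Discretise a continuous vector into equal-frequency bins.

    Defaults to ``ceil(sqrt(n))`` bins (minimum 2); duplicate quantile
    edges are merged, so heavily tied data yield fewer bins.
    """
    x = np.asarray(x, dtype=float)
    if n_bins is None:
        n_bins = max(2, math.ceil(math.sqrt(len(x))))
    codes = pd.qcut(x, q=n_bins, labels=False, duplicates="drop")
    codes = np.asarray(codes)
    if np.isnan(codes).any():  # constant vector: qcut yields a single bin
        codes = np.zeros(len(x))
    return codes.astype(int)


# ---------------------------------------------------------------------------
# moments and fingerprints
# ---------------------------------------------------------------------------

def response_moments(y) -> dict[str, float]:
    """Mean, sd, skewness and kurtosis of the response.

    Population-moment (biased) conventions; kurtosis is the plain fourth
    standardised moment (3 for a normal), not excess-corrected. Degenerate
    (constant) responses get NaN skewness/kurtosis.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 4:
        raise ValueError("moments need at least 4 observations")
    sd = float(np.std(y))
    if sd == 0.0:
        skew = kurt = float("nan")
    else:
        skew = float(stats.skew(y, bias=True))
        kurt = float(stats.kurtosis(y, fisher=False, bias=True))
    return {"mean": float(np.mean(y)), "sd": sd, "skew": skew, "kurt": kurt}


def aggregated_fingerprint(fp: pd.DataFrame) -> pd.Series:
    """Per-bit fraction of compounds with the bit set (column means)."""
    if fp.shape[0] == 0:
        raise ValueError("empty fingerprint table")
    vals = fp.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("fingerprint table must be binary")
    return fp.mean(axis=0)


# ---------------------------------------------------------------------------
# full per-dataset feature vector
# ---------------------------------------------------------------------------

def dataset_metafeatures(
    fp: pd.DataFrame,
    descriptors: pd.DataFrame,
    y: pd.Series,
    multiinfo_columns: int = 8,
    seed: int = 0,
    nentropyfeat_denominator: str = "count",
) -> pd.Series:
    """The scalar dataset meta-features plus the aggregated fingerprint.

    Nominal information-theoretic features are computed on the fingerprint
    bits (with the response equal-frequency binned); statistical moments of
    the features are computed on the continuous descriptor table, ignoring
    missing cells. Scalars are prefixed ``ds_``, aggregated-fingerprint
    entries ``fp_agg_``.
    """
    y_arr = y.to_numpy(dtype=float)
    y_binned = equal_frequency_bins(y_arr)
    bits = [fp.iloc[:, j].to_numpy() for j in range(fp.shape[1])]

    mi_per_bit = [mutual_information(b, y_binned) for b in bits]
    bit_entropies = [entropy(b) for b in bits]
    moments = response_moments(y_arr)

    features: dict[str, float] = {
        "ds_n_instances": float(len(y_arr)),
        "ds_multiinfo": total_correlation(bits, max_columns=multiinfo_columns, seed=seed),
        "ds_mutualinfo": float(np.mean(mi_per_bit)),
        "ds_nentropyfeat": float(
            np.mean(bit_entropies)
            / (math.log(fp.shape[1]) if nentropyfeat_denominator == "count" else math.log(2))
        ),
        "ds_mmeanfeat": float(descriptors.mean(axis=0).mean()),
        "ds_msdfeat": float(descriptors.std(axis=0, ddof=0).mean()),
        "ds_meanresp": moments["mean"],
        "ds_sdresp": moments["sd"],
        "ds_skewresp": moments["skew"],
        "ds_kurtresp": moments["kurt"],
        "ds_nentropyresp": normalized_entropy(y_binned, 2, denominator="levels"),
    }
    for bit_name, frac in aggregated_fingerprint(fp).items():
        features[f"fp_agg_{bit_name}"] = float(frac)
    return pd.Series(features)
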