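"""Expression-atlas operations: replicate QC, tissue averaging, expressed
filtering, Z-scoring and Tau tissue-specificity classification.

Tau is the canonical max-normalized tissue-specificity index

    tau = sum_i (1 - x_i / max_j x_j) / (N - 1)

computed on the linear per-tissue mean-FPKM profile (N tissues). It ranges
from 0 (uniform expression) to 1 (expression confined to one tissue) and is
invariant to positive rescaling of the profile. Replicate correlations and
Z-scores are computed on log2(FPKM + 1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .models import ExpressionAtlas, ValidationError

__all__ = [
    "replicate_correlation",
    "average_replicates",
    "filter_expressed",
    "compute_tau",
    "classify_tissue_specific",
    "zscore_rows",
]

LOG_PSEUDOCOUNT = 1.0


def log_transform(x: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """log2(FPKM + 1), the pipeline's analysis transform."""
    return np.log2(x + LOG_PSEUDOCOUNT)


def replicate_correlation(atlas: ExpressionAtlas) -> pd.DataFrame:
    """Pairwise Pearson r between biological replicates within each tissue.

    Computed on log2(FPKM+1). Tissues with a single replicate are skipped
    with a warning; a zero-variance replicate yields r = NaN (undefined).

    Returns a table with columns tissue, sample_a, sample_b, r.
    """
    rows = []
    log_m = log_transform(atlas.matrix)
    for tissue in atlas.tissues:
        samples = atlas.samples_for(tissue)
        if len(samples) < 2:
            warnings.warn(f"tissue {tissue!r} has a single replicate; skipped")
            continue
        for i, a in enumerate(samples):
            for b in samples[i + 1 :]:
                x, y = log_m[a].to_numpy(), log_m[b].to_numpy()
                if x.std() == 0 or y.std() == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
                rows.append({"tissue": tissue, "sample_a": a, "sample_b": b, "r": r})
    return pd.DataFrame(rows, columns=["tissue", "sample_a", "sample_b", "r"])


def average_replicates(atlas: ExpressionAtlas) -> pd.DataFrame:
    """Arithmetic mean FPKM per tissue: the expression-atlas profile matrix.

    Returns transcripts x tissues, tissue columns in sample-sheet order,
    transcript order preserved.
    """
    cols = {}
    for tissue in atlas.tissues:
        cols[tissue] = atlas.matrix[atlas.samples_for(tissue)].mean(axis=1)
    return pd.DataFrame(cols, index=atlas.matrix.index)


def filter_expressed(profiles: pd.DataFrame, min_fpkm: float = 0.5) -> list[str]:
    """Transcripts expressed (mean FPKM >= ``min_fpkm``) in at least one tissue.

    The boundary is inclusive.
    """
    keep = profiles.max(axis=1) >= min_fpkm
    return list(profiles.index[keep])


def compute_tau(profile: np.ndarray | pd.Series) -> float:
    """Tissue-specificity index of one linear mean-FPKM profile.

    Returns NaN (undefined) for an all-zero profile; raises for N < 2.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("Tau needs a 1-d profile over >= 2 tissues")
    if (x < 0).any():
        raise ValidationError("negative FPKM in profile")
    m = x.max()
    if m <= 0:
        return float("nan")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def classify_tissue_specific(
    profiles: pd.DataFrame,
    tau_threshold: float = 0.9,
    min_fpkm: float = 0.5,
) -> pd.DataFrame:
    """Tau-based tissue-specificity calls for every transcript.

    A transcript is *eligible* when its maximal tissue mean reaches the FPKM
    floor, and *specific* when additionally tau >= ``tau_threshold`` (both
    boundaries inclusive). The peak tissue is the profile argmax; ties are
    broken by tissue (column) order and flagged.

    Returns a table indexed by transcript with columns tau, peak_tissue,
    is_specific, eligible, peak_tied.
    """
    values = profiles.to_numpy(dtype=float)
    n = values.shape[1]
    if n < 2:
        raise ValidationError("need >= 2 tissues")
    maxima = values.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = values / maxima[:, None]
    tau = np.where(maxima > 0, (1.0 - norm).sum(axis=1) / (n - 1), np.nan)
    peak_idx = values.argmax(axis=1)
    tied = (values == maxima[:, None]).sum(axis=1) > 1
    eligible = maxima >= min_fpkm
    specific = eligible & (tau >= tau_threshold)
    return pd.DataFrame(
        {
            "tau": tau,
            "peak_tissue": [profiles.columns[i] for i in peak_idx],
            "is_specific": specific,
            "eligible": eligible,
            "peak_tied": tied,
        },
        index=profiles.index,
    )


def zscore_rows(profiles: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-scores of log2(FPKM+1) profiles (sample sd, ddof=1).

    Constant rows come back as all zeros rather than NaN.
    """
    log_p = log_transform(profiles.to_numpy(dtype=float))
    mean = log_p.mean(axis=1, keepdims=True)
    sd = log_p.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (log_p - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=profiles.index, columns=profiles.columns)
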