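"""Cross-study harmonization of guide efficiency screens.

Two lentiviral sgRNA screens measured on different affine scales are
combined into one training set: read-count filtering, replicate-day
averaging, an ordinary-least-squares normalization fitted on the guides
the screens share, and duplicate-averaged merging.  Guide identity is
keyed on the full 30-mer expanded target sequence, since features are
computed at that resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EfficiencyDataset",
    "NormalizationModel",
    "DegenerateFitError",
    "filter_min_reads",
    "average_replicates",
    "fit_normalization",
    "apply_normalization",
    "merge_average_duplicates",
    "find_overlap",
    "build_training_set",
]

SEQ = "sequence30"
EFF = "efficiency"
READS = "reads"


class DegenerateFitError(ValueError):
    """Normalization cannot be fitted (too few pairs or constant source)."""


@dataclass
class EfficiencyDataset:
    """A table of guides with efficiency scores on one common scale.

    ``frame`` holds columns ``sequence30``, ``efficiency`` and
    optionally ``reads``; ``scale_tag`` records score provenance.
    """

    frame: pd.DataFrame
    scale_tag: str = "raw"

    def __post_init__(self):
        missing = {SEQ, EFF} - set(self.frame.columns)
        if missing:
            raise ValueError(f"dataset missing required columns: {sorted(missing)}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sequences(self) -> pd.Series:
        return self.frame[SEQ]


@dataclass(frozen=True)
class NormalizationModel:
    """Affine rescaling ``reference = intercept + slope * source``."""

    intercept: float
    slope: float
    n_overlap: int
    residual_sd: float

    def transform(self, scores: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(scores, dtype=float)


def filter_min_reads(ds: EfficiencyDataset, threshold: int) -> EfficiencyDataset:
    """Keep guides with at least *threshold* supporting reads (inclusive)."""
    if READS not in ds.frame.columns or ds.frame[READS].isna().any():
        raise ValueError("read counts required on every record for filtering")
    kept = ds.frame[ds.frame[READS] >= threshold]
    logger.info(
        "read filter >=%d: kept %d of %d guides", threshold, len(kept), len(ds.frame)
    )
    return EfficiencyDataset(kept.copy(), ds.scale_tag)


def average_replicates(
    dsA: EfficiencyDataset, dsB: EfficiencyDataset
) -> EfficiencyDataset:
    """Intersect two replicate measurements and average their efficiencies."""
    a = dsA.frame[[SEQ, EFF]].groupby(SEQ, as_index=False).mean()
    b = dsB.frame[[SEQ, EFF]].groupby(SEQ, as_index=False).mean()
    merged = a.merge(b, on=SEQ, suffixes=("_a", "_b"))
    merged[EFF] = (merged[f"{EFF}_a"] + merged[f"{EFF}_b"]) / 2
    out = merged[[SEQ, EFF]]
    return EfficiencyDataset(out, f"mean({dsA.scale_tag},{dsB.scale_tag})")


def fit_normalization(
    source: np.ndarray, reference: np.ndarray
) -> NormalizationModel:
    """OLS of reference-scale scores on source-scale scores for shared guides."""
    source = np.asarray(source, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if source.shape != reference.shape:
        raise ValueError("source and reference must be paired")
    n = len(source)
    if n < 2 or np.ptp(source) == 0:
        raise DegenerateFitError(
            f"normalization needs >= 2 pairs with non-constant source (n={n})"
        )
    res = stats.linregress(source, reference)
    resid = reference - (res.intercept + res.slope * source)
    dof = max(n - 2, 1)
    return NormalizationModel(
        intercept=float(res.intercept),
        slope=float(res.slope),
        n_overlap=n,
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
    )


def apply_normalization(
    ds: EfficiencyDataset, m: NormalizationModel
) -> EfficiencyDataset:
    frame = ds.frame.copy()
    frame[EFF] = m.transform(frame[EFF].to_numpy())
    return EfficiencyDataset(frame, f"{ds.scale_tag}->rescaled")


def merge_average_duplicates(
    datasets: list[EfficiencyDataset], scale_tag: str = "merged"
) -> EfficiencyDataset:
    """Union of guides across datasets; shared guides get the unweighted mean."""
    if not datasets:
        raise ValueError("nothing to merge")
    frames = [d.frame[[SEQ, EFF]] for d in datasets]
    stacked = pd.concat(frames, ignore_index=True)
    merged = stacked.groupby(SEQ, as_index=False, sort=True).mean()
    return EfficiencyDataset(merged, scale_tag)


def find_overlap(
    dsA: EfficiencyDataset, dsB: EfficiencyDataset
) -> pd.DataFrame:
    """Guides shared by two datasets, with both efficiency columns."""
    return dsA.frame[[SEQ, EFF]].merge(
        dsB.frame[[SEQ, EFF]], on=SEQ, suffixes=("_a", "_b")
    )


def build_training_set(
    screen_a_train: EfficiencyDataset,
    screen_a_test: EfficiencyDataset,
    screen_b_day8: EfficiencyDataset,
    screen_b_day10: EfficiencyDataset,
    read_threshold: int = 200,
) -> tuple[EfficiencyDataset, NormalizationModel, dict]:
    """Full harmonization pipeline for two overlapping screens.

    The first screen's train/test tables are merged with duplicate
    averaging; the second screen's two assay days are read-filtered then
    intersection-averaged; an affine normalization is fitted on the
    overlap (reference = first screen) and applied to the second; the
    rescaled second screen is merged into the first.  Returns the
    combined dataset, the fitted normalization, and a report of all
    intermediate counts.
    """
    screen_a = merge_average_duplicates(
        [screen_a_train, screen_a_test], scale_tag="screenA"
    )
    screen_b = average_replicates(
        filter_min_reads(screen_b_day8, read_threshold),
        filter_min_reads(screen_b_day10, read_threshold),
    )
    overlap = find_overlap(screen_b, screen_a)
    model = fit_normalization(
        overlap[f"{EFF}_a"].to_numpy(), overlap[f"{EFF}_b"].to_numpy()
    )
    screen_b_rescaled = apply_normalization(screen_b, model)
    combined = merge_average_duplicates(
        [screen_a, screen_b_rescaled], scale_tag="screenA"
    )
    report = {
        "n_screenA_merged": len(screen_a),
        "n_screenB_unique": len(screen_b),
        "n_overlap": int(len(overlap)),
        "n_combined_unique": len(combined),
        "norm_intercept": model.intercept,
        "norm_slope": model.slope,
    }
    logger.info("harmonization counts: %s", report)
    return combined, model, report
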