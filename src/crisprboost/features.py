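"""Sequence-derived features for the 149-column predictor input.

Feature blocks, in fixed schema order:

* ``gc`` -- GC fraction of the 30-mer (1 numeric feature);
* k-mer counts for k = 1, 2, 3 over the whole 30-mer, overlapping
  windows, lexicographic order (4 + 16 + 64 numeric features, named by
  the k-mer itself, e.g. ``TT``);
* poly-T summaries: number of maximal T-runs of length >= 3 and the
  length of the longest maximal T-run (2 numeric features) -- T-runs are
  RNA-polymerase-III termination signals that depress guide expression;
* thermodynamic features from :mod:`crisprboost.thermo` (Tm1-Tm4,
  dG_spacer, dG_full; 6 numeric features);
* position-specific mononucleotides, one categorical feature per label
  -4..-1, 1..21, +1..+3 (28 features; the static GG at labels 22-23 is
  dropped), named ``mono<label>``;
* position-specific dinucleotides keyed by start label, all adjacent
  pairs except the static (22,23) pair (28 categorical features), named
  ``di<label>`` -- so ``di-1`` spans the -1/1 boundary, ``di20`` spans
  spacer end + PAM 'N', and ``di23`` spans the PAM/downstream boundary.

Total: 93 numeric + 56 categorical = 149 features.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .targets import LABEL_TO_OFFSET, POSITION_LABELS, ExpandedTarget
from .thermo import ThermoFeatures

__all__ = [
    "NUCLEOTIDES",
    "DINUCLEOTIDES",
    "MONO_LABELS",
    "DI_LABELS",
    "FeatureSchema",
    "SCHEMA",
    "kmer_counts",
    "gc_content",
    "polyt_features",
    "positional_mononucleotides",
    "positional_dinucleotides",
    "featurize",
    "featurize_frame",
]

NUCLEOTIDES = ("A", "C", "G", "T")
DINUCLEOTIDES = tuple("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=2))
TRINUCLEOTIDES = tuple("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))

#: Labels carrying a positional mononucleotide feature (static PAM GG removed).
MONO_LABELS: tuple[str, ...] = tuple(
    lab for lab in POSITION_LABELS if lab not in ("22", "23")
)

#: Start labels of positional dinucleotide features (pair (22,23) removed).
DI_LABELS: tuple[str, ...] = tuple(
    POSITION_LABELS[i] for i in range(29) if POSITION_LABELS[i] != "22"
)

THERMO_NAMES = ("Tm1", "Tm2", "Tm3", "Tm4", "dG_spacer", "dG_full")


@dataclass(frozen=True)
class FeatureSchema:
    """Fixed feature order, dtypes, and categorical vocabularies.

    The schema is persisted alongside any trained model so that
    category-to-code mappings stay stable between training and
    prediction.
    """

    numeric: tuple[str, ...] = field(default_factory=tuple)
    categorical: tuple[str, ...] = field(default_factory=tuple)
    vocabularies: dict = field(default_factory=dict)

    @property
    def names(self) -> tuple[str, ...]:
        return self.numeric + self.categorical

    @property
    def width(self) -> int:
        return len(self.numeric) + len(self.categorical)

    def empty_frame(self, n_rows: int) -> pd.DataFrame:
        cols: dict[str, pd.Series] = {}
        for name in self.numeric:
            cols[name] = pd.Series(np.zeros(n_rows), dtype=float)
        for name in self.categorical:
            cols[name] = pd.Series(
                pd.Categorical([None] * n_rows, categories=self.vocabularies[name])
            )
        return pd.DataFrame(cols)

    def to_json(self) -> str:
        return json.dumps(
            {
                "numeric": list(self.numeric),
                "categorical": list(self.categorical),
                "vocabularies": {k: list(v) for k, v in self.vocabularies.items()},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        d = json.loads(text)
        return cls(
            numeric=tuple(d["numeric"]),
            categorical=tuple(d["categorical"]),
            vocabularies={k: tuple(v) for k, v in d["vocabularies"].items()},
        )

    def validate_frame(self, frame: pd.DataFrame) -> None:
        """Raise ``SchemaError`` if *frame* does not conform to the schema."""
        missing = [c for c in self.names if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing feature columns: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        extra = [c for c in frame.columns if c not in self.names]
        if extra:
            raise SchemaError(f"unexpected feature columns: {extra[:5]}")


class SchemaError(ValueError):
    pass


def _build_default_schema() -> FeatureSchema:
    numeric = (
        ("gc",)
        + NUCLEOTIDES
        + DINUCLEOTIDES
        + TRINUCLEOTIDES
        + ("n_polyT", "max_polyT")
        + THERMO_NAMES
    )
    categorical = tuple(f"mono{lab}" for lab in MONO_LABELS) + tuple(
        f"di{lab}" for lab in DI_LABELS
    )
    vocab = {f"mono{lab}": NUCLEOTIDES for lab in MONO_LABELS}
    vocab.update({f"di{lab}": DINUCLEOTIDES for lab in DI_LABELS})
    return FeatureSchema(numeric=numeric, categorical=categorical, vocabularies=vocab)


#: The canonical 149-feature schema (93 numeric + 56 categorical).
SCHEMA: FeatureSchema = _build_default_schema()


def kmer_counts(
    target: ExpandedTarget, k: int, *, proportions: bool = False
) -> np.ndarray:
    """Counts of all overlapping k-windows, fixed lexicographic k-mer order.

    Returns a length-``4**k`` integer vector summing to ``30 - k + 1``
    (or the corresponding proportions when ``proportions=True``).
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    seq = target.sequence
    kmers = (NUCLEOTIDES, DINUCLEOTIDES, TRINUCLEOTIDES)[k - 1]
    index = {km: i for i, km in enumerate(kmers)}
    counts = np.zeros(len(kmers), dtype=np.int64)
    for i in range(len(seq) - k + 1):
        counts[index[seq[i : i + k]]] += 1
    if proportions:
        return counts / counts.sum()
    return counts


def gc_content(target: ExpandedTarget) -> float:
    """GC fraction of the full 30-mer, in [0, 1]."""
    seq = target.sequence
    return (seq.count("G") + seq.count("C")) / len(seq)


def _t_runs(seq: str) -> list[int]:
    runs, run = [], 0
    for ch in seq:
        if ch == "T":
            run += 1
        elif run:
            runs.append(run)
            run = 0
    if run:
        runs.append(run)
    return runs


def polyt_features(
    target: ExpandedTarget, *, min_run_for_max: int = 1
) -> tuple[int, int]:
    """Poly-T summaries of the 30-mer.

    Returns ``(n_polyT_segments, max_polyT_length)`` where a poly-T
    segment is a maximal run of >= 3 consecutive Ts.  ``max_polyT_length``
    reports the longest maximal T-run unconditionally by default (so
    values 1 and 2 occur); pass ``min_run_for_max=3`` to zero out runs
    shorter than a segment.
    """
    runs = _t_runs(target.sequence)
    n_seg = sum(1 for r in runs if r >= 3)
    longest = max(runs, default=0)
    if longest < min_run_for_max:
        longest = 0
    return n_seg, longest


def positional_mononucleotides(target: ExpandedTarget) -> dict[str, str]:
    """One nucleotide per label in -4..-1, 1..21, +1..+3 (28 values)."""
    return {lab: target.sequence[LABEL_TO_OFFSET[lab]] for lab in MONO_LABELS}


def positional_dinucleotides(target: ExpandedTarget) -> dict[str, str]:
    """Adjacent nucleotide pairs keyed by start label (28 values).

    The pair starting at label 22 (the static GG) is excluded; di-1
    spans the upstream/spacer boundary and di23 spans the PAM/downstream
    boundary.
    """
    seq = target.sequence
    out = {}
    for lab in DI_LABELS:
        i = LABEL_TO_OFFSET[lab]
        out[lab] = seq[i : i + 2]
    return out


def featurize(
    target: ExpandedTarget,
    thermo: ThermoFeatures,
    *,
    kmer_proportions: bool = False,
    polyt_min_run_for_max: int = 1,
) -> dict[str, float | str]:
    """Assemble the full 149-feature record for one target.

    The thermodynamic features must have been computed for the same
    target; this function does not recheck that.
    """
    row: dict[str, float | str] = {"gc": gc_content(target)}
    for k, kmers in zip((1, 2, 3), (NUCLEOTIDES, DINUCLEOTIDES, TRINUCLEOTIDES)):
        counts = kmer_counts(target, k, proportions=kmer_proportions)
        row.update(zip(kmers, counts.tolist()))
    n_seg, longest = polyt_features(target, min_run_for_max=polyt_min_run_for_max)
    row["n_polyT"] = n_seg
    row["max_polyT"] = longest
    for name, value in zip(THERMO_NAMES, thermo.as_tuple()):
        row[name] = value
    for lab, base in positional_mononucleotides(target).items():
        row[f"mono{lab}"] = base
    for lab, pair in positional_dinucleotides(target).items():
        row[f"di{lab}"] = pair
    assert len(row) == SCHEMA.width
    return row


def featurize_frame(
    targets: list[ExpandedTarget],
    thermos: list[ThermoFeatures],
    *,
    kmer_proportions: bool = False,
    polyt_min_run_for_max: int = 1,
) -> pd.DataFrame:
    """Feature table for many targets, schema order, categorical dtypes fixed.

    Categorical columns use pandas ``Categorical`` with the full fixed
    vocabulary so category codes are stable regardless of which levels
    happen to occur in the data.
    """
    if len(targets) != len(thermos):
        raise ValueError("targets and thermo features must align one-to-one")
    rows = [
        featurize(
            t,
            th,
            kmer_proportions=kmer_proportions,
            polyt_min_run_for_max=polyt_min_run_for_max,
        )
        for t, th in zip(targets, thermos)
    ]
    frame = pd.DataFrame(rows, columns=list(SCHEMA.names))
    for name in SCHEMA.numeric:
        frame[name] = frame[name].astype(float)
    for name in SCHEMA.categorical:
        frame[name] = pd.Categorical(
            frame[name], categories=SCHEMA.vocabularies[name]
        )
    return frame
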