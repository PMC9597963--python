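"""Synthetic sgRNA screens with planted, analytically known sequence effects.

The generator emulates the statistical structure of lentiviral
guide-efficiency screens at desk scale: a baseline efficiency around the
mid-40s (indel %, 0-100 scale), a poly-T penalty growing with the
longest T-run (Pol III termination), a quadratic GC-content optimum, a
handful of positional-dinucleotide category offsets concentrated at the
3' end of the spacer, plus Gaussian noise and clipping to the score
bounds.  A paired-screen variant reproduces the cross-study setting: a
second screen observes an affine transform of the same true signal on
two replicate days with per-guide read counts, sharing a configurable
overlap of guides with the first screen.

Every draw is deterministic given the config seed, and the noiseless
signal is returned alongside the observed scores so recovery can be
tested exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import gc_content, polyt_features, positional_dinucleotides
from .harmonize import EfficiencyDataset
from .targets import ExpandedTarget, validate_target

logger = logging.getLogger(__name__)

__all__ = ["GeneratorConfig", "random_target", "simulate_dataset", "simulate_paired_screens"]


def _default_di_effects() -> dict:
    # Positional dinucleotide offsets mirroring the dominant 3'-end
    # categories seen in real screens: favourable GA / unfavourable AT
    # at position 19, with smaller effects at 18 and 20.
    return {
        "19": {"GA": 4.0, "AT": -4.2, "TT": -3.0},
        "18": {"TG": 1.8, "AA": -6.7},
        "20": {"GA": 2.5, "GC": 2.5, "GG": 2.5, "GT": 2.5},
    }


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic screen; defaults are the study conditions.

    ``polyT_penalty`` is applied per unit of the longest T-run above 2
    (so a TTT guide loses one unit, TTTT two); ``gc_curvature`` scales
    the squared deviation of GC fraction from ``gc_center``.  Screen B
    of the paired variant reports ``affine_a + affine_b * signal`` plus
    its own noise; read counts fall below 200 with probability
    ``low_read_fraction``.
    """

    n_guides: int = 5000
    baseline: float = 45.0
    polyT_penalty: float = -10.0
    gc_center: float = 0.55
    gc_curvature: float = -80.0
    di_effects: dict = field(default_factory=_default_di_effects)
    noise_sd: float = 10.0
    bounds: tuple[float, float] = (0.0, 100.0)
    affine_a: float = -6.0
    affine_b: float = 1.25
    overlap: int = 49
    low_read_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_guides <= 0:
            raise ValueError("n_guides must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must be ordered")
        if not 0 <= self.overlap <= self.n_guides:
            raise ValueError("overlap must be within [0, n_guides]")


_BASES = np.array(list("ACGT"))


def random_target(rng: np.random.Generator) -> ExpandedTarget:
    """Uniform random 30-mer with the GG of the NGG PAM fixed."""
    letters = _BASES[rng.integers(0, 4, size=30)]
    letters[25] = "G"
    letters[26] = "G"
    return validate_target("".join(letters))


def _signal(cfg: GeneratorConfig, target: ExpandedTarget) -> float:
    s = cfg.baseline
    _, longest = polyt_features(target)
    s += cfg.polyT_penalty * max(0, longest - 2)
    gc = gc_content(target)
    s += cfg.gc_curvature * (gc - cfg.gc_center) ** 2
    dis = positional_dinucleotides(target)
    for label, offsets in cfg.di_effects.items():
        s += offsets.get(dis[label], 0.0)
    return s


def _reads(rng: np.random.Generator, n: int, low_fraction: float) -> np.ndarray:
    low = rng.random(n) < low_fraction
    reads = rng.integers(200, 2000, size=n)
    reads[low] = rng.integers(0, 200, size=int(low.sum()))
    return reads


def simulate_dataset(
    cfg: GeneratorConfig,
) -> tuple[EfficiencyDataset, np.ndarray]:
    """One screen: returns the observed dataset and the noiseless signal.

    Observed efficiency = clip(signal + N(0, noise_sd), bounds); the
    fraction of guides hitting a bound is logged so planted effects stay
    analytically known away from the clip.
    """
    rng = np.random.default_rng(cfg.seed)
    targets = _unique_targets(rng, cfg.n_guides)
    signal = np.array([_signal(cfg, t) for t in targets])
    noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_guides)
    observed = np.clip(signal + noise, *cfg.bounds)
    clipped = np.mean((signal + noise < cfg.bounds[0]) | (signal + noise > cfg.bounds[1]))
    if clipped:
        logger.info("clipping applied to %.1f%% of guides", 100 * clipped)
    frame = pd.DataFrame(
        {
            "sequence30": [t.sequence for t in targets],
            "efficiency": observed,
            "reads": _reads(rng, cfg.n_guides, cfg.low_read_fraction),
        }
    )
    return EfficiencyDataset(frame, scale_tag="synthetic"), signal


def _unique_targets(rng: np.random.Generator, n: int) -> list[ExpandedTarget]:
    seen: set[str] = set()
    out: list[ExpandedTarget] = []
    while len(out) < n:
        t = random_target(rng)
        if t.sequence not in seen:
            seen.add(t.sequence)
            out.append(t)
    return out


def simulate_paired_screens(
    cfg: GeneratorConfig,
) -> tuple[EfficiencyDataset, EfficiencyDataset, EfficiencyDataset, dict]:
    """Two overlapping screens with a known affine link.

    Screen A observes the signal directly (plus noise).  Screen B covers
    a different guide panel sharing exactly ``cfg.overlap`` guides with
    A, observed twice (two assay days, independent noise) on the scale
    ``affine_a + affine_b * signal``, with read counts for filtering.
    Returns (screen_A, screen_B_day8, screen_B_day10, truth) where
    ``truth`` holds the overlap keys, the affine parameters, and the
    per-guide noiseless signals.
    """
    rng = np.random.default_rng(cfg.seed)
    n_a = cfg.n_guides
    n_b = cfg.n_guides
    total = n_a + n_b - cfg.overlap
    targets = _unique_targets(rng, total)
    a_targets = targets[:n_a]
    b_targets = targets[n_a - cfg.overlap : total]
    sig_a = np.array([_signal(cfg, t) for t in a_targets])
    sig_b = np.array([_signal(cfg, t) for t in b_targets])

    lo, hi = cfg.bounds
    obs_a = np.clip(sig_a + rng.normal(0, cfg.noise_sd, n_a), lo, hi)
    screen_a = EfficiencyDataset(
        pd.DataFrame(
            {
                "sequence30": [t.sequence for t in a_targets],
                "efficiency": obs_a,
                "reads": _reads(rng, n_a, cfg.low_read_fraction),
            }
        ),
        scale_tag="screenA",
    )

    def day(tag: str) -> EfficiencyDataset:
        obs = cfg.affine_a + cfg.affine_b * sig_b + rng.normal(0, cfg.noise_sd, n_b)
        return EfficiencyDataset(
            pd.DataFrame(
                {
                    "sequence30": [t.sequence for t in b_targets],
                    "efficiency": obs,
                    "reads": _reads(rng, n_b, cfg.low_read_fraction),
                }
            ),
            scale_tag=tag,
        )

    truth = {
        "overlap_sequences": {t.sequence for t in targets[n_a - cfg.overlap : n_a]},
        "affine_a": cfg.affine_a,
        "affine_b": cfg.affine_b,
        "signal_a": sig_a,
        "signal_b": sig_b,
    }
    return screen_a, day("screenB_day8"), day("screenB_day10"), truth
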