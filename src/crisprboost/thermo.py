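"""Thermodynamic features: duplex melting temperatures and RNA folding energy.

Four nearest-neighbor melting temperatures are computed over sub-regions
of the spacer + first PAM base (labels 1-21): Tm1 over 1-21, Tm2 over
1-4, Tm3 over 5-12, and Tm4 over 16-20.  Defaults use the unified
SantaLucia (2004) DNA/DNA parameter table with 50 mM Na+ and 25 nM
strand concentrations.

Two minimum-free-energy features come from RNA secondary-structure
prediction at 37 degC: dG_spacer folds the transcribed 20-nt spacer
alone, and dG_full folds the spacer joined to the 81-nt wild-type
SpCas9 scaffold (101 nt).  The folding engine is pluggable: the default
shells out to an RNAfold-compatible program; a deterministic stub keeps
pipelines runnable and reproducible without one.
"""

from __future__ import annotations

import hashlib
import logging
import re
import shutil
import subprocess
from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

from .targets import ExpandedTarget

logger = logging.getLogger(__name__)

__all__ = [
    "TmParameters",
    "ThermoFeatures",
    "ScaffoldConfig",
    "DEFAULT_SCAFFOLD",
    "FoldingEngine",
    "RNAfoldEngine",
    "HashStubEngine",
    "EngineUnavailableError",
    "melting_temperature",
    "tm_features",
    "mfe",
    "free_energy_features",
    "compute_thermo",
    "compute_thermo_many",
]

# Tm region boundaries as array offsets into the 30-mer (inclusive start,
# exclusive end).  Labels: Tm1 = 1-21, Tm2 = 1-4, Tm3 = 5-12, Tm4 = 16-20.
TM_REGIONS = {
    "Tm1": (4, 25),
    "Tm2": (4, 8),
    "Tm3": (8, 16),
    "Tm4": (19, 24),
}


@dataclass(frozen=True)
class TmParameters:
    """Nearest-neighbor Tm settings.

    ``table`` names a Biopython NN parameter table; DNA_NN4 is the
    unified SantaLucia (2004) DNA/DNA set.  Concentrations are nM
    (strands) and mM (Na+); ``saltcorr`` selects the salt-correction
    formula (5 = SantaLucia 1998 entropy correction).
    """

    table: str = "DNA_NN4"
    na_mM: float = 50.0
    dnac1_nM: float = 25.0
    dnac2_nM: float = 25.0
    saltcorr: int = 5

    def as_dict(self) -> dict:
        return {
            "table": self.table,
            "na_mM": self.na_mM,
            "dnac1_nM": self.dnac1_nM,
            "dnac2_nM": self.dnac2_nM,
            "saltcorr": self.saltcorr,
        }


@dataclass(frozen=True)
class ThermoFeatures:
    Tm1: float
    Tm2: float
    Tm3: float
    Tm4: float
    dG_spacer: float
    dG_full: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.Tm1, self.Tm2, self.Tm3, self.Tm4, self.dG_spacer, self.dG_full)


# Canonical wild-type SpCas9 sgRNA scaffold: the 76-nt constant segment
# followed by the 5-U Pol III terminator (81 nt total).
DEFAULT_SCAFFOLD = (
    "GUUUUAGAGCUAGAAAUAGCAAGUUAAAAUAAGGCUAGUCCGUUAUCAACUUGAAAAAGUGGCACCGAGUCGGUGC"
    "UUUUU"
)


@dataclass(frozen=True)
class ScaffoldConfig:
    """The constant sgRNA scaffold appended to the spacer for full-guide folding."""

    scaffold_seq: str = DEFAULT_SCAFFOLD

    def __post_init__(self):
        seq = self.scaffold_seq.upper().replace("T", "U")
        object.__setattr__(self, "scaffold_seq", seq)
        if len(seq) != 81:
            raise ValueError(f"scaffold must be 81 nt, got {len(seq)}")
        if set(seq) - set("ACGU"):
            raise ValueError("scaffold must be RNA over A/C/G/U")


class EngineUnavailableError(RuntimeError):
    """The configured folding engine cannot be run."""


def melting_temperature(dna: str, params: TmParameters | None = None) -> float:
    """Nearest-neighbor duplex melting temperature in degC.

    Deterministic given the parameter set; the duplex partner is the
    exact reverse complement at equal concentration.
    """
    params = params or TmParameters()
    if len(dna) < 2:
        raise ValueError(f"Tm needs at least 2 nt, got {len(dna)}")
    seq = dna.upper()
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-DNA character in Tm input {dna!r}")
    table = getattr(_mt, params.table)
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=table,
            Na=params.na_mM,
            dnac1=params.dnac1_nM,
            dnac2=params.dnac2_nM,
            saltcorr=params.saltcorr,
        )
    )


def tm_features(
    target: ExpandedTarget, params: TmParameters | None = None
) -> tuple[float, float, float, float]:
    """(Tm1, Tm2, Tm3, Tm4) over spacer regions 1-21, 1-4, 5-12, 16-20."""
    seq = target.sequence
    return tuple(
        melting_temperature(seq[a:b], params) for a, b in TM_REGIONS.values()
    )


class FoldingEngine:
    """Interface: fold RNA sequences, return minimum free energies (kcal/mol)."""

    name = "abstract"

    def fold_many(self, sequences: list[str]) -> list[float]:
        raise NotImplementedError

    def fold(self, sequence: str) -> float:
        return self.fold_many([sequence])[0]


_ENERGY_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


class RNAfoldEngine(FoldingEngine):
    """Folding via an external RNAfold-compatible executable.

    Protocol: one plain sequence per stdin line; for each, the program
    prints the sequence then a ``structure (energy)`` line, parsed
    bit-exactly.  Sequences are batched through a single subprocess.
    """

    name = "RNAfold"

    def __init__(self, executable: str = "RNAfold", extra_args: tuple[str, ...] = ("--noPS",)):
        self.executable = executable
        self.extra_args = extra_args

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def fold_many(self, sequences: list[str]) -> list[float]:
        if not sequences:
            return []
        if not self.available():
            raise EngineUnavailableError(
                f"folding engine {self.executable!r} not found on PATH"
            )
        stdin = "\n".join(sequences) + "\n"
        proc = subprocess.run(
            [self.executable, *self.extra_args],
            input=stdin,
            capture_output=True,
            text=True,
            check=True,
        )
        energies: list[float] = []
        for line in proc.stdout.splitlines():
            m = _ENERGY_RE.search(line)
            if m:
                energies.append(float(m.group(1)))
        if len(energies) != len(sequences):
            raise RuntimeError(
                f"{self.executable} returned {len(energies)} energies "
                f"for {len(sequences)} sequences"
            )
        return energies


class HashStubEngine(FoldingEngine):
    """Deterministic stand-in folding engine for pipeline tests.

    Maps each sequence to a reproducible pseudo-energy in [-20, 0] via a
    stable hash.  Carries no thermodynamic meaning; it exists so the
    pipeline contract (finite dG <= 0, reproducibility) can be exercised
    without invoking an external program.
    """

    name = "hash-stub"

    def fold_many(self, sequences: list[str]) -> list[float]:
        out = []
        for seq in sequences:
            h = int(hashlib.md5(seq.encode()).hexdigest()[:8], 16)
            out.append(-round((h % 2000) / 100.0, 2))
        return out


def mfe(rna: str, engine: FoldingEngine) -> float:
    """Minimum free energy (kcal/mol) of one RNA sequence at 37 degC."""
    if not rna:
        raise ValueError("empty sequence has no folding energy")
    seq = rna.upper()
    if "T" in seq:
        logger.info("transcribing DNA input to RNA for folding (T -> U)")
        seq = seq.replace("T", "U")
    if set(seq) - set("ACGU"):
        raise ValueError(f"non-RNA character in folding input {rna!r}")
    return engine.fold(seq)


def free_energy_features(
    target: ExpandedTarget,
    scaffold: ScaffoldConfig,
    engine: FoldingEngine,
) -> tuple[float, float]:
    """(dG_spacer, dG_full): fold the 20-nt spacer, then spacer + scaffold."""
    spacer_rna = target.spacer.replace("T", "U")
    full = spacer_rna + scaffold.scaffold_seq
    e_spacer, e_full = engine.fold_many([spacer_rna, full])
    return e_spacer, e_full


def compute_thermo(
    target: ExpandedTarget,
    *,
    tm_params: TmParameters | None = None,
    scaffold: ScaffoldConfig | None = None,
    engine: FoldingEngine | None = None,
) -> ThermoFeatures:
    return compute_thermo_many(
        [target], tm_params=tm_params, scaffold=scaffold, engine=engine
    )[0]


def compute_thermo_many(
    targets: list[ExpandedTarget],
    *,
    tm_params: TmParameters | None = None,
    scaffold: ScaffoldConfig | None = None,
    engine: FoldingEngine | None = None,
) -> list[ThermoFeatures]:
    """Thermo features for many targets, batching all folding calls."""
    tm_params = tm_params or TmParameters()
    scaffold = scaffold or ScaffoldConfig()
    engine = engine or RNAfoldEngine()
    spacers = [t.spacer.replace("T", "U") for t in targets]
    fulls = [s + scaffold.scaffold_seq for s in spacers]
    energies = engine.fold_many(spacers + fulls)
    n = len(targets)
    out = []
    for i, t in enumerate(targets):
        tm1, tm2, tm3, tm4 = tm_features(t, tm_params)
        out.append(
            ThermoFeatures(tm1, tm2, tm3, tm4, energies[i], energies[n + i])
        )
    return out
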