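"""Seeded generator of PrLD-like labeled sequences.

Emulates the compositional contrast between PrLDs that are recruited into
heat-induced stress granules and those that are not: positives are
enriched in hydrophobic (W, F, I, L, V) and charged (H, E, K, R) residues
and carry some cysteine, with cationic residues outweighing anionic ones
(expected NCPR > 0); negatives are Q/N-rich, polar and slightly anionic,
with almost no cysteine. Sequences are drawn i.i.d. per residue from a
class composition profile — every feature the classifier consumes is
composition- or window-average-based, so positional structure is not
modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError
from .features import PKaTable, residue_charge
from .sequence_io import (
    CANONICAL_RESIDUES,
    NEGATIVE,
    POSITIVE,
    LabeledDataset,
    SequenceRecord,
)

RESIDUE_ORDER = tuple(sorted(CANONICAL_RESIDUES))

# Default training-condition sizes: 32 recruited + 32 non-recruited PrLDs.
DEFAULT_N_POS = 32
DEFAULT_N_NEG = 32
DEFAULT_LENGTH_MIN = 60
DEFAULT_LENGTH_MAX = 250

_POSITIVE_FREQS: dict[str, float] = {
    # hydrophobic / aggregation-prone
    "W": 0.030, "F": 0.050, "I": 0.070, "L": 0.090, "V": 0.080,
    # charged, cationic mass (K+R+H) above anionic (D+E)
    "H": 0.030, "E": 0.050, "K": 0.060, "R": 0.050, "D": 0.030,
    # disulfide potential
    "C": 0.015,
    # background
    "A": 0.060, "G": 0.070, "M": 0.020, "N": 0.040, "P": 0.050,
    "Q": 0.050, "S": 0.080, "T": 0.050, "Y": 0.025,
}

_NEGATIVE_FREQS: dict[str, float] = {
    # Q/N-rich, polar, classical prion-domain-like
    "Q": 0.140, "N": 0.140, "G": 0.100, "S": 0.120, "Y": 0.060,
    # slightly anionic: D+E above K+R+H
    "D": 0.035, "E": 0.035, "K": 0.020, "R": 0.020, "H": 0.015,
    # cysteine nearly absent
    "C": 0.0015,
    # hydrophobics depleted
    "W": 0.005, "F": 0.010, "I": 0.015, "L": 0.025, "V": 0.020,
    # background
    "A": 0.060, "M": 0.010, "P": 0.080, "T": 0.0885,
}


@dataclass(frozen=True)
class CompositionProfile:
    """Residue-frequency distribution used to sample sequences."""

    name: str
    freqs: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.freqs) != CANONICAL_RESIDUES:
            raise ConfigurationError(
                f"profile {self.name!r} must cover exactly the 20 canonical residues"
            )
        if any(f < 0 for f in self.freqs.values()):
            raise ConfigurationError(f"profile {self.name!r} has negative frequencies")
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"profile {self.name!r} frequencies sum to {total}, expected 1"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.freqs[r] for r in RESIDUE_ORDER])

    def expected_ncpr(self, ph: float, table: PKaTable) -> float:
        """Closed-form expected NCPR: frequency-weighted residue charges."""
        return sum(
            f * residue_charge(res, ph, table) for res, f in self.freqs.items()
        )

    def expected_cys_pct(self) -> float:
        return 100.0 * self.freqs["C"]


@dataclass(frozen=True)
class GeneratorConfig:
    n_pos: int = DEFAULT_N_POS
    n_neg: int = DEFAULT_N_NEG
    length_min: int = DEFAULT_LENGTH_MIN
    length_max: int = DEFAULT_LENGTH_MAX
    pos_profile: CompositionProfile = field(
        default_factory=lambda: default_profiles()[0]
    )
    neg_profile: CompositionProfile = field(
        default_factory=lambda: default_profiles()[1]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ConfigurationError("sample counts must be non-negative")
        if not 0 < self.length_min <= self.length_max:
            raise ConfigurationError(
                f"need 0 < length_min <= length_max, got "
                f"({self.length_min}, {self.length_max})"
            )


def default_profiles() -> tuple[CompositionProfile, CompositionProfile]:
    """The default recruited / non-recruited composition profiles."""
    return (
        CompositionProfile(name="sg-positive", freqs=_POSITIVE_FREQS),
        CompositionProfile(name="sg-negative", freqs=_NEGATIVE_FREQS),
    )


def _sample_sequence(
    rng: np.random.Generator, length: int, freqs: np.ndarray
) -> str:
    letters = rng.choice(len(RESIDUE_ORDER), size=length, p=freqs)
    return "".join(RESIDUE_ORDER[i] for i in letters)


def generate_dataset(config: GeneratorConfig | None = None) -> LabeledDataset:
    """Draw a labeled synthetic PrLD dataset.

    Record ids encode class and index (``pos_0001`` ...); sequence lengths
    are uniform on [length_min, length_max]; deterministic for a fixed
    seed.
    """
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    records: list[SequenceRecord] = []
    labels: list[str] = []
    for cls, n, profile in (
        (POSITIVE, config.n_pos, config.pos_profile),
        (NEGATIVE, config.n_neg, config.neg_profile),
    ):
        freqs = profile.as_array()
        prefix = "pos" if cls == POSITIVE else "neg"
        for i in range(n):
            length = int(rng.integers(config.length_min, config.length_max + 1))
            seq = _sample_sequence(rng, length, freqs)
            records.append(
                SequenceRecord(
                    id=f"{prefix}_{i + 1:04d}",
                    residues=seq,
                    description=f"synthetic {cls} PrLD",
                )
            )
            labels.append(cls)
    return LabeledDataset(records=records, labels=labels)
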