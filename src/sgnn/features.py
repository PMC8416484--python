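"""Sequence-derived biophysical features for stress-granule prediction.

Three features are computed per PrLD, and together form the classifier
input:

1. **Aggregation propensity** — an AGGRESCAN-style score. Each residue
   carries an intrinsic aggregation-propensity value (a3v); a sliding
   window averages these into per-position values (a4v); the
   length-normalized summary ``Na4vSS = mean(a4v) * 100`` condenses the
   profile into one number, which is then min-max normalized between the
   least and most aggregation-prone reference PrLDs so the network only
   sees values in [0, 1].
2. **Net charge per residue (NCPR)** — total sequence charge at a given pH
   divided by length, with per-group fractional charges from the
   Henderson–Hasselbalch equation.
3. **Cysteine percentage** — 100 x count(C) / length, a proxy for
   disulfide-bonding potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    InvalidResidueError,
    ParameterError,
    SequenceLengthError,
)
from .sequence_io import CANONICAL_RESIDUES, SequenceRecord

ACIDIC = "acidic"
BASIC = "basic"

# AGGRESCAN-style length-dependent window rule: (max sequence length, window).
# Longer sequences use wider windows; the last band is open-ended.
DEFAULT_WINDOW_BANDS: tuple[tuple[int, int], ...] = (
    (75, 5),
    (175, 7),
    (300, 9),
    (10**9, 11),
)

DEFAULT_PH = 7.0


@dataclass(frozen=True)
class PropensityScale:
    """Named per-residue aggregation-propensity scale (a3v values)."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = CANONICAL_RESIDUES - set(self.values)
        extra = set(self.values) - CANONICAL_RESIDUES
        if missing or extra:
            raise ConfigurationError(
                f"scale {self.name!r} must cover exactly the 20 canonical "
                f"residues (missing {sorted(missing)}, extra {sorted(extra)})"
            )


@dataclass(frozen=True)
class PKaEntry:
    pka: float
    polarity: str

    def __post_init__(self) -> None:
        if not 0.0 < self.pka < 14.0:
            raise ConfigurationError(f"pKa {self.pka} outside (0, 14)")
        if self.polarity not in (ACIDIC, BASIC):
            raise ConfigurationError(f"polarity must be acidic/basic, got {self.polarity!r}")


@dataclass(frozen=True)
class PKaTable:
    """Ionizable-group pKa values for Henderson–Hasselbalch charges.

    ``include_termini`` controls whether free N-/C-terminal charges are
    added; default off, because PrLDs are internal domains of larger
    proteins and free termini would be artifactual.
    """

    entries: Mapping[str, PKaEntry]
    include_termini: bool = False
    nterm_pka: float = 8.0
    cterm_pka: float = 3.1

    def __post_init__(self) -> None:
        required = {"D", "E", "C", "Y", "H", "K", "R"}
        missing = required - set(self.entries)
        if missing:
            raise ConfigurationError(f"pKa table missing residues {sorted(missing)}")


@dataclass(frozen=True)
class NormalizationBounds:
    """Na4vSS anchors: least (min) and most (max) aggregation-prone reference."""

    na4vss_min: float
    na4vss_max: float

    def __post_init__(self) -> None:
        if not self.na4vss_min < self.na4vss_max:
            raise ConfigurationError(
                f"na4vss_min ({self.na4vss_min}) must be < na4vss_max "
                f"({self.na4vss_max})"
            )


@dataclass(frozen=True)
class FeatureVector:
    """The three classifier inputs (plus the raw aggregation score)."""

    agg_raw: float
    agg_norm: float
    ncpr: float
    cys_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.agg_norm <= 1.0:
            raise ConfigurationError(f"agg_norm {self.agg_norm} outside [0, 1]")
        if not -1.0 <= self.ncpr <= 1.0:
            raise ConfigurationError(f"ncpr {self.ncpr} outside [-1, 1]")
        if not 0.0 <= self.cys_pct <= 100.0:
            raise ConfigurationError(f"cys_pct {self.cys_pct} outside [0, 100]")

    def as_array(self) -> np.ndarray:
        """Network input order: (agg_norm, ncpr, cys_pct)."""
        return np.array([self.agg_norm, self.ncpr, self.cys_pct], dtype=float)


@dataclass(frozen=True)
class FeatureConfig:
    """Everything needed to featurize a sequence deterministically."""

    scale: PropensityScale
    pka_table: PKaTable
    ph: float = DEFAULT_PH
    window_bands: tuple[tuple[int, int], ...] = DEFAULT_WINDOW_BANDS
    bounds: NormalizationBounds | None = None

    def with_bounds(self, bounds: NormalizationBounds) -> "FeatureConfig":
        return replace(self, bounds=bounds)


# ---------------------------------------------------------------------------
# config-file loading

def parse_scale_file(text: str, name: str = "custom") -> PropensityScale:
    """Parse a one-residue-per-line ``<residue> <value>`` scale file."""
    values: dict[str, float] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ConfigurationError(f"bad scale line: {raw!r}")
        values[parts[0].upper()] = float(parts[1])
    return PropensityScale(name=name, values=values)


def parse_pka_file(text: str, include_termini: bool = False) -> PKaTable:
    """Parse a ``<group> <pKa> <polarity>`` pKa file (NTERM/CTERM rows allowed)."""
    entries: dict[str, PKaEntry] = {}
    nterm, cterm = 8.0, 3.1
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ConfigurationError(f"bad pKa line: {raw!r}")
        key, pka, polarity = parts[0].upper(), float(parts[1]), parts[2].lower()
        if key == "NTERM":
            nterm = pka
        elif key == "CTERM":
            cterm = pka
        else:
            entries[key] = PKaEntry(pka=pka, polarity=polarity)
    return PKaTable(
        entries=entries,
        include_termini=include_termini,
        nterm_pka=nterm,
        cterm_pka=cterm,
    )


def default_scale() -> PropensityScale:
    """The packaged per-residue aggregation-propensity scale."""
    from importlib.resources import files

    text = files("sgnn.data").joinpath("a3v_scale.txt").read_text()
    return parse_scale_file(text, name="a3v-v1")


def default_pka_table(include_termini: bool = False) -> PKaTable:
    """The packaged conventional-biochemistry pKa table."""
    from importlib.resources import files

    text = files("sgnn.data").joinpath("pka_table.txt").read_text()
    return parse_pka_file(text, include_termini=include_termini)


def default_feature_config() -> FeatureConfig:
    return FeatureConfig(scale=default_scale(), pka_table=default_pka_table())


# ---------------------------------------------------------------------------
# aggregation propensity

def window_for_length(length: int, bands: Sequence[tuple[int, int]] = DEFAULT_WINDOW_BANDS) -> int:
    """Pick the sliding-window size for a sequence of the given length."""
    for max_len, window in bands:
        if length <= max_len:
            return window
    return bands[-1][1]


def sliding_window_profile(
    seq: str, scale: PropensityScale, window: int
) -> np.ndarray:
    """Window-averaged propensity (a4v) at every position.

    The window is centered on each residue and truncated (shrunk one-sided)
    at the sequence ends, so the profile always has one value per residue.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be an odd positive integer, got {window}")
    n = len(seq)
    if n < window:
        raise SequenceLengthError(
            f"sequence of length {n} is shorter than window {window}"
        )
    try:
        a3v = np.array([scale.values[ch] for ch in seq], dtype=float)
    except KeyError as exc:
        raise InvalidResidueError(f"residue {exc.args[0]!r} not in scale") from exc
    half = window // 2
    # cumulative-sum trick: mean over [max(0, i-half), min(n, i+half+1))
    csum = np.concatenate(([0.0], np.cumsum(a3v)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def compute_na4vss(seq: str, scale: PropensityScale, window: int) -> float:
    """Length-normalized aggregation summary: ``mean(a4v) * 100``."""
    profile = sliding_window_profile(seq, scale, window)
    return float(profile.mean() * 100.0)


def normalize_na4vss(raw: float, bounds: NormalizationBounds) -> float:
    """Min-max normalize a raw Na4vSS to [0, 1], clamping out-of-range values."""
    span = bounds.na4vss_max - bounds.na4vss_min
    return float(np.clip((raw - bounds.na4vss_min) / span, 0.0, 1.0))


# ---------------------------------------------------------------------------
# net charge per residue

def residue_charge(residue: str, ph: float, table: PKaTable) -> float:
    """Henderson–Hasselbalch fractional charge of one residue at a given pH.

    Basic groups contribute ``+1/(1+10^(pH-pKa))``, acidic groups
    ``-1/(1+10^(pKa-pH))``; non-ionizable residues contribute zero.
    """
    if residue not in CANONICAL_RESIDUES:
        raise InvalidResidueError(f"invalid residue {residue!r}")
    entry = table.entries.get(residue)
    if entry is None:
        return 0.0
    if entry.polarity == BASIC:
        return 1.0 / (1.0 + 10.0 ** (ph - entry.pka))
    return -1.0 / (1.0 + 10.0 ** (entry.pka - ph))


def compute_ncpr(seq: str, ph: float, table: PKaTable) -> float:
    """Net charge per residue: summed fractional charges / length.

    Terminal charges are added only when the table's ``include_termini``
    flag is set.
    """
    total = sum(residue_charge(ch, ph, table) for ch in seq)
    if table.include_termini:
        total += 1.0 / (1.0 + 10.0 ** (ph - table.nterm_pka))
        total += -1.0 / (1.0 + 10.0 ** (table.cterm_pka - ph))
    return total / len(seq)


# ---------------------------------------------------------------------------
# cysteine content

def compute_cys_percentage(seq: str) -> float:
    """Percentage of cysteine residues: ``100 * count(C) / length``."""
    return 100.0 * seq.count("C") / len(seq)


# ---------------------------------------------------------------------------
# combined featurization

def featurize(record: SequenceRecord, config: FeatureConfig) -> FeatureVector:
    """Compute the full feature vector for one record (pure function).

    ``config.bounds`` must be set (normally taken from the training data or
    a trained model bundle) so that the normalized aggregation score is
    defined.
    """
    if config.bounds is None:
        raise ConfigurationError(
            "feature config has no normalization bounds; fit them from "
            "training data or load them from a model bundle"
        )
    window = window_for_length(len(record.residues), config.window_bands)
    raw = compute_na4vss(record.residues, config.scale, window)
    return FeatureVector(
        agg_raw=raw,
        agg_norm=normalize_na4vss(raw, config.bounds),
        ncpr=compute_ncpr(record.residues, config.ph, config.pka_table),
        cys_pct=compute_cys_percentage(record.residues),
    )


def raw_na4vss_for_records(
    records: Sequence[SequenceRecord], config: FeatureConfig
) -> np.ndarray:
    """Raw Na4vSS per record, using the length-dependent window rule."""
    return np.array(
        [
            compute_na4vss(
                rec.residues,
                config.scale,
                window_for_length(len(rec.residues), config.window_bands),
            )
            for rec in records
        ]
    )


def bounds_from_records(
    records: Sequence[SequenceRecord], config: FeatureConfig
) -> NormalizationBounds:
    """Derive normalization anchors from a reference set of PrLDs.

    The least and most aggregation-prone sequences in the set define the
    [0, 1] range of the normalized aggregation feature.
    """
    raw = raw_na4vss_for_records(records, config)
    lo, hi = float(raw.min()), float(raw.max())
    if lo == hi:
        raise ConfigurationError(
            "all reference sequences share one Na4vSS value; cannot normalize"
        )
    return NormalizationBounds(na4vss_min=lo, na4vss_max=hi)
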