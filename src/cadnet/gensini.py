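"""Angiographic ground truth: binary CAD labels and the modified Gensini target.

The classical Gensini index scores each coronary lesion as the product of a
stenosis-band severity score and a vessel-segment location multiplier.  The
training target used here is a *worst-case-lesion* variant: only the lesion
with the maximal severity x location product contributes, a dampening factor
of 0.25 is applied when collaterals are present, and the result is passed
through ``ln(offset + raw)`` so a linear model can regress it.

The binary CAD label is independent of the Gensini score: a subject is
positive when any lesion has stenosis >= 70% (visual rule) or a measured
fractional flow reserve (FFR) <= 0.80.  Where FFR was measured it is the
final determinant and overrides the visual stenosis rule for that lesion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "Lesion",
    "AngiogramRecord",
    "GensiniConfig",
    "GensiniResult",
    "severity_score",
    "location_multiplier",
    "modified_gensini",
    "cad_label",
    "SEGMENTS",
]

#: Supported vessel-segment codes (left main, proximal/mid/distal LAD,
#: proximal circumflex, obtuse marginal, right coronary, posterior
#: descending, and a catch-all for small branches).
SEGMENTS = ("LM", "pLAD", "mLAD", "dLAD", "pLCx", "OM", "RCA", "PDA", "OTHER")

# Severity bands: lower edge of each stenosis band -> integer score.
# Band edges are lower-closed: a stenosis exactly at an edge takes the
# upper band's score (75 -> 4).  Exactly 100 means total occlusion.
_SEVERITY_BANDS: tuple[tuple[float, int], ...] = (
    (0.0, 0),
    (25.0, 1),
    (50.0, 2),
    (75.0, 4),
    (90.0, 8),
    (99.0, 16),
    (100.0, 32),
)

_LOCATION_MULTIPLIERS: dict[str, float] = {
    "LM": 5.0,
    "pLAD": 2.5,
    "pLCx": 2.5,
    "mLAD": 1.5,
    "dLAD": 1.0,
    "RCA": 1.0,
    "OM": 1.0,
    "PDA": 1.0,
    "OTHER": 0.5,
}


@dataclass(frozen=True)
class Lesion:
    """A single coronary lesion.

    Parameters
    ----------
    stenosis : float
        Percent diameter reduction, in [0, 100].
    segment : str
        Vessel-segment code, one of :data:`SEGMENTS`.
    ffr : float or None
        Fractional flow reserve in (0, 1]; present iff ``ffr_measured``.
    ffr_measured : bool
        Whether a pressure-wire FFR assessment was performed.
    """

    stenosis: float
    segment: str
    ffr: float | None = None
    ffr_measured: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.stenosis <= 100.0:
            raise ValueError(f"stenosis must be in [0, 100], got {self.stenosis}")
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment code {self.segment!r}")
        if self.ffr_measured != (self.ffr is not None):
            raise ValueError("ffr must be present iff ffr_measured is set")
        if self.ffr is not None and not 0.0 < self.ffr <= 1.0:
            raise ValueError(f"ffr must be in (0, 1], got {self.ffr}")


@dataclass(frozen=True)
class AngiogramRecord:
    """Catheterization findings for one subject.

    An empty lesion list is a valid record (a clean angiogram).
    """

    lesions: tuple[Lesion, ...] = ()
    collaterals_present: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesions", tuple(self.lesions))


@dataclass(frozen=True)
class GensiniConfig:
    """Scoring tables and transform parameters.

    ``dampening_factor`` multiplies the raw worst-case product when
    collaterals are present.  ``log_offset`` shifts the log so that a
    lesion-free subject maps exactly to 0.  Both tables can be overridden
    (e.g. loaded from JSON) to express alternative Gensini dialects.
    """

    dampening_factor: float = 0.25
    log_offset: float = 1.0
    severity_table: tuple[tuple[float, int], ...] = _SEVERITY_BANDS
    location_table: Mapping[str, float] = field(
        default_factory=lambda: dict(_LOCATION_MULTIPLIERS)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.dampening_factor <= 1.0:
            raise ValueError("dampening_factor must be in (0, 1]")
        if self.log_offset < 0:
            raise ValueError("log_offset must be nonnegative")
        scores = [s for _, s in self.severity_table]
        if any(b >= a for a, b in zip(scores[1:], scores)):
            raise ValueError("severity scores must be strictly increasing")
        if any(m <= 0 for m in self.location_table.values()):
            raise ValueError("location multipliers must be positive")

    @classmethod
    def from_json(cls, path: str) -> "GensiniConfig":
        with open(path) as fh:
            raw = json.load(fh)
        kwargs: dict = {}
        if "dampening_factor" in raw:
            kwargs["dampening_factor"] = raw["dampening_factor"]
        if "log_offset" in raw:
            kwargs["log_offset"] = raw["log_offset"]
        if "severity_table" in raw:
            kwargs["severity_table"] = tuple(
                (float(edge), int(score)) for edge, score in raw["severity_table"]
            )
        if "location_table" in raw:
            kwargs["location_table"] = {k: float(v) for k, v in raw["location_table"].items()}
        return cls(**kwargs)


@dataclass(frozen=True)
class GensiniResult:
    raw_worst_case: float
    modified_score: float
    cad_positive: bool


_DEFAULT_CONFIG = GensiniConfig()


def severity_score(stenosis: float, config: GensiniConfig = _DEFAULT_CONFIG) -> int:
    """Banded severity score for a percent-diameter stenosis.

    Default bands: [0,25)->0, [25,50)->1, [50,75)->2, [75,90)->4,
    [90,99)->8, [99,100)->16 and exactly 100 (occlusion) ->32.
    """
    if not 0.0 <= stenosis <= 100.0:
        raise ValueError(f"stenosis must be in [0, 100], got {stenosis}")
    score = config.severity_table[0][1]
    for edge, band_score in config.severity_table:
        if stenosis >= edge:
            score = band_score
        else:
            break
    return score


def location_multiplier(segment: str, config: GensiniConfig = _DEFAULT_CONFIG) -> float:
    """Vessel-segment multiplier (LM 5, proximal LAD/LCx 2.5, mid LAD 1.5, ...)."""
    try:
        return config.location_table[segment]
    except KeyError:
        raise ValueError(f"unknown segment code {segment!r}") from None


def modified_gensini(
    angiogram: AngiogramRecord, config: GensiniConfig = _DEFAULT_CONFIG
) -> GensiniResult:
    """Worst-case-lesion modified Gensini score.

    raw = max over lesions of severity x location (0 for a clean angiogram),
    multiplied by ``dampening_factor`` when collaterals are present;
    modified_score = ln(log_offset + raw).
    """
    raw = 0.0
    for lesion in angiogram.lesions:
        product = severity_score(lesion.stenosis, config) * location_multiplier(
            lesion.segment, config
        )
        raw = max(raw, product)
    if angiogram.collaterals_present:
        raw *= config.dampening_factor
    return GensiniResult(
        raw_worst_case=raw,
        modified_score=math.log(config.log_offset + raw),
        cad_positive=cad_label(angiogram),
    )


def _lesion_positive(lesion: Lesion) -> bool:
    # FFR is the final determinant wherever a flow wire was used.
    if lesion.ffr_measured:
        return lesion.ffr <= 0.80
    return lesion.stenosis >= 70.0


def cad_label(angiogram: AngiogramRecord) -> bool:
    """Binary CAD label: any lesion with stenosis >= 70% (no FFR) or FFR <= 0.80."""
    return any(_lesion_positive(lesion) for lesion in angiogram.lesions)
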