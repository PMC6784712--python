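"""Shared domain vocabulary: study settings, categories, severities, and
possibly-censored AHI values.

AHI (apnea-hypopnea index) estimates below the clinical normal/abnormal
boundary of 5 events/h are reported as the censored token ``"<5"`` rather
than a number, mirroring how screening reports print them.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass


class Setting(enum.Enum):
    """Where and how a study night was recorded."""

    CLINIC_PSG = "clinic_psg"      # attended polysomnography night
    HOME_HSAT = "home_hsat"        # home night wearing HSAT sensors
    HOME_LC_ONLY = "home_lc_only"  # home night with load cells only

    @classmethod
    def parse(cls, text: str) -> "Setting":
        return cls(text.strip().lower())


class Category(enum.Enum):
    """Binary screening outcome of a sleep test."""

    NORMAL = "normal"
    ABNORMAL = "abnormal"


class Severity(enum.Enum):
    """Three-class OSA severity; moderate and severe are managed alike
    clinically (CPAP) and are collapsed into one predicted class."""

    NORMAL = "normal"
    MILD = "mild"
    MODERATE_SEVERE = "moderate_severe"


#: Rank order used for monotonicity checks (normal < mild < moderate/severe).
SEVERITY_RANK = {Severity.NORMAL: 0, Severity.MILD: 1, Severity.MODERATE_SEVERE: 2}

#: Token printed for censored below-threshold AHI estimates.
CENSORED_TOKEN = "<5"


@dataclass(frozen=True)
class CensoredAHI:
    """An AHI in events/h that is either numeric or censored below 5.

    ``value is None`` encodes the censored token ``"<5"``.
    """

    value: float | None

    def __post_init__(self) -> None:
        if self.value is not None:
            v = float(self.value)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"AHI must be finite and >= 0, got {self.value!r}")
            object.__setattr__(self, "value", v)

    @classmethod
    def censored(cls) -> "CensoredAHI":
        return cls(None)

    @classmethod
    def of(cls, value: float) -> "CensoredAHI":
        return cls(float(value))

    @classmethod
    def parse(cls, text: str) -> "CensoredAHI":
        text = text.strip()
        if text == CENSORED_TOKEN:
            return cls.censored()
        return cls(float(text))

    @property
    def is_censored(self) -> bool:
        return self.value is None

    def numeric(self, censored_as: float = 2.5) -> float:
        """Numeric view; censored values map to ``censored_as`` (midpoint of
        the normal range by default)."""
        return censored_as if self.value is None else self.value

    def __str__(self) -> str:
        return CENSORED_TOKEN if self.value is None else f"{self.value:.2f}"
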