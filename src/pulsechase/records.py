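"""Domain record types shared across the pipeline.

A :class:`PeptideQuantRecord` is one peptide observation in one LC-MS/MS run
of the pulse-chase experiment: its heavy (pre-chase-synthesized, isotope
labeled) and light (post-chase-synthesized) MS1 chromatographic peak areas,
the chase time in days (day 30 in vitro, the end of the pulse, is time 0),
the genotype of the culture and the experiment replicate.

A :class:`SpectralCountRecord` is one protein's spectral count in one
immunoprecipitation run, either with the bait antibody (VCP) or the
nonspecific IgG control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .errors import ValidationError


class Genotype(str, Enum):
    MUT = "MUT"
    CTRL = "CTRL"


class Bait(str, Enum):
    VCP = "VCP"
    IGG = "IGG"


def _as_enum(value, enum_cls):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(str(value).upper())
    except ValueError:
        raise ValidationError(
            f"unknown {enum_cls.__name__} label {value!r}; "
            f"expected one of {[m.value for m in enum_cls]}"
        ) from None


@dataclass(frozen=True)
class PeptideQuantRecord:
    """One peptide x run quantification.

    Invariants: areas are finite and nonnegative, not both zero;
    chase_time >= 0; replicate >= 1.
    """

    peptide: str
    protein: str
    heavy_area: float
    light_area: float
    chase_time: float
    genotype: Genotype
    replicate: int = 1

    def __post_init__(self):
        object.__setattr__(self, "genotype", _as_enum(self.genotype, Genotype))
        for name in ("heavy_area", "light_area", "chase_time"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v!r}")
        if self.heavy_area == 0 and self.light_area == 0:
            raise ValidationError(
                f"heavy_area and light_area are both zero for peptide "
                f"{self.peptide!r} (unquantified observation)"
            )
        if not self.peptide:
            raise ValidationError("peptide sequence must be non-empty")
        if not self.protein:
            raise ValidationError("protein accession must be non-empty")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")


@dataclass(frozen=True)
class SpectralCountRecord:
    """One protein x IP-run spectral count."""

    protein: str
    bait: Bait
    genotype: Genotype
    replicate: int
    spec_count: int

    def __post_init__(self):
        object.__setattr__(self, "bait", _as_enum(self.bait, Bait))
        object.__setattr__(self, "genotype", _as_enum(self.genotype, Genotype))
        if not self.protein:
            raise ValidationError("protein accession must be non-empty")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if self.spec_count < 0:
            raise ValidationError(f"spec_count must be >= 0, got {self.spec_count}")
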