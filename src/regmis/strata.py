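"""The sex x age-band cross-classification used throughout the package.

Incidence is modelled on eight covariate patterns: two sexes crossed with
four age bands (0-14, 15-49, 50-69, 70+ years). The ordering is fixed —
sex-major (female first), ascending age within sex — and every per-stratum
vector in the package is indexed in this order.
"""

from __future__ import annotations

from dataclasses import dataclass

AGE_BANDS: tuple[str, ...] = ("0-14", "15-49", "50-69", "70+")
SEXES: tuple[str, ...] = ("female", "male")


@dataclass(frozen=True, order=True)
class Stratum:
    """One cell of the sex x age-band cross-classification."""

    sex: str
    age_band: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(
                f"unknown age band {self.age_band!r}; expected one of {AGE_BANDS}"
            )

    @property
    def label(self) -> str:
        return f"{self.sex}:{self.age_band}"


#: canonical ordering: female 0-14 .. female 70+, male 0-14 .. male 70+
STRATA: tuple[Stratum, ...] = tuple(
    Stratum(sex, band) for sex in SEXES for band in AGE_BANDS
)

N_STRATA = len(STRATA)

STRATUM_INDEX: dict[Stratum, int] = {s: i for i, s in enumerate(STRATA)}


def age_index(stratum: Stratum) -> int:
    """Position of the stratum's age band within AGE_BANDS."""
    return AGE_BANDS.index(stratum.age_band)
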