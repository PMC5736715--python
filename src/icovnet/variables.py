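"""Registry of the 18 clinical and neurocognitive measures.

Each participant contributes one score per measure: self-reported symptom
totals (BDI, BAI), nine MMPI-2 clinical-scale T-scores, and seven
neurocognitive performance indices (continuous performance test errors,
trail-making reaction times, WCST perseverative errors, digit spans).

The sign convention used throughout the pipeline lives here: a measure's
``better_direction`` is +1 when a higher raw score indicates a better
condition (only the two digit-span measures) and -1 otherwise, so that
after flipping, positive z-scores always mean "better".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["VariableSpec", "default_registry", "registry_names"]

CLINICAL = "clinical"
NEUROCOGNITIVE = "neurocognitive"


@dataclass(frozen=True)
class VariableSpec:
    """One measure: identity, display label, domain and sign convention.

    Parameters
    ----------
    name:
        Short machine identifier, used as the cohort-table column name.
    label:
        Human-readable display name.
    domain:
        ``"clinical"`` or ``"neurocognitive"``.
    better_direction:
        +1 if a higher raw score is the better condition, -1 otherwise.
        Z-scores are multiplied by this factor before network construction.
    is_symptom_outcome:
        True for the symptom-severity outcomes (BDI, BAI) that centralities
        are correlated against.
    """

    name: str
    label: str
    domain: str
    better_direction: int = -1
    is_symptom_outcome: bool = False

    def __post_init__(self) -> None:
        if self.domain not in (CLINICAL, NEUROCOGNITIVE):
            raise ValueError(f"unknown domain {self.domain!r} for {self.name!r}")
        if self.better_direction not in (-1, 1):
            raise ValueError(f"better_direction must be +1/-1 for {self.name!r}")


def default_registry() -> list[VariableSpec]:
    """The 18 measures in canonical column order.

    Clinical block first (BDI, BAI, nine MMPI-2 scales), then the seven
    neurocognitive measures. Only digit span forward/backward carry
    ``better_direction=+1``; for every other measure a higher score is worse.
    """
    c, n = CLINICAL, NEUROCOGNITIVE
    return [
        VariableSpec("BDI", "Beck Depression Inventory total", c, -1, True),
        VariableSpec("BAI", "Beck Anxiety Inventory total", c, -1, True),
        VariableSpec("MMPI_1_Hs", "MMPI-2 scale 1 (Hypochondriasis) T", c),
        VariableSpec("MMPI_2_D", "MMPI-2 scale 2 (Depression) T", c),
        VariableSpec("MMPI_3_Hy", "MMPI-2 scale 3 (Hysteria) T", c),
        VariableSpec("MMPI_4_Pd", "MMPI-2 scale 4 (Psychopathic deviate) T", c),
        VariableSpec("MMPI_6_Pa", "MMPI-2 scale 6 (Paranoia) T", c),
        VariableSpec("MMPI_7_Pt", "MMPI-2 scale 7 (Psychasthenia) T", c),
        VariableSpec("MMPI_8_Sc", "MMPI-2 scale 8 (Schizophrenia) T", c),
        VariableSpec("MMPI_9_Ma", "MMPI-2 scale 9 (Hypomania) T", c),
        VariableSpec("MMPI_0_Si", "MMPI-2 scale 0 (Social introversion) T", c),
        VariableSpec("CPT_omission", "CPT omission errors", n),
        VariableSpec("CPT_commission", "CPT commission errors", n),
        VariableSpec("TMT_A", "Trail Making Test A reaction time (s)", n),
        VariableSpec("TMT_B", "Trail Making Test B reaction time (s)", n),
        VariableSpec("WCST_PE", "WCST perseverative errors", n),
        VariableSpec("DS_forward", "Digit span forward", n, +1),
        VariableSpec("DS_backward", "Digit span backward", n, +1),
    ]


def registry_names(registry: Iterable[VariableSpec]) -> list[str]:
    return [spec.name for spec in registry]


def validate_registry(registry: list[VariableSpec]) -> None:
    """Reject registries with duplicate names."""
    names = registry_names(registry)
    if len(set(names)) != len(names):
        raise ValueError("registry contains duplicate variable names")
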