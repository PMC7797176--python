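"""Feature schema for the 23-variable TADPOLE-style marker set.

The variable set mirrors the marker panel recommended by the TADPOLE
challenge for ADNI: one categorical clinical diagnosis (NC / MCI / AD) plus
22 continuous markers spanning cognition, T1 MRI volumetry, PET uptake and
CSF biochemistry.  Each continuous variable carries its population mean,
standard deviation, the fraction of visits at which it is typically
measured, and the clinical direction of change with worsening disease
(+1 increases, -1 decreases, 0 roughly stable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Variable",
    "FeatureSchema",
    "DEFAULT_SCHEMA",
    "DX",
    "DX_LABELS",
    "SchemaError",
]


class SchemaError(ValueError):
    """Raised when a table does not match the expected variable schema."""


DX = "DX"
DX_LABELS = ("NC", "MCI", "AD")


@dataclass(frozen=True)
class Variable:
    """One continuous marker: name, marginal moments, availability, direction."""

    name: str
    mean: float
    sd: float
    observed_frac: float
    direction: int  # +1 worsens upward, -1 worsens downward, 0 disease-neutral


# Cognitive scores, MRI volumes (mm^3), PET SUVR, CSF (pg/ml); availability
# is the fraction of subject-visits at which the marker is measured in ADNI.
_CONTINUOUS = (
    Variable("CDRSB", 2.17, 2.81, 0.7036, +1),
    Variable("ADAS11", 11.3, 8.6, 0.6995, +1),
    Variable("ADAS13", 17.5, 11.6, 0.6927, +1),
    Variable("MMSE", 26.5, 3.9, 0.7012, -1),
    Variable("RAVLT_immediate", 34.4, 13.6, 0.6933, -1),
    Variable("RAVLT_learning", 4.02, 2.81, 0.6933, -1),
    Variable("RAVLT_forgetting", 4.23, 2.52, 0.6912, +1),
    Variable("RAVLT_perc_forgetting", 59.7, 38.3, 0.6857, +1),
    Variable("FAQ", 5.59, 7.92, 0.7060, +1),
    Variable("MOCA", 23.0, 4.7, 0.3899, -1),
    Variable("Ventricles", 4.21e4, 2.32e4, 0.5844, +1),
    Variable("Hippocampus", 6.68e3, 1.24e3, 0.5339, -1),
    Variable("WholeBrain", 1.01e6, 0.11e6, 0.6035, -1),
    Variable("Entorhinal", 3.44e3, 0.81e3, 0.5078, -1),
    Variable("Fusiform", 1.71e4, 0.28e4, 0.5078, -1),
    Variable("MidTemp", 1.92e4, 0.31e4, 0.5078, -1),
    Variable("ICV", 1.53e6, 0.16e6, 0.6243, 0),
    Variable("AV45", 1.19, 0.22, 0.1662, +1),
    Variable("FDG", 1.20, 0.16, 0.2631, -1),
    Variable("ABETA", 1.02e3, 0.59e3, 0.1860, -1),
    Variable("TAU", 2.93e2, 1.30e2, 0.1855, +1),
    Variable("PTAU", 48.0, 14.4, 0.1862, +1),
)

_DX_OBSERVED_FRAC = 0.6989


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered variable schema: one categorical diagnosis + 22 continuous markers.

    The in-memory value layout for a visit is a 25-vector:
    columns 0-2 are the one-hot diagnosis (NC, MCI, AD) and columns 3-24 the
    continuous markers in schema order.  The observation mask has 23 entries
    (diagnosis counted once, then one per marker).
    """

    continuous: tuple[Variable, ...] = _CONTINUOUS
    dx_observed_frac: float = _DX_OBSERVED_FRAC

    def __post_init__(self) -> None:
        if len({v.name for v in self.continuous}) != len(self.continuous):
            raise SchemaError("duplicate continuous variable names")
        if DX in {v.name for v in self.continuous}:
            raise SchemaError(f"{DX!r} is reserved for the categorical diagnosis")

    # --- sizes -----------------------------------------------------------
    @property
    def n_continuous(self) -> int:
        return len(self.continuous)

    @property
    def n_features(self) -> int:
        """Number of masked features: diagnosis + continuous markers."""
        return 1 + self.n_continuous

    @property
    def n_values(self) -> int:
        """Width of the value vector: 3 one-hot diagnosis + continuous."""
        return 3 + self.n_continuous

    # --- names and lookups ------------------------------------------------
    @property
    def continuous_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.continuous)

    @property
    def names(self) -> tuple[str, ...]:
        """All 23 variable names, diagnosis first."""
        return (DX,) + self.continuous_names

    @property
    def means(self) -> np.ndarray:
        return np.array([v.mean for v in self.continuous])

    @property
    def sds(self) -> np.ndarray:
        return np.array([v.sd for v in self.continuous])

    @property
    def observed_fracs(self) -> np.ndarray:
        """Per-feature observed fraction, diagnosis first (length 23)."""
        return np.array(
            [self.dx_observed_frac] + [v.observed_frac for v in self.continuous]
        )

    @property
    def directions(self) -> np.ndarray:
        return np.array([v.direction for v in self.continuous])

    def continuous_index(self, name: str) -> int:
        """Index of a marker among the continuous variables (0-based)."""
        try:
            return self.continuous_names.index(name)
        except ValueError:
            raise SchemaError(f"unknown continuous variable {name!r}") from None

    def value_column(self, name: str) -> int:
        """Column of a marker in the 25-wide value matrix."""
        return 3 + self.continuous_index(name)

    def feature_index(self, name: str) -> int:
        """Index in the 23-wide mask (0 = diagnosis)."""
        if name == DX:
            return 0
        return 1 + self.continuous_index(name)


DEFAULT_SCHEMA = FeatureSchema()
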