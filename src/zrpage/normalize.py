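"""Per-array Z-score normalization of raw hybridization intensities.

Each array (sample/column) is log-transformed and standardized on its own:

    Z_gj = (log(x_gj) - mean_g log(x_gj)) / sd_g log(x_gj)

with the sample standard deviation (denominator n-1). The resulting Z
scores are dimensionless and base-invariant: changing the logarithm base
rescales the numerator and denominator identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError

#: Standard-deviation denominator convention used everywhere in the package.
SD_DDOF = 1


@dataclass(frozen=True)
class SampleDesign:
    """Assignment of samples (arrays) to experimental groups.

    Parameters
    ----------
    assignments
        Ordered mapping ``sample_id -> group label``.
    groups
        Ordered group labels. Defaults to the distinct groups in
        ``assignments``, in order of first appearance.
    """

    assignments: dict[str, str]
    groups: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValidationError("assignments: design is empty")
        seen = tuple(dict.fromkeys(self.assignments.values()))
        if not self.groups:
            object.__setattr__(self, "groups", seen)
        else:
            object.__setattr__(self, "groups", tuple(self.groups))
            missing = set(seen) - set(self.groups)
            if missing:
                raise ValidationError(
                    f"groups: samples assigned to unlisted groups {sorted(missing)}"
                )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.assignments)

    def samples_in(self, group: str) -> list[str]:
        """Sample ids belonging to ``group``, in design order."""
        if group not in self.groups:
            raise ValidationError(f"group: unknown group label {group!r}")
        return [s for s, g in self.assignments.items() if g == group]

    def require_replicates(self, minimum: int = 2) -> None:
        """Raise unless every group has at least ``minimum`` samples."""
        for g in self.groups:
            n = len(self.samples_in(g))
            if n < minimum:
                raise ValidationError(
                    f"group {g!r} has {n} replicate(s); at least {minimum} required"
                )


def _validate_raw(raw: pd.DataFrame) -> None:
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dups[:5]}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:5]}")
    if raw.shape[0] < 2:
        raise ValidationError("at least 2 genes per array are required")
    values = raw.to_numpy(dtype=float)
    if np.isnan(values).any():
        g, s = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"missing value at gene {raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    if (values <= 0).any():
        g, s = np.argwhere(values <= 0)[0]
        raise ValidationError(
            f"nonpositive intensity {values[g, s]!r} at gene "
            f"{raw.index[g]!r}, sample {raw.columns[s]!r}"
        )


def zscore_normalize(raw: pd.DataFrame, log_base: float = 10.0) -> pd.DataFrame:
    """Standardize log intensities within each array.

    Parameters
    ----------
    raw
        Gene x sample matrix of strictly positive intensities.
    log_base
        Base of the log transform (cosmetic: Z scores are base-invariant).

    Returns
    -------
    pandas.DataFrame
        Z-score matrix on the same axes; per column, mean 0 and sample
        SD 1 to numerical precision.

    Raises
    ------
    ValidationError
        Nonpositive or missing intensities, duplicate ids, <2 genes.
    DegenerateInputError
        An array whose log intensities are constant (SD = 0).
    """
    if not np.isfinite(log_base) or log_base <= 0 or log_base == 1:
        raise ValidationError(f"log_base must be positive and != 1, got {log_base}")
    _validate_raw(raw)
    logx = np.log(raw.to_numpy(dtype=float)) / np.log(log_base)
    sd = logx.std(axis=0, ddof=SD_DDOF)
    if (sd == 0).any():
        j = int(np.argwhere(sd == 0)[0][0])
        raise DegenerateInputError(
            f"array {raw.columns[j]!r} has constant log intensities (SD = 0)"
        )
    z = (logx - logx.mean(axis=0)) / sd
    return pd.DataFrame(z, index=raw.index, columns=raw.columns)
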