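"""iTRAQ 4-plex reporter-ion normalization: log2 ratios → population Z-scores.

Channel layout (two-condition, two-replicate design):

* tag 114 — exponential phase, replicate A
* tag 115 — exponential phase, replicate B
* tag 116 — stationary phase, replicate A
* tag 117 — stationary phase, replicate B

Four log2 ratios are formed per PSM: the two *differential* ratios
r0 = log2(116/114), r1 = log2(117/115) compare stationary to exponential
within replicate, and the two *replicate* ratios r2 = log2(115/114),
r3 = log2(117/116) measure biological-replicate stability within a growth
phase.  Each ratio channel is standardized against the run-wide peptide
population (global normalization): z = (r − mean) / width, where width is
the population standard deviation of that channel's peptide log2 ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UnquantifiablePSMError
from .psm_io import PSM

#: ratio channels as (numerator tag, denominator tag)
RATIO_CHANNELS: dict[str, tuple[str, str]] = {
    "r0": ("116", "114"),
    "r1": ("117", "115"),
    "r2": ("115", "114"),
    "r3": ("117", "116"),
}

RATIO_NAMES = tuple(RATIO_CHANNELS)
Z_NAMES = ("z0", "z1", "z2", "z3")


def compute_log2_ratios(psm: PSM) -> dict[str, float]:
    """The four per-PSM log2 reporter ratios.

    Raises :class:`UnquantifiablePSMError` when any channel is missing or
    non-positive; such PSMs are excluded from ratio space (but still count
    toward spectral counting).
    """
    intensities = psm.reporter_intensities
    if intensities is None:
        raise UnquantifiablePSMError(f"{psm.spectrum_id}: no reporter intensities")
    for channel, value in intensities.items():
        if value <= 0:
            raise UnquantifiablePSMError(
                f"{psm.spectrum_id}: non-positive intensity {value} in channel {channel}"
            )
    return {
        name: float(np.log2(intensities[num] / intensities[den]))
        for name, (num, den) in RATIO_CHANNELS.items()
    }


def ratio_table(psms: Sequence[PSM]) -> tuple[pd.DataFrame, int]:
    """Per-PSM log2-ratio table over the quantifiable subset.

    Returns the table (spectrum_id, peptide, protein_ids, r0..r3) and the
    number of PSMs dropped as unquantifiable.
    """
    rows = []
    n_unquantifiable = 0
    for psm in psms:
        try:
            ratios = compute_log2_ratios(psm)
        except UnquantifiablePSMError:
            n_unquantifiable += 1
            continue
        rows.append(
            {
                "spectrum_id": psm.spectrum_id,
                "peptide": psm.peptide,
                "protein_ids": psm.protein_ids,
                **ratios,
            }
        )
    columns = ["spectrum_id", "peptide", "protein_ids", *RATIO_NAMES]
    return pd.DataFrame(rows, columns=columns), n_unquantifiable


@dataclass(frozen=True)
class RatioDistribution:
    """Location and width of one ratio channel's peptide population."""

    channel: str
    mean: float
    width: float
    n: int

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"{self.channel}: width must be > 0, got {self.width}")


def fit_distribution(values: Iterable[float], channel: str = "", robust: bool = False) -> RatioDistribution:
    """Fit the peptide population distribution of one ratio channel.

    Default: arithmetic mean and population standard deviation (denominator
    n).  ``robust=True`` uses median and scaled MAD instead, for
    outlier-heavy runs.  Requires at least two values with nonzero spread.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError(f"channel {channel or '?'}: need >= 2 finite values, got {arr.size}")
    if robust:
        center = float(np.median(arr))
        width = float(np.median(np.abs(arr - center)) * 1.4826)
    else:
        center = float(arr.mean())
        width = float(arr.std(ddof=0))
    if width == 0:
        raise ValueError(f"channel {channel or '?'}: zero spread, cannot standardize")
    return RatioDistribution(channel=channel, mean=center, width=width, n=int(arr.size))


def standardize(
    ratios: pd.DataFrame, distributions: Mapping[str, RatioDistribution]
) -> pd.DataFrame:
    """Map ratios to Z-scores: distance from the population mean in units of
    the population standard deviation, per channel."""
    out = ratios.copy()
    for r_name, z_name in zip(RATIO_NAMES, Z_NAMES):
        if r_name not in distributions:
            raise ValueError(f"no fitted distribution for channel {r_name}")
        dist = distributions[r_name]
        out[z_name] = (out[r_name] - dist.mean) / dist.width
    return out


def normalize_psms(
    psms: Sequence[PSM], robust: bool = False
) -> tuple[pd.DataFrame, dict[str, RatioDistribution], int]:
    """Full peptide-level normalization: ratios, population fits, Z-scores.

    Returns (z_table, distributions, n_unquantifiable).  The distributions
    are fit on the same quantifiable cohort that is standardized, so each z
    channel has sample mean 0 and population SD 1 by construction.
    """
    ratios, n_unquantifiable = ratio_table(psms)
    if len(ratios) < 2:
        raise ValueError(
            f"need >= 2 quantifiable PSMs to fit population distributions, got {len(ratios)}"
        )
    distributions = {
        name: fit_distribution(ratios[name], channel=name, robust=robust) for name in RATIO_NAMES
    }
    z_table = standardize(ratios, distributions)
    return z_table, distributions, n_unquantifiable
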