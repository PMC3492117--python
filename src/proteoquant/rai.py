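"""Relative Abundance Index (RAI) profiling.

RAI is a coarse label-free abundance proxy: the protein's spectral count
(SpC) divided by its molecular mass Mr in kDa.  Dividing by mass corrects
for the fact that larger proteins yield more tryptic peptides and hence
more spectra at the same molar abundance.  Proteins are ranked within a
cohort by percentile so statements like "top 20% of detected proteins"
translate directly to ``percentile >= 80``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import parser as _pparser
from scipy import stats as _stats

from .psm_io import DetectedProtein, ProteinRecord


def compute_rai(spectral_count: float, molecular_mass_kDa: float) -> float:
    """SpC / Mr.  Mass must be positive; a zero count gives RAI 0."""
    if molecular_mass_kDa <= 0:
        raise ValueError(f"molecular mass must be > 0, got {molecular_mass_kDa}")
    if spectral_count < 0:
        raise ValueError(f"spectral count must be >= 0, got {spectral_count}")
    return spectral_count / molecular_mass_kDa


def build_rai_table(
    detected: Sequence[DetectedProtein], records: Sequence[ProteinRecord]
) -> pd.DataFrame:
    """Per-protein RAI table (protein_id, spectral_count, molecular_mass_kDa,
    rai, percentile) for a cohort of detected proteins."""
    masses = {r.protein_id: r.molecular_mass_kDa for r in records}
    rows = [
        {
            "protein_id": d.protein_id,
            "spectral_count": d.spectral_count,
            "molecular_mass_kDa": masses[d.protein_id],
            "rai": compute_rai(d.spectral_count, masses[d.protein_id]),
        }
        for d in detected
    ]
    frame = pd.DataFrame(rows, columns=["protein_id", "spectral_count", "molecular_mass_kDa", "rai"])
    if len(frame):
        frame = rank_percentiles(frame)
    return frame


def rank_percentiles(entries: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``percentile`` column: 100 × (#entries with rai ≤ this)/n.

    Ties share the maximal percentile, so percentiles lie in (0, 100] and a
    "top X%" claim corresponds to percentile ≥ 100 − X.
    """
    if len(entries) == 0:
        raise ValueError("cannot rank an empty cohort")
    out = entries.copy()
    n = len(out)
    out["percentile"] = out["rai"].rank(method="max") / n * 100.0
    return out


@dataclass(frozen=True)
class CohortComparison:
    """Paired comparison of RAI between two acquisition cohorts."""

    n_shared: int
    spearman_rho: float
    frac_lower_in_b: float
    pairs: pd.DataFrame


def compare_cohorts(entries_a: pd.DataFrame, entries_b: pd.DataFrame) -> CohortComparison:
    """Join two RAI cohorts on protein_id and compare their abundance trends.

    Reports the Spearman rank correlation of RAI over shared proteins and the
    fraction of shared proteins whose RAI is strictly lower in cohort B —
    e.g. a multiplexed (4-plex) acquisition versus a single-plex shotgun run,
    where splitting acquisition time across labels lowers per-protein counts
    while preserving the abundance ordering.
    """
    pairs = entries_a.merge(entries_b, on="protein_id", suffixes=("_a", "_b"))
    if len(pairs) == 0:
        raise ValueError("cohorts share no proteins")
    if len(pairs) == 1:
        rho = float("nan")
    else:
        rho = float(_stats.spearmanr(pairs["rai_a"], pairs["rai_b"]).statistic)
    frac_lower = float((pairs["rai_b"] < pairs["rai_a"]).mean())
    return CohortComparison(
        n_shared=len(pairs),
        spearman_rho=rho,
        frac_lower_in_b=frac_lower,
        pairs=pairs[["protein_id", "rai_a", "rai_b"]],
    )


def nsaf(spectral_counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """Normalized spectral abundance factor: (SpC/L) / Σ(SpC/L).

    Alternative length-based normalization, provided for cross-checks against
    the mass-based RAI; both are monotone in SpC at fixed size.
    """
    counts = np.asarray(spectral_counts, dtype=float)
    lens = np.asarray(lengths, dtype=float)
    if np.any(lens <= 0):
        raise ValueError("protein lengths must be positive")
    saf = counts / lens
    total = saf.sum()
    if total == 0:
        return saf
    return saf / total


def pai(n_observed_peptides: int, sequence: str, min_len: int = 6, max_len: int = 30) -> float:
    """Protein abundance index: observed / theoretically observable peptides.

    Theoretically observable peptides are fully tryptic cleavage products of
    the sequence within the given length window.
    """
    theoretical = [
        pep
        for pep in _pparser.cleave(sequence, _pparser.expasy_rules["trypsin"], missed_cleavages=0)
        if min_len <= len(pep) <= max_len
    ]
    if not theoretical:
        raise ValueError("sequence yields no observable tryptic peptides in the length window")
    return n_observed_peptides / len(theoretical)
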