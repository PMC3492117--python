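"""Category assignment and the core-metabolism summary table.

Builds the per-category report: proteins detected by each acquisition
method (single-plex shotgun vs iTRAQ 4-plex), their union, and
increase/decrease counts among confident change calls, with a totals row
and headline percentages over the 4-plex-detected cohort.

Two small text resources ship with the package: a seed category map for
the *C. thermocellum* locus tags of the core-metabolism pathways
(user-replaceable — real analyses should supply their own genome-wide
map), and a reference per-category count table for cellobiose-grown batch
cultures used by the worked examples.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .errors import DuplicateEntryError

#: the 11 core-metabolism reporting categories, in table order
CORE_CATEGORIES = (
    "Non-catalytic cellulosomal proteins",
    "Cellulosomal glycosidases",
    "Non-cellulosomal glycosidases",
    "RsgI-like sigma factors and anti-sigma-I factors",
    "Cello-oligosaccharide ABC transporters",
    "Glycolysis",
    "Pentose phosphate pathway",
    "Energy storage",
    "Pyruvate formation from phosphoenolpyruvate",
    "End-product synthesis from pyruvate",
    "Energy generation",
)

SUMMARY_COLUMNS = (
    "category",
    "total_genes",
    "detected_1plex",
    "detected_4plex",
    "detected_total",
    "increased",
    "decreased",
)


class HeadlinePercents(NamedTuple):
    pct_changed: int
    pct_increased: int
    pct_decreased: int


def load_category_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (locus_tag, category) into a dict.

    A tag appearing twice is an error: category membership must be
    unambiguous.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["locus_tag", "category"]:
        frame.columns = ["locus_tag", "category", *frame.columns[2:]]
    mapping: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        tag, category = row.locus_tag, row.category
        if tag in mapping:
            raise DuplicateEntryError(f"locus tag {tag} mapped to more than one category")
        mapping[tag] = category
    return mapping


def load_builtin_category_map() -> dict[str, str]:
    """The packaged seed map covering the locus tags of the core pathways."""
    ref = resources.files("proteoquant").joinpath("data/categories_seed.tsv")
    with resources.as_file(ref) as path:
        return load_category_map(path)


def load_reference_counts() -> pd.DataFrame:
    """Packaged reference per-category count table (11 rows, no totals row)."""
    ref = resources.files("proteoquant").joinpath("data/core_metabolism_counts.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def assign_categories(
    protein_ids: Iterable[str], category_map: Mapping[str, str]
) -> pd.DataFrame:
    """Label proteins with their category; unmapped tags become "other"."""
    rows = [
        {"protein_id": pid, "category": category_map.get(pid, "other")} for pid in protein_ids
    ]
    return pd.DataFrame(rows, columns=["protein_id", "category"])


def totals_row(summary: pd.DataFrame) -> pd.Series:
    """Column-wise sums of the per-category count rows (the totals logic)."""
    numeric = [c for c in SUMMARY_COLUMNS if c != "category"]
    totals = summary[numeric].sum()
    totals["category"] = "Total"
    return totals[list(SUMMARY_COLUMNS)]


def summarize(
    detected_1plex_ids: Iterable[str],
    quant_4plex: pd.DataFrame,
    category_map: Mapping[str, str],
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build the per-category summary with a trailing totals row.

    ``detected_1plex_ids`` are proteins detected by the shotgun run;
    ``quant_4plex`` is the protein quantitation table from the 4-plex path
    (needs protein_id, direction, change_class).  ``total_genes`` counts the
    map entries per category; detection totals are strict per-protein unions
    of the two methods; increase/decrease counts take confident calls
    (change_class != "none") split by direction.
    """
    ids_1plex = set(detected_1plex_ids)
    ids_4plex = set(quant_4plex["protein_id"]) if len(quant_4plex) else set()

    if categories is None:
        seen = set(category_map.values())
        categories = [c for c in CORE_CATEGORIES if c in seen]
        categories += sorted(seen - set(CORE_CATEGORIES))
    cat_of = lambda pid: category_map.get(pid, "other")

    increased_ids: set[str] = set()
    decreased_ids: set[str] = set()
    if len(quant_4plex):
        called = quant_4plex[quant_4plex["change_class"] != "none"]
        increased_ids = set(called.loc[called["direction"] > 0, "protein_id"])
        decreased_ids = set(called.loc[called["direction"] < 0, "protein_id"])

    all_ids = ids_1plex | ids_4plex
    rows = []
    for category in categories:
        members = {pid for pid in all_ids if cat_of(pid) == category}
        rows.append(
            {
                "category": category,
                "total_genes": sum(1 for c in category_map.values() if c == category),
                "detected_1plex": len(members & ids_1plex),
                "detected_4plex": len(members & ids_4plex),
                "detected_total": len(members),
                "increased": len(members & increased_ids),
                "decreased": len(members & decreased_ids),
            }
        )
    summary = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    summary = pd.concat([summary, totals_row(summary).to_frame().T], ignore_index=True)
    for column in SUMMARY_COLUMNS[1:]:
        summary[column] = summary[column].astype(int)
    return summary


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def headline_percents(increased: int, decreased: int, detected_4plex: int) -> HeadlinePercents:
    """Percentages of 4-plex-detected proteins that changed / increased /
    decreased, rounded half-up to whole percent."""
    if detected_4plex <= 0:
        raise ValueError("detected_4plex must be positive")
    pct = lambda k: _round_half_up(100.0 * k / detected_4plex)
    return HeadlinePercents(
        pct_changed=pct(increased + decreased),
        pct_increased=pct(increased),
        pct_decreased=pct(decreased),
    )
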