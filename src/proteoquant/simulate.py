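"""Synthetic proteome / PSM generator with ground truth.

Emulates the statistical structure the analysis assumes for a
two-condition (exponential vs stationary phase), two-replicate iTRAQ
4-plex experiment:

* protein molecular masses and molar abundances are lognormal;
* spectral counts are Poisson with mean proportional to abundance × mass
  (larger, more abundant proteins yield more spectra);
* each PSM carries four reporter intensities with independent
  multiplicative lognormal noise per channel (normal on the log2 scale);
  channels 114/115 follow the exponential-phase abundance, 116/117 are
  shifted by the protein's true log2 fold change;
* a configurable fraction of proteins carries a true fold change, the
  rest are nulls;
* a configurable fraction of PSMs fails the expectation filter, and a
  fraction of peptides is shared between two database entries.

What it does **not** emulate: chromatographic retention, fragmentation,
search-engine scoring, isotope impurity bleed-through between reporter
channels, or correlated replicate batch effects (the latter available via
``replicate_noise_corr`` to stress-test the replicate-noise subtraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .psm_io import PSM, ProteinRecord, average_mass_kda, write_psm_table
from .report import CORE_CATEGORIES
from .vdiff import ClassThresholds, quantify_proteins

# residues used to build simulated tryptic segments: body excludes K/R/P
# (P only to keep cleavage behaviour trivial), last residue is K or R
_BODY_AA = np.array(list("ACDEFGHILMNQSTVWY"))
_TERM_AA = np.array(list("KR"))

#: average residue mass, used only to size sequences toward a target mass
_MEAN_RESIDUE_KDA = 0.1111


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults describe a realistic mid-size run.

    Masses centre near 35 kDa (typical bacterial protein), abundances span
    ~2 orders of magnitude (sigma 1.0 on the natural-log scale), and
    ``spc_rate`` = 0.25 gives a median detected protein on the order of ten
    spectra.  15% of proteins carry a true change with log2 fold changes
    drawn from N(0, 1.5); reporter noise is 0.3 on the log2 scale.
    """

    n_proteins: int = 500
    seed: int = 0
    mass_lognormal: tuple[float, float] = (math.log(35.0), 0.45)
    abundance_lognormal: tuple[float, float] = (0.0, 1.0)
    spc_rate: float = 0.25
    frac_differential: float = 0.15
    log2fc_distribution: tuple[float, float] = (0.0, 1.5)
    reporter_noise_sd: float = 0.3
    peptides_per_protein: float = 4.0
    frac_shared_peptides: float = 0.05
    base_intensity: float = 1000.0
    frac_low_confidence: float = 0.05
    frac_other_category: float = 0.25
    replicate_noise_corr: float = 0.0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        for name in ("spc_rate", "reporter_noise_sd", "peptides_per_protein", "base_intensity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "frac_differential",
            "frac_shared_peptides",
            "frac_low_confidence",
            "frac_other_category",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not -1.0 <= self.replicate_noise_corr <= 1.0:
            raise ValueError("replicate_noise_corr must be in [-1, 1]")
        if self.mass_lognormal[1] <= 0 or self.abundance_lognormal[1] <= 0:
            raise ValueError("lognormal sigmas must be > 0")


def tryptic_peptides(sequence: str, min_len: int = 6) -> list[str]:
    """Split after every K/R (no proline rule) and keep peptides ≥ min_len.

    Simplified cleavage, consistent with how simulated sequences are built;
    order follows the sequence.
    """
    peptides: list[str] = []
    start = 0
    for i, ch in enumerate(sequence):
        if ch in "KR":
            peptides.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        peptides.append(sequence[start:])
    return [p for p in peptides if len(p) >= min_len]


def _random_sequence(rng: np.random.Generator, target_kda: float) -> str:
    """Concatenate random tryptic segments until the target mass is reached."""
    target_len = max(8, int(round(target_kda * 1000.0 / (_MEAN_RESIDUE_KDA * 1000.0))))
    chunks: list[str] = []
    total = 0
    while total < target_len:
        seg_len = int(rng.integers(7, 21))
        body = "".join(_BODY_AA[rng.integers(0, len(_BODY_AA), seg_len - 1)])
        chunks.append(body + str(_TERM_AA[rng.integers(0, 2)]))
        total += seg_len
    return "".join(chunks)


def _truncated_poisson(rng: np.random.Generator, lam: float) -> int:
    """Poisson conditioned on >= 1."""
    while True:
        k = int(rng.poisson(lam))
        if k >= 1:
            return k


def simulate_proteome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Draw a protein database plus ground truth.

    Returns FASTA-ready records and a truth table with one row per protein:
    protein_id, abundance, log2fc (0 for nulls), mass_kDa, length,
    n_peptides (observable), category.  Deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    rows = []
    mu_m, sd_m = config.mass_lognormal
    mu_a, sd_a = config.abundance_lognormal
    for i in range(config.n_proteins):
        pid = f"SIM_{i:04d}"
        target_mass = float(rng.lognormal(mu_m, sd_m))
        sequence = _random_sequence(rng, target_mass)
        abundance = float(rng.lognormal(mu_a, sd_a))
        log2fc = 0.0
        if rng.random() < config.frac_differential:
            log2fc = float(rng.normal(*config.log2fc_distribution))
        if rng.random() < config.frac_other_category:
            category = "other"
        else:
            category = str(CORE_CATEGORIES[int(rng.integers(0, len(CORE_CATEGORIES)))])
        available = tryptic_peptides(sequence)
        n_peptides = min(_truncated_poisson(rng, config.peptides_per_protein), len(available))
        record = ProteinRecord(
            protein_id=pid,
            description=f"simulated protein ({category})",
            sequence=sequence,
            molecular_mass_kDa=average_mass_kda(sequence),
            category=category,
        )
        records.append(record)
        rows.append(
            {
                "protein_id": pid,
                "abundance": abundance,
                "log2fc": log2fc,
                "mass_kDa": record.molecular_mass_kDa,
                "length": len(sequence),
                "n_peptides": n_peptides,
                "category": category,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["protein_id", "abundance", "log2fc", "mass_kDa", "length", "n_peptides", "category"],
    )
    return records, truth


def simulate_psms(
    records: Sequence[ProteinRecord],
    truth: pd.DataFrame,
    config: SimulationConfig,
    with_reporters: bool = True,
    spc_multiplier: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[PSM]:
    """Draw a PSM table for the given proteome.

    Per protein, SpC ~ Poisson(spc_rate × abundance × mass) spread uniformly
    over its observable peptides.  With reporters, channels 114/115 track
    exponential-phase abundance and 116/117 the same shifted by the true
    log2 fold change, each with independent N(0, reporter_noise_sd) noise on
    the log2 scale (optionally correlated within a phase via
    ``replicate_noise_corr``).  A ``frac_low_confidence`` share of PSMs draws
    a failing expectation value; ``frac_shared_peptides`` of peptides map to
    a second, randomly chosen database entry.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    by_id = {r.protein_id: r for r in records}
    all_ids = [r.protein_id for r in records]
    psms: list[PSM] = []
    scan = 0
    corr = config.replicate_noise_corr
    for row in truth.itertuples(index=False):
        record = by_id[row.protein_id]
        mean_spc = config.spc_rate * spc_multiplier * row.abundance * row.mass_kDa
        spc = int(rng.poisson(mean_spc))
        if spc == 0:
            continue
        peptides = tryptic_peptides(record.sequence)[: row.n_peptides]
        partners: dict[str, str | None] = {}
        for pep in peptides:
            partner = None
            if len(all_ids) > 1 and rng.random() < config.frac_shared_peptides:
                while partner is None or partner == row.protein_id:
                    partner = all_ids[int(rng.integers(0, len(all_ids)))]
            partners[pep] = partner
        base = config.base_intensity * row.abundance
        for _ in range(spc):
            scan += 1
            pep = peptides[int(rng.integers(0, len(peptides)))]
            intensities = None
            if with_reporters:
                eps = rng.normal(0.0, config.reporter_noise_sd, 4)
                if corr != 0.0:
                    shared_exp = rng.normal(0.0, config.reporter_noise_sd)
                    shared_sta = rng.normal(0.0, config.reporter_noise_sd)
                    w = math.sqrt(abs(corr))
                    eps[0] = w * shared_exp + math.sqrt(1 - abs(corr)) * eps[0]
                    eps[1] = w * shared_exp + math.sqrt(1 - abs(corr)) * eps[1]
                    eps[2] = w * shared_sta + math.sqrt(1 - abs(corr)) * eps[2]
                    eps[3] = w * shared_sta + math.sqrt(1 - abs(corr)) * eps[3]
                intensities = {
                    "114": base * 2.0 ** eps[0],
                    "115": base * 2.0 ** eps[1],
                    "116": base * 2.0 ** (row.log2fc + eps[2]),
                    "117": base * 2.0 ** (row.log2fc + eps[3]),
                }
            low_confidence = rng.random() < config.frac_low_confidence
            if low_confidence:
                log_e = float(rng.uniform(-1.5, -0.3))
                confidence = float(rng.uniform(0.90, 0.999))
            else:
                log_e = float(rng.uniform(-6.0, -2.0))
                confidence = float(rng.uniform(0.9992, 1.0))
            partner = partners[pep]
            protein_ids = (row.protein_id,) if partner is None else (row.protein_id, partner)
            psms.append(
                PSM(
                    spectrum_id=f"scan_{scan:06d}",
                    peptide=pep,
                    protein_ids=protein_ids,
                    log_expectation=log_e,
                    confidence=confidence,
                    reporter_intensities=intensities,
                )
            )
    return psms


def end_to_end_fixture(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete on-disk fixture: FASTA, 1-plex and 4-plex PSM TSVs,
    category map, ground truth.

    The 1-plex (shotgun) table is an independent, label-free draw at twice
    the spectral sampling rate, mimicking the deeper coverage of
    single-plex acquisition.  Deterministic given ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    records, truth = simulate_proteome(config, rng=np.random.default_rng(seeds[0]))
    psms_4plex = simulate_psms(
        records, truth, config, with_reporters=True, rng=np.random.default_rng(seeds[1])
    )
    psms_1plex = simulate_psms(
        records,
        truth,
        config,
        with_reporters=False,
        spc_multiplier=2.0,
        rng=np.random.default_rng(seeds[2]),
    )

    paths = {
        "fasta": outdir / "proteome.fasta",
        "psms_4plex": outdir / "psms_4plex.tsv",
        "psms_1plex": outdir / "psms_1plex.tsv",
        "categories": outdir / "categories.tsv",
        "truth": outdir / "truth.tsv",
    }
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description=r.description) for r in records
    ]
    SeqIO.write(seq_records, str(paths["fasta"]), "fasta")
    write_psm_table(psms_4plex, paths["psms_4plex"])
    write_psm_table(psms_1plex, paths["psms_1plex"])
    truth[["protein_id", "category"]].rename(columns={"protein_id": "locus_tag"}).to_csv(
        paths["categories"], sep="\t", index=False
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def recovery_rates(
    config: SimulationConfig,
    n_sims: int = 25,
    seed: int | None = None,
    fc_threshold: float = 1.0,
    min_quant_peptides: int = 3,
    thresholds: ClassThresholds = ClassThresholds(),
) -> dict[str, float]:
    """Monte-Carlo recall / false-call evaluation of the calling pipeline.

    Runs ``n_sims`` independent simulations at the given config and pools:

    * recall — fraction of proteins with |true log2FC| ≥ ``fc_threshold``
      and ≥ ``min_quant_peptides`` quantified peptides that are called
      (d_scaled ≥ t_confident) in the correct direction;
    * null_rate — fraction of call-eligible null proteins called at all.
    """
    base_seed = config.seed if seed is None else seed
    n_true = n_called = n_null = n_false = 0
    for i in range(n_sims):
        cfg = replace(config, seed=base_seed + i)
        records, truth = simulate_proteome(cfg)
        psms = simulate_psms(records, truth, cfg)
        quant, _ = quantify_proteins(psms, records, thresholds=thresholds)
        merged = quant.merge(truth[["protein_id", "log2fc"]], on="protein_id", how="left")
        # shared peptides can attach a few spectra to proteins with no truth
        # row of their own channel pattern; log2fc is always defined here
        differential = merged[
            (merged["log2fc"].abs() >= fc_threshold)
            & (merged["n_peptides"] >= min_quant_peptides)
        ]
        n_true += len(differential)
        correct = (differential["change_class"] != "none") & (
            np.sign(differential["direction"]) == np.sign(differential["log2fc"])
        )
        n_called += int(correct.sum())
        nulls = merged[(merged["log2fc"] == 0) & (~merged["low_evidence"])]
        n_null += len(nulls)
        n_false += int((nulls["change_class"] != "none").sum())
    return {
        "recall": n_called / n_true if n_true else float("nan"),
        "null_rate": n_false / n_null if n_null else float("nan"),
        "n_true": n_true,
        "n_null": n_null,
        "n_sims": n_sims,
    }
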