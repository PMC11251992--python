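"""Synthetic inputs for every pipeline stage, with known ground truth.

The generator emulates the structure of the wet-lab screen: random proteins
with planted point mutations, 384-well TR-FRET plates (controls in the
first two columns, up to 352 sample wells), log-normal fluorescence noise,
binders planted at a chosen effect size, predictor rank tables correlated
with the planted truth, and PRM quantification tables derived from known
presented amounts plus background. Every output is a pure function of the
configuration (including its seed); the same configuration reproduces the
same tables byte for byte.

Effect sizes are expressed in robust units: a planted binder's mean %DeltaF
sits ``binder_effect`` scaled-MADs (of the null %DeltaF distribution) above
the negative controls, so the expected RZ-score of a binder well is close
to ``binder_effect`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .enumeration import (
    AMINO_ACIDS,
    NeoantigenVariant,
    ScreenManifest,
    build_manifest,
    build_window,
)
from .trfret import (
    MAD_SCALE,
    ROLE_NEG_NO_HLA,
    ROLE_NEG_NO_PEPTIDE,
    ROLE_POS,
    ROLE_SAMPLE,
)

#: common HLA class I alleles used to name simulated screens
DEFAULT_ALLELES = (
    "A*01:01", "A*02:01", "A*03:01", "A*11:01", "A*24:02",
    "B*07:02", "B*08:01", "B*35:01", "B*44:02", "B*51:01",
    "C*03:04", "C*04:01", "C*05:01", "C*06:02", "C*07:01", "C*07:02",
)

PLATE_ROWS = "ABCDEFGHIJKLMNOP"
PLATE_COLS = 24
POS_CTRL_PEPTIDE = "NLVPMVATV"  # CMV pp65, the canonical A*02:01 exchange control
POS_CTRL_ALLELE = "A*02:01"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic screen and quantification.

    Defaults mirror the screened study design: 47 neoantigens by 15 HLA
    alleles, 384-well plates with <= 352 sample wells, positive controls in
    quadruplicate and no-peptide negatives in octuplicate, and a planted
    binder fraction near the observed candidate rate (844 of 24,149 pairs).
    """

    seed: int = 0
    n_variants: int = 47
    n_alleles: int = 15
    plate_size: int = 384
    max_samples_per_plate: int = 352
    flank: int = 12
    protein_length: int = 200
    binder_fraction: float = 0.035
    #: separation of a planted binder's mean %DeltaF from the negative
    #: distribution, in scaled-MAD units (so expected RZ ~ binder_effect)
    binder_effect: float = 10.0
    #: separation of the positive exchange control, same units; a strong
    #: viral epitope separates more than a typical planted hit
    pos_ctrl_effect: float = 20.0
    #: lognormal coefficient of variation of the RFU channels
    noise_cv: float = 0.05
    #: probability a true binder receives predictor rank <= 2
    rank_concordance: float = 0.3
    rank_threshold: float = 2.0
    base_ratio: float = 2000.0
    base_rfu_615: float = 5.0e4
    n_pos_ctrl: int = 4
    n_neg_no_peptide: int = 8
    n_neg_no_hla: int = 4
    # PRM quantification
    prm_noise_cv: float = 0.1
    background_amol: float = 20.0
    spike_fmol: float = 100.0
    injected_fraction: float = 1.0 / 3.0
    n_cells: float = 5.0e7


@dataclass
class SimulatedScreen:
    plates: pd.DataFrame
    truth: pd.DataFrame  # peptide, allele, is_binder
    ranks: pd.DataFrame  # peptide, allele, ba_rank, el_rank
    manifest: ScreenManifest
    variants: list[NeoantigenVariant] = field(default_factory=list)
    proteins: dict[str, str] = field(default_factory=dict)


def lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def lognormal_scaled_mad(cv: float) -> float:
    """Scaled MAD (1.4826 * MAD) of a mean-1 lognormal with the given CV.

    Used to translate an effect size in robust units into a multiplicative
    shift of the well ratio: the null %DeltaF distribution has scaled MAD of
    about ``100 * lognormal_scaled_mad(cv)`` percent.
    """
    if cv <= 0:
        raise ValueError("cv must be positive")
    sigma = np.sqrt(np.log1p(cv**2))
    median = np.exp(-sigma**2 / 2)

    def cdf(t: float) -> float:
        return norm.cdf((np.log(t) + sigma**2 / 2) / sigma) if t > 0 else 0.0

    def half_mass(d: float) -> float:
        return cdf(median + d) - cdf(max(median - d, 0.0)) - 0.5

    mad = brentq(half_mass, 1e-12, 10.0)
    return MAD_SCALE * mad


def simulate_proteins_and_variants(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[NeoantigenVariant]]:
    """Random proteins, one interior point substitution each."""
    aa = np.array(list(AMINO_ACIDS))
    proteins: dict[str, str] = {}
    variants: list[NeoantigenVariant] = []
    lo = 2 * config.flank + 1
    hi = config.protein_length - 2 * config.flank
    if hi < lo:
        raise ValueError("protein_length too short for interior mutations")
    for i in range(config.n_variants):
        protein_id = f"PROT{i + 1:03d}"
        seq = "".join(rng.choice(aa, size=config.protein_length))
        position = int(rng.integers(lo, hi + 1))
        ref = seq[position - 1]
        alt = str(rng.choice([a for a in AMINO_ACIDS if a != ref]))
        proteins[protein_id] = seq
        variants.append(
            build_window(
                seq, position, ref, alt,
                flank=config.flank,
                variant_id=f"VAR{i + 1:03d}",
                protein_id=protein_id,
            )
        )
    return proteins, variants


def _control_wells() -> list[str]:
    """Well addresses reserved for controls (plate columns 1-2)."""
    return [f"{row}{col}" for col in (1, 2) for row in PLATE_ROWS]


def _sample_wells(n: int) -> list[str]:
    wells = [
        f"{row}{col}" for col in range(3, PLATE_COLS + 1) for row in PLATE_ROWS
    ]
    return wells[:n]


def _plate_rows(
    config: SimulationConfig,
    rng: np.random.Generator,
    plate_id: str,
    allele: str,
    peptides: list[str],
    is_binder: np.ndarray,
    s_delta: float,
) -> list[dict]:
    """One 384-well plate: controls in columns 1-2, samples in 3-24."""
    control_wells = _control_wells()
    rows: list[dict] = []

    def emit(well, role, peptide, well_allele, multiplier):
        ratio = config.base_ratio * multiplier * lognormal_factors(rng, config.noise_cv, 1)[0]
        rfu_615 = config.base_rfu_615 * lognormal_factors(rng, config.noise_cv, 1)[0]
        rows.append(
            {
                "plate_id": plate_id,
                "well": well,
                "role": role,
                "peptide": peptide,
                "allele": well_allele,
                "rfu_665": ratio * rfu_615 / 1e4,
                "rfu_615": rfu_615,
            }
        )

    w = iter(control_wells)
    pos_mult = 1.0 + config.pos_ctrl_effect * s_delta
    for _ in range(config.n_pos_ctrl):
        emit(next(w), ROLE_POS, POS_CTRL_PEPTIDE, POS_CTRL_ALLELE, pos_mult)
    for _ in range(config.n_neg_no_peptide):
        emit(next(w), ROLE_NEG_NO_PEPTIDE, None, allele, 1.0)
    for _ in range(config.n_neg_no_hla):
        emit(next(w), ROLE_NEG_NO_HLA, None, allele, 0.5)

    binder_mult = 1.0 + config.binder_effect * s_delta
    for well, peptide, binder in zip(_sample_wells(len(peptides)), peptides, is_binder):
        emit(well, ROLE_SAMPLE, peptide, allele, binder_mult if binder else 1.0)
    return rows


def simulate_screen(
    config: SimulationConfig, manifest: ScreenManifest | None = None
) -> SimulatedScreen:
    """Generate TR-FRET plates, binder truth and predictor ranks.

    When no manifest is supplied, random proteins and variants are generated
    and expanded into the full candidate-by-allele manifest first. Peptides
    for each allele are laid out on as many plates as needed (<= 352 sample
    wells per plate, controls in the first two columns).
    """
    rng = np.random.default_rng(config.seed)
    proteins: dict[str, str] = {}
    variants: list[NeoantigenVariant] = []
    if manifest is None:
        proteins, variants = simulate_proteins_and_variants(config, rng)
        alleles = list(DEFAULT_ALLELES[: config.n_alleles])
        manifest = build_manifest(variants, alleles)

    table = manifest.table
    truth = table[["peptide", "allele"]].copy()
    truth["is_binder"] = rng.random(len(truth)) < config.binder_fraction

    s_delta = lognormal_scaled_mad(config.noise_cv)
    plate_rows: list[dict] = []
    for allele, sub in truth.groupby("allele", sort=True):
        peptides = sub["peptide"].tolist()
        binder = sub["is_binder"].to_numpy()
        n_chunk = config.max_samples_per_plate
        for chunk_idx, start in enumerate(range(0, len(peptides), n_chunk)):
            plate_id = f"{allele}|p{chunk_idx + 1}"
            plate_rows.extend(
                _plate_rows(
                    config, rng, plate_id, allele,
                    peptides[start : start + n_chunk],
                    binder[start : start + n_chunk],
                    s_delta,
                )
            )
    plates = pd.DataFrame(plate_rows)

    # predictor ranks: binders hit rank <= threshold with probability
    # rank_concordance; null peptides get uniform percentile ranks, so they
    # land below the threshold at the ~2% base rate by construction
    is_binder = truth["is_binder"].to_numpy()
    n = len(truth)

    def draw_ranks() -> np.ndarray:
        ranks = rng.uniform(0.0, 100.0, size=n)
        concordant = is_binder & (rng.random(n) < config.rank_concordance)
        ranks[concordant] = rng.uniform(0.0, config.rank_threshold, size=int(concordant.sum()))
        discordant = is_binder & ~concordant
        ranks[discordant] = rng.uniform(
            config.rank_threshold, 100.0, size=int(discordant.sum())
        )
        return ranks

    ranks = truth[["peptide", "allele"]].copy()
    ranks["ba_rank"] = draw_ranks()
    ranks["el_rank"] = draw_ranks()

    return SimulatedScreen(
        plates=plates,
        truth=truth,
        ranks=ranks,
        manifest=manifest,
        variants=variants,
        proteins=proteins,
    )


def simulate_prm(
    config: SimulationConfig,
    truth_amounts: pd.DataFrame,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """PRM measurement table from known presented amounts.

    ``truth_amounts`` has columns ``peptide, allele, amount_amol`` giving the
    true presented amount per pair in the whole sample. The injected
    fraction of each sample carries ``amount * fraction`` attomoles onto the
    column; the light channel adds the synthetic-peptide background and
    lognormal noise, and the heavy channel fluctuates independently around a
    nominal response. The ``background_amol`` column carries the background
    as measured in a synthetic-only run (noisy, not the exact truth).
    """
    for col in ("peptide", "allele", "amount_amol"):
        if col not in truth_amounts.columns:
            raise ValueError("truth_amounts needs columns peptide, allele, amount_amol")
    if (truth_amounts["amount_amol"] < 0).any():
        raise ValueError("amounts must be nonnegative")
    rng = np.random.default_rng(config.seed + 1)
    heavy_nominal = 1.0e6
    spike_amol = config.spike_fmol * 1e3
    rows = []
    for rep in range(1, n_replicates + 1):
        n = len(truth_amounts)
        heavy = heavy_nominal * lognormal_factors(rng, config.prm_noise_cv, n)
        on_column = (
            truth_amounts["amount_amol"].to_numpy() * config.injected_fraction
            + config.background_amol
        )
        light = (
            heavy_nominal
            * (on_column / spike_amol)
            * lognormal_factors(rng, config.prm_noise_cv, n)
        )
        bg_measured = config.background_amol * lognormal_factors(
            rng, config.prm_noise_cv, n
        )
        for i, row in enumerate(truth_amounts.itertuples(index=False)):
            rows.append(
                {
                    "peptide": row.peptide,
                    "allele": row.allele,
                    "sample_id": f"rep{rep}",
                    "light_area": light[i],
                    "heavy_area": heavy[i],
                    "spike_fmol": config.spike_fmol,
                    "background_amol": bg_measured[i],
                    "injected_fraction": config.injected_fraction,
                    "n_cells": config.n_cells,
                }
            )
    return pd.DataFrame(rows)


def write_input_bundle(sim: SimulatedScreen, directory) -> dict[str, Path]:
    """Write the simulated inputs (FASTA, variants, plates, ranks, truth) to disk."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    fasta = directory / "proteins.fasta"
    with open(fasta, "w") as fh:
        for pid, seq in sim.proteins.items():
            fh.write(f">{pid}\n{seq}\n")
    paths["proteins"] = fasta

    variants = directory / "variants.tsv"
    pd.DataFrame(
        [
            {
                "variant_id": v.variant_id,
                "protein_id": v.protein_id,
                "position": v.protein_position,
                "ref": v.ref_residue,
                "alt": v.alt_residue,
            }
            for v in sim.variants
        ]
    ).to_csv(variants, sep="\t", index=False)
    paths["variants"] = variants

    for name, df in (
        ("plates", sim.plates), ("ranks", sim.ranks), ("truth", sim.truth),
    ):
        path = directory / f"{name}.{'csv' if name == 'plates' else 'tsv'}"
        df.to_csv(path, sep="," if name == "plates" else "\t", index=False)
        paths[name] = path
    return paths
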