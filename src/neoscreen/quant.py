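"""Targeted-MS absolute quantification of presented neoepitopes.

Parallel reaction monitoring (PRM) with AQUA heavy spike-ins quantifies a
light (endogenous) peptide against a co-eluting heavy isotope-labeled
standard of known amount:

    amount on column = (light area / heavy area) * spike amount.

Background measured in a synthetic-peptide-only run is subtracted (floored
at zero; negative presented amounts are non-physical), and, when the cell
input is known, the net molar amount converts to copies per cell via
Avogadro's number and the injected fraction of the sample.

Also includes the specific-lysis computation from TCR reactivity assays.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .cassette import CassetteDesign

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23
AMOL_PER_FMOL = 1e3
MOL_PER_AMOL = 1e-18
DEFAULT_INJECTED_FRACTION = 1.0 / 3.0

PRM_COLUMNS = [
    "peptide", "allele", "sample_id", "light_area", "heavy_area",
    "spike_fmol", "background_amol", "injected_fraction", "n_cells",
]


def amount_on_column(
    light_area: float, heavy_area: float, spike_fmol: float
) -> float:
    """Light/heavy ratio scaled by the heavy spike amount, in attomoles.

    Returns NaN (not-quantifiable) when the heavy standard was not detected
    (``heavy_area == 0``); the peptide cannot be quantified without its
    reference channel.
    """
    if light_area < 0 or heavy_area < 0 or spike_fmol < 0:
        raise ValueError("areas and spike amount must be nonnegative")
    if heavy_area == 0:
        logger.warning("heavy standard not detected; measurement flagged not-quantifiable")
        return math.nan
    return (light_area / heavy_area) * spike_fmol * AMOL_PER_FMOL


def subtract_background(amount_amol: float, background_amol: float) -> float:
    """Background-subtracted amount, floored at zero attomoles."""
    if amount_amol < 0 or background_amol < 0:
        raise ValueError("amounts must be nonnegative")
    net = amount_amol - background_amol
    if net < 0:
        logger.info(
            "background %.3g amol exceeds signal %.3g amol; floored at 0",
            background_amol, amount_amol,
        )
        return 0.0
    return net


def copies_per_cell(
    amount_net_amol: float,
    injected_fraction: float = DEFAULT_INJECTED_FRACTION,
    n_cells: float = None,
) -> float:
    """Presented copies per cell from the net on-column amount.

    Scales the on-column amount up by the injected fraction of the sample,
    converts attomoles to molecules, and divides by the number of input
    cells: ``(amount_net / fraction) * 1e-18 * N_A / n_cells``.
    """
    if not 0 < injected_fraction <= 1:
        raise ValueError("injected_fraction must lie in (0, 1]")
    if n_cells is None or n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if amount_net_amol < 0:
        raise ValueError("amount must be nonnegative")
    return amount_net_amol / injected_fraction * MOL_PER_AMOL * AVOGADRO / n_cells


def quantify(prm: pd.DataFrame) -> pd.DataFrame:
    """Run the full quantification over a PRM measurement table.

    Input columns: ``peptide, allele, sample_id, light_area, heavy_area,
    spike_fmol, background_amol, injected_fraction, n_cells`` (``n_cells``
    may be null, in which case copies per cell is null too).

    Output adds ``amount_on_column_amol``, ``amount_net_amol``,
    ``copies_per_cell`` and a ``quantifiable`` flag (False when the heavy
    standard was absent).
    """
    missing = [c for c in PRM_COLUMNS if c not in prm.columns]
    if missing:
        raise ValueError(f"PRM table is missing columns: {missing}")
    out = prm.copy()
    heavy = out["heavy_area"].to_numpy(dtype=float)
    light = out["light_area"].to_numpy(dtype=float)
    spike = out["spike_fmol"].to_numpy(dtype=float)
    if (heavy < 0).any() or (light < 0).any() or (spike < 0).any():
        raise ValueError("areas and spike amounts must be nonnegative")
    quantifiable = heavy > 0
    n_flagged = int((~quantifiable).sum())
    if n_flagged:
        logger.warning(
            "%d measurements lack a detected heavy standard; flagged", n_flagged
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        on_col = np.where(
            quantifiable, light / np.where(quantifiable, heavy, 1.0) * spike * AMOL_PER_FMOL,
            np.nan,
        )
    bg = out["background_amol"].to_numpy(dtype=float)
    if (bg < 0).any():
        raise ValueError("background amounts must be nonnegative")
    net = np.maximum(on_col - bg, 0.0)
    frac = out["injected_fraction"].to_numpy(dtype=float)
    if ((frac <= 0) | (frac > 1)).any():
        raise ValueError("injected_fraction must lie in (0, 1]")
    n_cells = pd.to_numeric(out["n_cells"], errors="coerce").to_numpy(dtype=float)
    cpc = np.where(
        np.isnan(n_cells),
        np.nan,
        net / frac * MOL_PER_AMOL * AVOGADRO / np.where(np.isnan(n_cells), 1.0, n_cells),
    )
    out["quantifiable"] = quantifiable
    out["amount_on_column_amol"] = on_col
    out["amount_net_amol"] = net
    out["copies_per_cell"] = cpc
    return out


def summarize_presentation(
    results: pd.DataFrame,
    design: CassetteDesign,
    peptide_variants: pd.DataFrame,
) -> dict:
    """Summarize detected presentation per neoantigen and per allele.

    Parameters
    ----------
    results
        Output of :func:`quantify` (needs ``peptide, allele,
        amount_net_amol``).
    design
        The polyantigen cassette whose segment ids are neoantigen/variant
        ids, used to attach each neoantigen's cassette position.
    peptide_variants
        Mapping table with columns ``peptide, variant_id``.

    Returns
    -------
    dict with keys

    - ``per_neoantigen``: one row per neoantigen with >= 1 detection
      (net amount > 0): max net amount over its peptides and alleles, the
      detecting alleles, and the 1-based cassette segment index;
    - ``per_allele``: detected (peptide, allele) pair counts per allele;
    - ``orphans``: peptides in ``results`` without a variant mapping;
    - ``not_detected``: neoantigens with no detection (the zero-report).
    """
    for col in ("peptide", "variant_id"):
        if col not in peptide_variants.columns:
            raise ValueError("peptide_variants needs columns peptide, variant_id")
    merged = results.merge(peptide_variants, on="peptide", how="left")
    orphans = sorted(merged.loc[merged["variant_id"].isna(), "peptide"].unique())
    if orphans:
        logger.warning("%d peptides could not be mapped to a neoantigen", len(orphans))
    mapped = merged.dropna(subset=["variant_id"])
    detected = mapped[mapped["amount_net_amol"] > 0]

    rows = []
    for variant_id, sub in detected.groupby("variant_id", sort=True):
        best = sub.loc[sub["amount_net_amol"].idxmax()]
        rows.append(
            {
                "variant_id": variant_id,
                "max_amount_amol": float(best["amount_net_amol"]),
                "best_peptide": best["peptide"],
                "alleles": tuple(sorted(sub["allele"].unique())),
                "segment_index": (
                    design.segment_index(variant_id)
                    if variant_id in design.coord_map
                    else None
                ),
            }
        )
    per_neoantigen = pd.DataFrame(
        rows,
        columns=["variant_id", "max_amount_amol", "best_peptide", "alleles",
                 "segment_index"],
    )
    per_allele = (
        detected.drop_duplicates(["peptide", "allele"])
        .groupby("allele")
        .size()
        .rename("n_detected_pairs")
        .reset_index()
    )
    all_variants = set(peptide_variants["variant_id"])
    not_detected = sorted(all_variants - set(per_neoantigen["variant_id"]))
    return {
        "per_neoantigen": per_neoantigen,
        "per_allele": per_allele,
        "orphans": orphans,
        "not_detected": not_detected,
    }


def specific_lysis(p_mock: float, p_tcr: float) -> float:
    """Percent specific lysis from target-cell proportions.

    ``p_mock`` and ``p_tcr`` are the proportions of transfected target cells
    surviving co-culture with mock- and TCR-transfected effectors:
    ``100 * (p_mock - p_tcr) / p_mock``. A negative result (more targets
    with the TCR than with mock) is returned as-is with a warning.
    """
    if not 0 < p_mock <= 1:
        raise ValueError("p_mock must lie in (0, 1]")
    if not 0 <= p_tcr <= 1:
        raise ValueError("p_tcr must lie in [0, 1]")
    lysis = (p_mock - p_tcr) / p_mock * 100.0
    if lysis < 0:
        logger.warning("negative specific lysis (%.1f%%); target grew with TCR", lysis)
    return lysis


def read_prm(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PRM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PRM table is missing columns: {missing}")
    return df
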